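"""Independent reference implementations used to cross-check the pipeline.

These are deliberately naive: exhaustive pairwise graphs, full enumeration
of label assignments, direct dual-form kernel sums.  They share no code
with the production paths they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

from pepage.calibrate import link_predicate


def brute_force_partition(obs_by_sample, params, run_span):
    """Single-linkage clusters as connected components of the all-pairs graph."""
    flat = [(sid, o) for sid, prof in obs_by_sample.items() for o in prof]
    n = len(flat)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = flat[i][1], flat[j][1]
        if link_predicate(
            a.mass_da, a.migration_min, b.mass_da, b.migration_min, run_span, params
        ):
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    parts = set()
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        parts.add(frozenset((flat[k][0], flat[k][1].local_id) for k in comp))
    return parts


def tie_corrected_abs_z(values: np.ndarray, group_a: np.ndarray) -> float:
    """Standardized Wilcoxon rank sum with tie-corrected variance."""
    r = sps.rankdata(values)
    n = len(values)
    na = int(group_a.sum())
    w = r[group_a].sum()
    mean = na * (n + 1) / 2.0
    _, c = np.unique(values, return_counts=True)
    var = na * (n - na) / 12.0 * ((n + 1) - (c**3 - c).sum() / (n * (n - 1)))
    return float(abs(w - mean) / np.sqrt(var)) if var > 0 else 0.0


def exhaustive_maxt(x: np.ndarray, n_a: int) -> np.ndarray:
    """Exact maxT step-down adjusted p by full enumeration of assignments.

    ``x`` is peptides x samples (no missing values); the first ``n_a``
    columns form group A in the observed labelling.  Returns adjusted p per
    peptide in input row order.
    """
    m, n = x.shape
    obs_ga = np.arange(n) < n_a
    obs = np.array([tie_corrected_abs_z(x[i], obs_ga) for i in range(m)])
    order = np.argsort(-obs, kind="stable")
    zs = []
    for comb in itertools.combinations(range(n), n_a):
        ga = np.zeros(n, dtype=bool)
        ga[list(comb)] = True
        zs.append([tie_corrected_abs_z(x[i], ga) for i in range(m)])
    zs = np.asarray(zs)
    stepdown = np.maximum.accumulate(zs[:, order][:, ::-1], axis=1)[:, ::-1]
    p_ord = np.maximum.accumulate((stepdown >= obs[order]).mean(axis=0))
    p = np.empty(m)
    p[order] = p_ord
    return p


def dual_form_decision(model, x: np.ndarray) -> np.ndarray:
    """sum_i alpha_i y_i exp(-gamma ||sv_i - x||^2) + b, summed explicitly."""
    out = []
    for row in np.atleast_2d(x):
        acc = model.intercept
        for coef, sv in zip(model.dual_coef, model.support_vectors):
            acc += coef * np.exp(-model.hyper.gamma * np.sum((sv - row) ** 2))
        out.append(acc)
    return np.asarray(out)
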