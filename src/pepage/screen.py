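"""Per-peptide Wilcoxon rank-sum screening with maxT step-down adjustment.

For each master peptide the two age groups are compared with the Wilcoxon
rank-sum test; the base statistic is the tie-corrected standardized rank sum
|Z|, which keeps peptides with different missingness patterns on a common
scale.  Family-wise error is controlled with the Westfall-Young maxT
step-down procedure: one stream of label permutations is shared by all
peptides of a comparison, |Z| is recomputed for every peptide on every
permutation, and the adjusted p-value of the i-th peptide (in decreasing
observed-|Z| order) is the fraction of permutations whose step-down maximum
(the max of permuted |Z| over peptides ranked i and below) reaches the
observed |Z_i|, with +1 smoothing in numerator and denominator.  Monotonicity
down the ordering is enforced by a cumulative maximum.

Missing amplitudes are dropped pairwise per peptide; a peptide left with
fewer than two observed values in either group under a given labelling gets
|Z| = 0 for that labelling.

Consensus selection: with three age groups all three pairwise comparisons
are run and a peptide is selected when its adjusted p falls below ``alpha``
in at least ``min_comparisons`` of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ConfigurationError
from .io import CohortDesign, MatchedMatrix


@dataclass(frozen=True)
class SelectionRule:
    """Consensus rule over the pairwise age comparisons."""

    alpha: float = 0.05
    min_comparisons: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_comparisons < 1:
            raise ConfigurationError(
                f"min_comparisons must be >= 1, got {self.min_comparisons}"
            )


@dataclass
class ComparisonResult:
    """Screening result for one age-group pair.

    ``table`` is indexed by master_id (ascending) with columns ``z`` (observed
    tie-corrected |Z|), ``p_raw`` (per-peptide permutation p) and ``p_adj``
    (maxT step-down adjusted p).
    """

    pair: tuple[str, str]
    table: pd.DataFrame
    n_permutations: int
    seed: int

    def significant(self, alpha: float = 0.05) -> list:
        return list(self.table.index[self.table["p_adj"] < alpha])


@dataclass
class ScreenResult:
    """All pairwise comparisons plus the consensus selection."""

    comparisons: dict[tuple[str, str], ComparisonResult]
    selected: list
    rule: SelectionRule
    counts: pd.Series = field(default=None)  # per-peptide number of significant pairs


def wilcoxon_standardized(values_a, values_b) -> tuple[float, float]:
    """Tie-corrected standardized Wilcoxon rank-sum |Z| and large-sample p.

    Both groups need >=2 values.  If every pooled value is identical the
    statistic is 0 and p is 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError(
            f"need >=2 non-missing values per group, got {len(a)} and {len(b)}"
        )
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = sps.rankdata(pooled)
    w = ranks[:na].sum()
    mean = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = na * (n - na) / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    z = abs(w - mean) / np.sqrt(var)
    return float(z), float(2 * sps.norm.sf(z))


def _rank_stats(x: np.ndarray):
    """Per-peptide ranks/masks/tie terms reused across all permutations.

    ``x`` is peptides x samples with NaN for missing.  Returns ranks with 0
    at missing cells, presence mask, per-peptide n, and tie correction term
    sum(t^3 - t).
    """
    present = ~np.isnan(x)
    ranks = sps.rankdata(x, axis=1, nan_policy="omit")
    ranks = np.where(present, ranks, 0.0)
    n_obs = present.sum(axis=1).astype(float)
    tie = np.zeros(x.shape[0])
    for i in range(x.shape[0]):
        vals = x[i, present[i]]
        if vals.size:
            _, c = np.unique(vals, return_counts=True)
            tie[i] = float((c**3 - c).sum())
    return ranks, present.astype(float), n_obs, tie


def _z_matrix(ranks, mask, n_obs, tie, g):
    """|Z| for every peptide under every column of group-A indicator ``g``.

    ``g`` is samples x B.  Peptides with <2 observed members in either group
    under a labelling get |Z| = 0 there.
    """
    w = ranks @ g                      # peptides x B rank sums in group A
    na = mask @ g                      # observed group-A sizes
    n = n_obs[:, None]
    nb = n - na
    mean = na * (n + 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        var = na * nb / 12.0 * ((n + 1) - tie[:, None] / (n * (n - 1)))
        z = np.abs(w - mean) / np.sqrt(var)
    bad = (na < 2) | (nb < 2) | ~np.isfinite(z)
    z[bad] = 0.0
    return z


def maxt_adjust(
    matrix,
    labels: Sequence,
    n_permutations: int = 10_000,
    seed: int = 0,
    pair: tuple[str, str] | None = None,
) -> ComparisonResult:
    """Westfall-Young maxT step-down adjustment for one two-group comparison.

    ``matrix`` is a :class:`~pepage.io.MatchedMatrix` or a peptides x samples
    DataFrame; ``labels`` assigns each sample column to one of exactly two
    groups.  One permutation stream (seeded, keyed to master ids sorted
    ascending) is shared by all peptides, as maxT requires.
    """
    if isinstance(matrix, MatchedMatrix):
        df = matrix.amplitudes
    else:
        df = pd.DataFrame(matrix)
    labels = np.asarray(labels)
    if labels.shape[0] != df.shape[1]:
        raise AnalysisError(
            f"{labels.shape[0]} labels for {df.shape[1]} sample columns"
        )
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise AnalysisError(
            f"maxt_adjust needs exactly two groups, got {uniq!r}; "
            "use pairwise_screen for multi-group designs"
        )
    if n_permutations < 100:
        raise ConfigurationError(
            f"n_permutations must be >= 100, got {n_permutations}"
        )
    if df.shape[0] < 1:
        raise AnalysisError("matrix has no peptides")
    group_a = labels == uniq[0]
    if group_a.sum() < 2 or (~group_a).sum() < 2:
        raise AnalysisError("each group needs >= 2 samples")

    # deterministic internal order regardless of caller's row order
    df = df.sort_index()
    x = df.to_numpy(dtype=float)
    ranks, mask, n_obs, tie = _rank_stats(x)

    z_obs = _z_matrix(ranks, mask, n_obs, tie, group_a.astype(float)[:, None])[:, 0]

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(group_a.astype(float), (n_permutations, 1)), axis=1
    ).T                                                   # samples x B
    z_perm = _z_matrix(ranks, mask, n_obs, tie, perms)    # peptides x B

    # raw permutation p per peptide
    p_raw = (1 + (z_perm >= z_obs[:, None]).sum(axis=1)) / (n_permutations + 1)

    # step-down maxima: order by decreasing observed |Z|
    order = np.argsort(-z_obs, kind="stable")
    z_perm_ord = z_perm[order]
    stepdown_max = np.maximum.accumulate(z_perm_ord[::-1], axis=0)[::-1]
    exceed = (stepdown_max >= z_obs[order][:, None]).sum(axis=1)
    p_adj_ord = (1 + exceed) / (n_permutations + 1)
    p_adj_ord = np.maximum.accumulate(p_adj_ord)          # enforce monotonicity
    p_adj = np.empty_like(p_adj_ord)
    p_adj[order] = p_adj_ord

    table = pd.DataFrame(
        {"z": z_obs, "p_raw": p_raw, "p_adj": p_adj}, index=df.index
    )
    return ComparisonResult(
        pair=pair if pair is not None else (str(uniq[0]), str(uniq[1])),
        table=table,
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_screen(
    matrix: MatchedMatrix,
    design: CohortDesign,
    rule: SelectionRule = SelectionRule(),
    n_permutations: int = 10_000,
    seed: int = 0,
    treatment: str | None = None,
) -> ScreenResult:
    """Run every pairwise age comparison and apply the consensus rule.

    With three age groups the three pairs (young-middle, young-old,
    middle-old, per the design's declared age order) are screened; a peptide
    is selected when its adjusted p < ``rule.alpha`` in at least
    ``rule.min_comparisons`` pairs.  ``treatment`` restricts screening to one
    treatment arm (e.g. untreated controls).
    """
    ages = list(design.age_order)
    if len(ages) < 2:
        raise AnalysisError("screening requires >= 2 age groups in the design")
    pairs = [(ages[i], ages[j]) for i in range(len(ages)) for j in range(i + 1, len(ages))]
    if rule.min_comparisons > len(pairs):
        raise ConfigurationError(
            f"min_comparisons={rule.min_comparisons} exceeds {len(pairs)} pairs"
        )
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    comparisons: dict[tuple[str, str], ComparisonResult] = {}
    sig_count = pd.Series(0, index=matrix.amplitudes.sort_index().index)
    for pair_idx, (ga, gb) in enumerate(pairs):
        samples = [
            s
            for s in design.samples
            if design.age_group[s] in (ga, gb)
            and (treatment is None or design.treatment[s] == treatment)
        ]
        sub = matrix.amplitudes.loc[:, samples]
        labels = [design.age_group[s] for s in samples]
        pair_seed = int(children[pair_idx].generate_state(1)[0] % (2**31))
        res = maxt_adjust(
            sub, labels, n_permutations=n_permutations, seed=pair_seed, pair=(ga, gb)
        )
        comparisons[(ga, gb)] = res
        sig = res.table["p_adj"] < rule.alpha
        sig_count.loc[sig.index[sig]] += 1
    selected = sorted(sig_count.index[sig_count >= rule.min_comparisons])
    return ScreenResult(
        comparisons=comparisons, selected=selected, rule=rule, counts=sig_count
    )
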