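"""Internal-standard normalization and cross-sample peptide matching.

CE-MS runs drift: migration times warp smoothly from run to run and overall
signal intensity scales with urine concentration.  Both are corrected against
a set of internal polypeptide standards — endogenous peptides reliably
present in every sample:

* migration times are mapped by a monotone piecewise-linear interpolation
  anchored at (detected, reference) standard time pairs, with linear
  extrapolation beyond the outermost anchors;
* amplitudes are rescaled by a single global factor, the median of
  reference/detected amplitude ratios over the standards.

Normalized profiles are then pooled and clustered into master peptides.  Two
observations may be assigned to the same master peptide only when their mass
difference is within a ppm window of the smaller mass — 50 ppm below 4 kDa,
150 ppm above 6 kDa, linearly interpolated between — and their migration
times agree within a tolerance that ramps linearly from 1.0 min at the start
of the run to 2.5 min at the end.  Clustering uses single-linkage semantics:
observations are processed in ascending mass order and any pair satisfying
the joint tolerance predicate links their clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError, ValidationError
from .io import MatchedMatrix, PeptideObservation


@dataclass(frozen=True)
class MatchingParameters:
    """Tolerances governing standard detection and cross-sample matching.

    ``ppm_low``/``ppm_high`` bound the mass window below ``interp_bounds_da[0]``
    and above ``interp_bounds_da[1]``; between the bounds the window ramps
    linearly.  ``mig_tol_min_low``/``mig_tol_min_high`` likewise bound the
    migration-time window across the observed run span.  Master peptides seen
    in fewer than ``presence_threshold`` of samples are dropped.
    """

    ppm_low: float = 50.0
    ppm_high: float = 150.0
    interp_bounds_da: tuple[float, float] = (4000.0, 6000.0)
    mig_tol_min_low: float = 1.0
    mig_tol_min_high: float = 2.5
    presence_threshold: float = 0.3
    standard_time_window_min: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.ppm_low <= self.ppm_high:
            raise ConfigurationError(
                f"need 0 < ppm_low <= ppm_high, got {self.ppm_low}, {self.ppm_high}"
            )
        if not 0 < self.mig_tol_min_low <= self.mig_tol_min_high:
            raise ConfigurationError(
                "need 0 < mig_tol_min_low <= mig_tol_min_high, got "
                f"{self.mig_tol_min_low}, {self.mig_tol_min_high}"
            )
        if not 0 <= self.presence_threshold <= 1:
            raise ConfigurationError(
                f"presence_threshold must be in [0,1], got {self.presence_threshold}"
            )
        lo, hi = self.interp_bounds_da
        if not 0 < lo < hi:
            raise ConfigurationError(f"invalid interp_bounds_da {self.interp_bounds_da}")


@dataclass(frozen=True)
class StandardSet:
    """Reference coordinates of the internal polypeptide standards."""

    mass_da: tuple[float, ...]
    migration_min: tuple[float, ...]
    amplitude: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.mass_da)
        if n < 2:
            raise ConfigurationError("at least 2 internal standards are required")
        if len(self.migration_min) != n or len(self.amplitude) != n:
            raise ConfigurationError("standard field lengths disagree")
        times = np.asarray(self.migration_min)
        if not np.all(np.diff(times) > 0):
            raise ConfigurationError(
                "reference standard migration times must be strictly increasing"
            )

    @property
    def run_span(self) -> tuple[float, float]:
        return (self.migration_min[0], self.migration_min[-1])


def read_standard_set(path) -> StandardSet:
    """Read a reference standard table (mass_da, migration_min, amplitude TSV)."""
    from pathlib import Path

    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    header = lines[0].split("\t")
    for col in ("mass_da", "migration_min", "amplitude"):
        if col not in header:
            raise ConfigurationError(f"{path}: standards file missing column {col!r}")
    im, it, ia = (header.index(c) for c in ("mass_da", "migration_min", "amplitude"))
    rows = [ln.split("\t") for ln in lines[1:]]
    return StandardSet(
        mass_da=tuple(float(r[im]) for r in rows),
        migration_min=tuple(float(r[it]) for r in rows),
        amplitude=tuple(float(r[ia]) for r in rows),
    )


def write_standard_set(standards: StandardSet, path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("mass_da\tmigration_min\tamplitude\n")
        for m, t, a in zip(
            standards.mass_da, standards.migration_min, standards.amplitude
        ):
            fh.write(f"{repr(float(m))}\t{repr(float(t))}\t{repr(float(a))}\n")


def mass_tolerance_ppm(mass_da, params: MatchingParameters = MatchingParameters()):
    """Mass-match window in ppm for a peptide of the given mass.

    Piecewise: ``ppm_low`` below the lower interpolation bound, ``ppm_high``
    above the upper bound, linear in between.  Accepts scalars or arrays.
    """
    mass = np.asarray(mass_da, dtype=float)
    if np.any(mass <= 0):
        raise ValidationError(f"mass_da must be > 0, got {mass_da!r}")
    out = np.interp(mass, params.interp_bounds_da, (params.ppm_low, params.ppm_high))
    return float(out) if np.isscalar(mass_da) else out


def migration_tolerance_min(
    migration_min,
    run_span: tuple[float, float],
    params: MatchingParameters = MatchingParameters(),
):
    """Migration-time tolerance [min] at a given point of the run.

    Ramps linearly from ``mig_tol_min_low`` at the earliest standard to
    ``mig_tol_min_high`` at the latest, clamped outside the span.
    """
    t_min, t_max = run_span
    if not t_max > t_min:
        raise ValidationError(f"degenerate run span {run_span!r}")
    t = np.asarray(migration_min, dtype=float)
    out = np.interp(t, (t_min, t_max), (params.mig_tol_min_low, params.mig_tol_min_high))
    return float(out) if np.isscalar(migration_min) else out


def detect_standards(
    profile: Sequence[PeptideObservation],
    reference: StandardSet,
    params: MatchingParameters = MatchingParameters(),
) -> dict[int, PeptideObservation]:
    """Locate internal standards in a raw profile by mass and coarse position.

    A candidate observation must match a reference standard's mass within the
    ppm window and sit within ``params.standard_time_window_min`` of its
    reference migration time — standards anchor the alignment, so only the
    coarse (pre-normalization) position can be used.  Candidate pairs are
    ranked by relative mass deviation (ties by time deviation) and assigned
    greedily, so one observation never serves two standards.
    """
    pairs = []
    for k, ref_mass in enumerate(reference.mass_da):
        tol = mass_tolerance_ppm(ref_mass, params) * 1e-6 * ref_mass
        for obs in profile:
            dev = abs(obs.mass_da - ref_mass)
            tdev = abs(obs.migration_min - reference.migration_min[k])
            if dev <= tol and tdev <= params.standard_time_window_min:
                pairs.append((dev / ref_mass, tdev, k, obs))
    pairs.sort(key=lambda p: (p[0], p[1], p[2], p[3].local_id))
    found: dict[int, PeptideObservation] = {}
    used: set[str] = set()
    for _, _, k, obs in pairs:
        if k in found or obs.local_id in used:
            continue
        found[k] = obs
        used.add(obs.local_id)
    return found


def normalize_profile(
    profile: Sequence[PeptideObservation],
    reference: StandardSet,
    params: MatchingParameters = MatchingParameters(),
) -> list[PeptideObservation]:
    """Normalize one profile's migration times and amplitudes to the standards.

    Requires at least two standards detectable in the profile; raises
    :class:`NormalizationError` naming the standards that were found
    otherwise.  After normalization the detected standards sit exactly on the
    reference migration times, and the amplitude scale is corrected by the
    median reference/detected ratio.
    """
    found = detect_standards(profile, reference, params)
    if len(found) < 2:
        raise NormalizationError(
            f"only {len(found)} internal standard(s) detected "
            f"(indices {sorted(found)}); >=2 required for alignment"
        )
    ks = sorted(found)
    det_times = np.array([found[k].migration_min for k in ks])
    ref_times = np.array([reference.migration_min[k] for k in ks])
    if not np.all(np.diff(det_times) > 0):
        raise NormalizationError(
            "detected standard migration times are not strictly increasing; "
            "profile cannot be monotonically aligned"
        )
    ratios = [
        reference.amplitude[k] / found[k].amplitude
        for k in ks
        if found[k].amplitude > 0
    ]
    if not ratios:
        raise NormalizationError("all detected standards have zero amplitude")
    factor = float(np.median(ratios))

    def warp(t: float) -> float:
        # piecewise-linear through the anchors, linear extrapolation outside
        if t <= det_times[0]:
            slope = (ref_times[1] - ref_times[0]) / (det_times[1] - det_times[0])
            return float(ref_times[0] + slope * (t - det_times[0]))
        if t >= det_times[-1]:
            slope = (ref_times[-1] - ref_times[-2]) / (det_times[-1] - det_times[-2])
            return float(ref_times[-1] + slope * (t - det_times[-1]))
        return float(np.interp(t, det_times, ref_times))

    out = []
    for obs in profile:
        out.append(
            replace(
                obs,
                migration_min=warp(obs.migration_min),
                amplitude=obs.amplitude * factor,
            )
        )
    return out


def normalize_cohort(
    profiles: Mapping[str, Sequence[PeptideObservation]],
    reference: StandardSet,
    params: MatchingParameters = MatchingParameters(),
) -> dict[str, list[PeptideObservation]]:
    """Normalize every profile of a cohort against the same reference."""
    return {s: normalize_profile(p, reference, params) for s, p in profiles.items()}


# ---------------------------------------------------------------------------
# Cross-sample matching
# ---------------------------------------------------------------------------


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def link_predicate(
    mass_a: float,
    time_a: float,
    mass_b: float,
    time_b: float,
    run_span: tuple[float, float],
    params: MatchingParameters = MatchingParameters(),
) -> bool:
    """True iff two observations may share a master peptide.

    The ppm window is anchored at the smaller of the two masses; the
    migration tolerance is evaluated at the midpoint of the two times.
    """
    small = min(mass_a, mass_b)
    if abs(mass_a - mass_b) > mass_tolerance_ppm(small, params) * 1e-6 * small:
        return False
    tol_t = migration_tolerance_min(0.5 * (time_a + time_b), run_span, params)
    return abs(time_a - time_b) <= tol_t


def match_profiles(
    profiles: Mapping[str, Sequence[PeptideObservation]],
    params: MatchingParameters = MatchingParameters(),
    reference: StandardSet | None = None,
    run_span: tuple[float, float] | None = None,
) -> MatchedMatrix:
    """Cluster normalized profiles into a master peptide x sample matrix.

    Observations from all samples are pooled and clustered with
    single-linkage semantics under :func:`link_predicate`.  Within a cluster
    each sample contributes at most one observation (closest in mass to the
    cluster consensus wins; ties break on time, then local id).  Clusters
    present in fewer than ``params.presence_threshold`` of the samples are
    dropped.  Master ids are integers 1..K in ascending consensus-mass order.

    ``run_span`` defaults to the reference standards' span if ``reference``
    is given, else to the pooled observed time range.  When ``reference`` is
    supplied, each profile is additionally checked to contain its standards
    on the reference coordinates (i.e. to have been normalized).
    """
    sample_ids = list(profiles.keys())
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValidationError("no profiles to match")

    if reference is not None:
        for sid in sample_ids:
            found = detect_standards(profiles[sid], reference, params)
            if len(found) < 2:
                raise NormalizationError(
                    f"profile {sid!r} appears unnormalized: only {len(found)} "
                    "internal standard(s) found near reference coordinates"
                )
            for k, obs in found.items():
                if abs(obs.migration_min - reference.migration_min[k]) > 1e-6:
                    raise NormalizationError(
                        f"profile {sid!r} appears unnormalized: standard {k} at "
                        f"{obs.migration_min:.3f} min vs reference "
                        f"{reference.migration_min[k]:.3f} min"
                    )

    mass, time, amp = [], [], []
    sample_idx, local_ids = [], []
    for si, sid in enumerate(sample_ids):
        for obs in profiles[sid]:
            mass.append(obs.mass_da)
            time.append(obs.migration_min)
            amp.append(obs.amplitude)
            sample_idx.append(si)
            local_ids.append(obs.local_id)
    mass = np.asarray(mass)
    time = np.asarray(time)
    amp = np.asarray(amp)
    sample_idx = np.asarray(sample_idx)
    n = len(mass)
    if n == 0:
        empty = pd.DataFrame(
            {"mass_da": [], "migration_min": []}, index=pd.Index([], name="master_id")
        )
        return MatchedMatrix(empty, pd.DataFrame(index=empty.index, columns=sample_ids, dtype=float))

    if run_span is None:
        run_span = reference.run_span if reference is not None else (
            float(time.min()), float(time.max()))
        if run_span[1] <= run_span[0]:
            run_span = (run_span[0], run_span[0] + 1.0)

    # deterministic processing order: ascending mass, then time, sample, id
    order = np.lexsort((np.asarray(local_ids, dtype=object), sample_idx, time, mass))
    m, t = mass[order], time[order]

    tol_da = mass_tolerance_ppm(m, params) * 1e-6 * m
    hi = np.searchsorted(m, m + tol_da, side="right")
    counts = hi - np.arange(n) - 1
    ii = np.repeat(np.arange(n), counts)
    jj = np.concatenate([np.arange(i + 1, h) for i, h in zip(np.arange(n), hi)]) if n else np.array([], int)
    if ii.size:
        mid_t = 0.5 * (t[ii] + t[jj])
        tol_t = migration_tolerance_min(mid_t, run_span, params)
        keep = np.abs(t[ii] - t[jj]) <= tol_t
        ii, jj = ii[keep], jj[keep]

    uf = _UnionFind(n)
    for i, j in zip(ii.tolist(), jj.tolist()):
        uf.union(i, j)

    roots = np.array([uf.find(i) for i in range(n)])
    clusters: dict[int, list[int]] = {}
    for pos, r in enumerate(roots):
        clusters.setdefault(int(r), []).append(pos)

    s_sorted = sample_idx[order]
    a_sorted = amp[order]
    l_sorted = [local_ids[k] for k in order]

    kept_clusters = []
    n_dedup_dropped = 0
    for members in clusters.values():
        mem = np.asarray(members)
        w = a_sorted[mem]
        wsum = w.sum()
        if wsum > 0:
            cons_mass = float(np.average(m[mem], weights=w))
            cons_time = float(np.average(t[mem], weights=w))
        else:
            cons_mass = float(m[mem].mean())
            cons_time = float(t[mem].mean())
        # one observation per sample: closest in mass to the consensus
        best: dict[int, int] = {}
        for k in members:
            key = (abs(m[k] - cons_mass), abs(t[k] - cons_time), l_sorted[k])
            cur = best.get(int(s_sorted[k]))
            if cur is None or key < (abs(m[cur] - cons_mass), abs(t[cur] - cons_time), l_sorted[cur]):
                best[int(s_sorted[k])] = k
        kept = sorted(best.values())
        n_dedup_dropped += len(members) - len(kept)
        km = np.asarray(kept)
        w = a_sorted[km]
        if w.sum() > 0:
            cons_mass = float(np.average(m[km], weights=w))
            cons_time = float(np.average(t[km], weights=w))
        else:
            cons_mass = float(m[km].mean())
            cons_time = float(t[km].mean())
        kept_clusters.append((cons_mass, cons_time, kept))

    # presence filter and stable master ids in ascending consensus mass
    kept_clusters.sort(key=lambda c: (c[0], c[1]))
    rows = []
    n_presence_dropped = 0
    for cons_mass, cons_time, kept in kept_clusters:
        present = len({int(s_sorted[k]) for k in kept})
        if present / n_samples < params.presence_threshold:
            n_presence_dropped += len(kept)
            continue
        rows.append((cons_mass, cons_time, kept))

    ids = pd.Index(range(1, len(rows) + 1), name="master_id")
    peptides = pd.DataFrame(
        {
            "mass_da": [r[0] for r in rows],
            "migration_min": [r[1] for r in rows],
        },
        index=ids,
    )
    data = np.full((len(rows), n_samples), np.nan)
    for ri, (_, _, kept) in enumerate(rows):
        for k in kept:
            data[ri, int(s_sorted[k])] = a_sorted[k]
    amplitudes = pd.DataFrame(data, index=ids, columns=sample_ids)
    partition = sorted(
        sorted((sample_ids[int(s_sorted[k])], l_sorted[k]) for k in members)
        for members in clusters.values()
    )
    stats = {
        "n_observations": int(n),
        "n_assigned": int(n - n_dedup_dropped - n_presence_dropped),
        "n_dropped_duplicate_in_sample": int(n_dedup_dropped),
        "n_dropped_presence_threshold": int(n_presence_dropped),
        "n_master_peptides": len(rows),
        # single-linkage partition of all pooled observations, before the
        # per-sample dedup and presence filter (for audits and oracles)
        "partition": partition,
    }
    return MatchedMatrix(peptides=peptides, amplitudes=amplitudes, match_stats=stats)
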