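"""Synthetic CE-MS cohorts with known planted structure.

The generator emulates a mouse urinary-peptidome aging study: three age
groups with ~13 animals each, an optional treated arm, a master list of a
few hundred peptides, five internal-standard peptides present in every
sample, log-normal amplitudes, an age-dependent fold change planted on a
subset of peptides, ppm-scale mass jitter, a smooth monotone-quadratic
migration-time distortion per sample, a per-sample global intensity scale,
and missing-at-random dropout.  Every quantity needed to judge downstream
stages — which peptides carry an age effect and with what sign, the true
per-group means, the per-sample warp — is returned as :class:`GroundTruth`.

Master peptides are drawn so that no two are simultaneously within (a
generous multiple of) the matching mass window and the migration-time
window; planted identities are then well defined under the matching
tolerances and a noise-free cohort reconstructs exactly.

Also generated here: qPCR Ct tables consistent with the contamination-
corrected expression formula, and per-slide glomerulus area samples for the
stereological volume estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import MatchingParameters, StandardSet, mass_tolerance_ppm
from .errors import ConfigurationError
from .io import CohortDesign, MatchedMatrix, PeptideObservation


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference design: 3 age groups x 13 animals, ~200
    master peptides of 0.8-8 kDa migrating over 19-45 min, 5 internal
    standards, 10 peptides with a planted per-age-step log2 fold change of
    2, 15 ppm mass jitter, a mild per-sample migration warp and intensity
    scale, and 10% missing-at-random dropout.
    """

    n_per_group: int = 13
    age_groups: tuple[str, ...] = ("young", "middle", "old")
    treatments: tuple[str, ...] = ("control",)
    n_master_peptides: int = 200
    n_affected: int = 10
    effect_log2fc: float = 2.0
    treatment_age_shift: float = 0.0
    n_standards: int = 5
    mass_range_da: tuple[float, float] = (800.0, 8000.0)
    migration_range_min: tuple[float, float] = (19.0, 45.0)
    mass_jitter_ppm: float = 15.0
    migration_warp_scale: float = 1.0
    dropout_rate: float = 0.1
    amplitude_sd_log: float = 1.0
    amplitude_mean_log: float = 10.0
    amplitude_between_sd_log: float = 2.0
    sample_scale_sd_log: float = 0.5
    intensity_dependent_dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(fieldname, msg):
            raise ConfigurationError(f"{fieldname}: {msg}")

        if self.n_per_group < 1:
            bad("n_per_group", f"must be >= 1, got {self.n_per_group}")
        if len(self.age_groups) < 1:
            bad("age_groups", "needs at least one label")
        if len(self.treatments) < 1:
            bad("treatments", "needs at least one label")
        if self.n_master_peptides < 1:
            bad("n_master_peptides", f"must be >= 1, got {self.n_master_peptides}")
        if not 0 <= self.n_affected <= self.n_master_peptides:
            bad("n_affected", "must satisfy 0 <= n_affected <= n_master_peptides")
        if self.n_standards < 2:
            bad("n_standards", "at least 2 standards are needed for alignment")
        if not 0 < self.mass_range_da[0] < self.mass_range_da[1]:
            bad("mass_range_da", f"invalid range {self.mass_range_da}")
        if not 0 < self.migration_range_min[0] < self.migration_range_min[1]:
            bad("migration_range_min", f"invalid range {self.migration_range_min}")
        if self.mass_jitter_ppm < 0:
            bad("mass_jitter_ppm", "must be >= 0")
        if self.migration_warp_scale < 0:
            bad("migration_warp_scale", "must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            bad("dropout_rate", f"must be in [0,1), got {self.dropout_rate}")
        if self.amplitude_sd_log < 0:
            bad("amplitude_sd_log", "must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort.

    ``effect_sign`` maps each affected peptide index to +/-1 (direction of
    the planted per-age-step log2 fold change); ``group_mean_log2`` is the
    true mean log2 amplitude of every master peptide in every age group of
    the untreated arm; ``warp_coeffs`` holds the per-sample quadratic
    distortion (c0, c1, a) applied around the run midpoint.
    """

    master_mass_da: np.ndarray
    master_migration_min: np.ndarray
    base_log2_amplitude: np.ndarray
    standard_ids: list[int]
    affected_ids: list[int]
    effect_sign: dict[int, int]
    effect_log2fc: float
    group_mean_log2: np.ndarray          # n_master x n_age_groups
    warp_coeffs: dict[str, tuple[float, float, float]]
    sample_scale_log2: dict[str, float]
    config: SimulationConfig = field(repr=False, default=None)

    def to_json(self) -> str:
        payload = {
            "master_mass_da": [float(v) for v in self.master_mass_da],
            "master_migration_min": [float(v) for v in self.master_migration_min],
            "base_log2_amplitude": [float(v) for v in self.base_log2_amplitude],
            "standard_ids": list(self.standard_ids),
            "affected_ids": list(self.affected_ids),
            "effect_sign": {str(k): int(v) for k, v in self.effect_sign.items()},
            "effect_log2fc": self.effect_log2fc,
            "group_mean_log2": [[float(v) for v in row] for row in self.group_mean_log2],
            "warp_coeffs": {k: [float(x) for x in v] for k, v in self.warp_coeffs.items()},
            "sample_scale_log2": {k: float(v) for k, v in self.sample_scale_log2.items()},
            "config": asdict(self.config) if self.config is not None else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _draw_separated_peptides(rng, config: SimulationConfig, params: MatchingParameters):
    """Master (mass, time) pairs resolvable under the matching tolerances.

    Rejection sampling: a candidate is rejected when an existing peptide is
    simultaneously within 3x its ppm window (plus jitter allowance) in mass
    and within 2x the maximum migration tolerance (plus warp allowance) in
    time, so no pair can merge — even transitively — after jitter and warp.
    """
    lo_m, hi_m = config.mass_range_da
    lo_t, hi_t = config.migration_range_min
    time_margin = 2 * params.mig_tol_min_high + 4 * config.migration_warp_scale
    masses: list[float] = []
    times: list[float] = []

    # standards first: evenly spaced across the migration range interior
    std_times = np.linspace(lo_t, hi_t, config.n_standards + 2)[1:-1]
    std_masses = np.linspace(lo_m * 1.05, hi_m * 0.95, config.n_standards)
    for m, t in zip(std_masses, std_times):
        masses.append(float(m))
        times.append(float(t))

    n_needed = config.n_master_peptides
    attempts = 0
    while len(masses) < config.n_standards + n_needed:
        attempts += 1
        if attempts > 200 * n_needed + 1000:
            raise ConfigurationError(
                "n_master_peptides: too many peptides for the configured mass/"
                "migration ranges to keep them resolvable"
            )
        m = float(rng.uniform(lo_m, hi_m))
        t = float(rng.uniform(lo_t, hi_t))
        ok = True
        for m0, t0 in zip(masses, times):
            small = min(m, m0)
            mass_margin = (
                3 * mass_tolerance_ppm(small, params) + 10 * config.mass_jitter_ppm
            ) * 1e-6 * small
            if abs(m - m0) <= mass_margin and abs(t - t0) <= time_margin:
                ok = False
                break
        if ok:
            masses.append(m)
            times.append(t)
    return np.asarray(masses), np.asarray(times)


def reference_standards(config: SimulationConfig) -> StandardSet:
    """The reference :class:`StandardSet` implied by a configuration."""
    lo_t, hi_t = config.migration_range_min
    lo_m, hi_m = config.mass_range_da
    std_times = np.linspace(lo_t, hi_t, config.n_standards + 2)[1:-1]
    std_masses = np.linspace(lo_m * 1.05, hi_m * 0.95, config.n_standards)
    amp = 2.0 ** (config.amplitude_mean_log + 2.0)
    return StandardSet(
        mass_da=tuple(float(m) for m in std_masses),
        migration_min=tuple(float(t) for t in std_times),
        amplitude=tuple(float(amp) for _ in std_masses),
    )


def generate_cohort(
    config: SimulationConfig,
    params: MatchingParameters = MatchingParameters(),
) -> tuple[dict[str, list[PeptideObservation]], CohortDesign, GroundTruth]:
    """Generate per-sample peptide lists with planted age structure.

    Returns ``(profiles, design, truth)``.  Profiles are keyed by sample id
    in design order; every profile contains all internal standards (warped
    and jittered like any other peptide, but never dropped and with no
    intra-sample amplitude noise beyond the global sample scale).  Affected
    peptides shift their mean log2 amplitude by ``effect_log2fc`` (with a
    per-peptide sign) per age step; treated arms additionally shift the
    effective age of affected peptides by ``treatment_age_shift`` age steps.
    Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    masses, times = _draw_separated_peptides(rng, config, params)
    n_std = config.n_standards
    n_all = len(masses)
    standard_ids = list(range(n_std))
    peptide_ids = list(range(n_std, n_all))

    ref = reference_standards(config)
    base_log2 = np.empty(n_all)
    base_log2[:n_std] = np.log2(ref.amplitude)
    base_log2[n_std:] = rng.normal(
        config.amplitude_mean_log, config.amplitude_between_sd_log, n_all - n_std
    )

    affected = sorted(
        rng.choice(peptide_ids, size=config.n_affected, replace=False).tolist()
    )
    signs = {int(i): int(s) for i, s in zip(affected, rng.choice([-1, 1], size=len(affected)))}

    ages = list(config.age_groups)
    effect = np.zeros(n_all)
    for i in affected:
        effect[i] = signs[i] * config.effect_log2fc
    group_mean = base_log2[:, None] + effect[:, None] * np.arange(len(ages))[None, :]

    t_mid = 0.5 * sum(config.migration_range_min)
    half_span = 0.5 * (config.migration_range_min[1] - config.migration_range_min[0])

    samples: list[str] = []
    age_of: dict[str, str] = {}
    treat_of: dict[str, str] = {}
    profiles: dict[str, list[PeptideObservation]] = {}
    warps: dict[str, tuple[float, float, float]] = {}
    scales: dict[str, float] = {}

    idx = 0
    for age_i, age in enumerate(ages):
        for treat in config.treatments:
            for _ in range(config.n_per_group):
                idx += 1
                sid = f"S{idx:03d}"
                samples.append(sid)
                age_of[sid] = age
                treat_of[sid] = treat

                w = config.migration_warp_scale
                c0 = float(np.clip(rng.normal(0.0, 0.6 * w), -2 * w, 2 * w))
                c1 = float(np.clip(rng.normal(0.0, 0.04 * w), -0.12, 0.12))
                a = float(
                    np.clip(rng.normal(0.0, 0.015 * w), -0.045, 0.045) / max(half_span, 1e-9)
                )
                warps[sid] = (c0, c1, a)
                scale = float(rng.normal(0.0, config.sample_scale_sd_log))
                scales[sid] = scale

                eff_age = age_i + (
                    config.treatment_age_shift if treat != config.treatments[0] else 0.0
                )
                log2amp = base_log2 + effect * eff_age + scale
                noise = rng.normal(0.0, config.amplitude_sd_log, n_all)
                noise[:n_std] = 0.0  # standards are high-abundance and stable
                log2amp = log2amp + noise

                jitter = rng.normal(0.0, config.mass_jitter_ppm * 1e-6, n_all)
                obs_mass = masses * (1.0 + jitter)
                dt = times - t_mid
                obs_time = times + c0 + c1 * dt + a * dt**2

                drop = rng.random(n_all) < config.dropout_rate
                if config.intensity_dependent_dropout:
                    # low-abundance peptides drop preferentially (stress mode)
                    q = pd.Series(log2amp).rank(pct=True).to_numpy()
                    drop = rng.random(n_all) < config.dropout_rate * 2 * (1 - q)
                drop[:n_std] = False  # standards are never dropped

                keep = np.flatnonzero(~drop)
                order = keep[np.argsort(obs_time[keep], kind="stable")]
                prof = [
                    PeptideObservation(
                        local_id=f"p{k:04d}",
                        mass_da=float(obs_mass[i]),
                        migration_min=float(obs_time[i]),
                        amplitude=float(2.0 ** log2amp[i]),
                    )
                    for k, i in enumerate(order)
                ]
                profiles[sid] = prof

    design = CohortDesign(
        samples=tuple(samples),
        age_group=age_of,
        treatment=treat_of,
        age_order=tuple(ages),
    )
    truth = GroundTruth(
        master_mass_da=masses,
        master_migration_min=times,
        base_log2_amplitude=base_log2,
        standard_ids=standard_ids,
        affected_ids=[int(i) for i in affected],
        effect_sign=signs,
        effect_log2fc=config.effect_log2fc,
        group_mean_log2=group_mean,
        warp_coeffs=warps,
        sample_scale_log2=scales,
        config=config,
    )
    return profiles, design, truth


def match_truth_to_matrix(
    truth: GroundTruth,
    matrix: MatchedMatrix,
    params: MatchingParameters = MatchingParameters(),
) -> dict[int, int]:
    """Map planted master-peptide indices to matrix master ids by mass.

    For each planted peptide the matrix master peptide closest in consensus
    mass within the ppm tolerance (and within the high migration tolerance in
    time) is taken; unmatched planted peptides are absent from the result.
    """
    out: dict[int, int] = {}
    cons_mass = matrix.peptides["mass_da"].to_numpy()
    cons_time = matrix.peptides["migration_min"].to_numpy()
    ids = np.asarray(matrix.master_ids)
    for i, (m, t) in enumerate(zip(truth.master_mass_da, truth.master_migration_min)):
        tol = mass_tolerance_ppm(m, params) * 1e-6 * m
        cand = np.flatnonzero(
            (np.abs(cons_mass - m) <= tol)
            & (np.abs(cons_time - t) <= params.mig_tol_min_high)
        )
        if cand.size:
            best = cand[np.argmin(np.abs(cons_mass[cand] - m))]
            out[i] = int(ids[best])
    return out


# ---------------------------------------------------------------------------
# qPCR and glomerulus generators
# ---------------------------------------------------------------------------


def generate_qpcr_table(
    n_samples: int,
    true_expression_levels,
    contamination_offset: float = np.inf,
    ct_gapdh_mean: float = 20.0,
    sd_ct: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct triples whose noise-free expression recovers the planted levels.

    ``ct_gene`` is set to ``ct_gapdh - log2(expression)``; ``ct_rt_minus``
    sits ``contamination_offset`` cycles above ``ct_gene`` (infinite offset =
    no contamination signal, column NaN).  Gaussian Ct noise of ``sd_ct``
    cycles is added independently to gene and GAPDH wells.
    """
    if n_samples < 1:
        raise ConfigurationError(f"n_samples must be >= 1, got {n_samples}")
    expr = np.broadcast_to(
        np.asarray(true_expression_levels, dtype=float), (n_samples,)
    ).copy()
    if np.any(expr <= 0):
        raise ConfigurationError(
            f"true_expression_levels must be > 0, got {true_expression_levels!r}"
        )
    if contamination_offset < 0:
        raise ConfigurationError(
            f"contamination_offset must be >= 0, got {contamination_offset}"
        )
    rng = np.random.default_rng(seed)
    ct_gapdh = ct_gapdh_mean + rng.normal(0.0, sd_ct, n_samples)
    ct_gene = ct_gapdh_mean - np.log2(expr) + rng.normal(0.0, sd_ct, n_samples)
    if np.isinf(contamination_offset):
        ct_rt = np.full(n_samples, np.nan)
    else:
        ct_rt = ct_gene + contamination_offset
    return pd.DataFrame(
        {"ct_gene": ct_gene, "ct_gapdh": ct_gapdh, "ct_rt_minus": ct_rt}
    )


def generate_glomeruli(
    n: int, mean_area_um2: float = 5000.0, sd_area: float = 1500.0, seed: int = 0
) -> np.ndarray:
    """Per-slide glomerulus profile areas [um^2], gamma-distributed.

    The gamma family keeps areas positive with the requested mean and
    standard deviation; ``sd_area = 0`` gives a degenerate constant sample.
    """
    if n <= 0:
        raise ConfigurationError(f"n must be > 0, got {n}")
    if mean_area_um2 <= 0:
        raise ConfigurationError(f"mean_area_um2 must be > 0, got {mean_area_um2}")
    if sd_area < 0:
        raise ConfigurationError(f"sd_area must be >= 0, got {sd_area}")
    rng = np.random.default_rng(seed)
    if sd_area == 0:
        return np.full(n, float(mean_area_um2))
    shape = (mean_area_um2 / sd_area) ** 2
    scale = sd_area**2 / mean_area_um2
    return rng.gamma(shape, scale, n)
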