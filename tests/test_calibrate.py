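"""Tolerance rules, internal-standard normalization, and matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pepage as pp
from pepage.calibrate import link_predicate
from pepage.errors import NormalizationError, ValidationError
from pepage.io import PeptideObservation

from _oracles import brute_force_partition

PARAMS = pp.MatchingParameters()


class TestToleranceRules:
    @pytest.mark.parametrize(
        "mass,expected",
        [(2000.0, 50.0), (3999.0, 50.0), (5000.0, 100.0), (6001.0, 150.0), (8000.0, 150.0)],
    )
    def test_mass_tolerance_regimes(self, mass, expected):
        assert pp.mass_tolerance_ppm(mass, PARAMS) == pytest.approx(expected)

    def test_mass_tolerance_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            pp.mass_tolerance_ppm(0.0, PARAMS)

    @pytest.mark.parametrize(
        "t,expected", [(20.0, 1.0), (45.0, 2.5), (32.5, 1.75), (10.0, 1.0), (60.0, 2.5)]
    )
    def test_migration_tolerance_ramp(self, t, expected):
        assert pp.migration_tolerance_min(t, (20.0, 45.0), PARAMS) == pytest.approx(expected)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValidationError):
            pp.migration_tolerance_min(20.0, (20.0, 20.0), PARAMS)

    @settings(deadline=None, max_examples=50)
    @given(mass=st.floats(1.0, 50000.0, allow_nan=False))
    def test_mass_tolerance_monotone_and_bounded(self, mass):
        tol = pp.mass_tolerance_ppm(mass, PARAMS)
        assert PARAMS.ppm_low <= tol <= PARAMS.ppm_high


def _standards():
    return pp.StandardSet(
        mass_da=(1000.0, 3000.0, 5000.0),
        migration_min=(22.0, 30.0, 42.0),
        amplitude=(100.0, 100.0, 100.0),
    )


def _profile_from(masses, times, amps):
    return [
        PeptideObservation(f"p{i}", m, t, a)
        for i, (m, t, a) in enumerate(zip(masses, times, amps))
    ]


class TestNormalizeProfile:
    def test_profile_on_reference_is_unchanged(self):
        ref = _standards()
        prof = _profile_from([1000.0, 3000.0, 5000.0, 2000.0],
                             [22.0, 30.0, 42.0, 26.0],
                             [100.0, 100.0, 100.0, 55.0])
        out = pp.normalize_profile(prof, ref, PARAMS)
        for a, b in zip(out, prof):
            assert a.migration_min == pytest.approx(b.migration_min, abs=1e-12)
            assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)

    def test_affine_distortion_is_exactly_inverted(self):
        ref = _standards()
        # all times shifted +2.0 min, all amplitudes halved
        prof = _profile_from([1000.0, 3000.0, 5000.0, 2000.0],
                             [24.0, 32.0, 44.0, 28.0],
                             [50.0, 50.0, 50.0, 27.5])
        out = pp.normalize_profile(prof, ref, PARAMS)
        assert out[0].migration_min == pytest.approx(22.0, abs=1e-9)
        assert out[1].migration_min == pytest.approx(30.0, abs=1e-9)
        assert out[2].migration_min == pytest.approx(42.0, abs=1e-9)
        assert out[3].migration_min == pytest.approx(26.0, abs=1e-9)
        for o in out[:3]:
            assert o.amplitude == pytest.approx(100.0, abs=1e-9)
        assert out[3].amplitude == pytest.approx(55.0, abs=1e-9)

    def test_quadratic_warp_standards_land_on_reference(self, default_cohort):
        config, profiles, design, truth = default_cohort
        ref = pp.reference_standards(config)
        sq_err, n = 0.0, 0
        for sid in design.samples:
            out = pp.normalize_profile(profiles[sid], ref, PARAMS)
            from pepage.calibrate import detect_standards
            found = detect_standards(out, ref, PARAMS)
            for k, obs in found.items():
                sq_err += (obs.migration_min - ref.migration_min[k]) ** 2
                n += 1
        assert n >= 2 * len(design.samples)
        assert np.sqrt(sq_err / n) < 0.01

    def test_too_few_standards_lists_found(self):
        ref = _standards()
        prof = _profile_from([1000.0], [22.0], [100.0])
        with pytest.raises(NormalizationError, match="1 internal standard"):
            pp.normalize_profile(prof, ref, PARAMS)


class TestMatchProfiles:
    def test_within_tolerance_pair_shares_master(self):
        profiles = {
            "s1": _profile_from([2000.00], [25.0], [10.0]),
            "s2": _profile_from([2000.05], [25.3], [12.0]),  # 25 ppm, 0.3 min
        }
        mat = pp.match_profiles(profiles, PARAMS, run_span=(20.0, 45.0))
        assert mat.n_peptides == 1
        assert not mat.amplitudes.isna().any().any()

    def test_beyond_tolerance_pair_splits(self):
        profiles = {
            "s1": _profile_from([2000.00], [25.0], [10.0]),
            "s2": _profile_from([2000.30], [25.3], [12.0]),  # 150 ppm > 50 ppm
        }
        params = pp.MatchingParameters(presence_threshold=0.0)
        mat = pp.match_profiles(profiles, params, run_span=(20.0, 45.0))
        assert mat.n_peptides == 2

    def test_greedy_equals_brute_force_single_linkage(self):
        params = pp.MatchingParameters(presence_threshold=0.0)
        run_span = (20.0, 45.0)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n_obs = int(rng.integers(5, 31))
            n_samp = int(rng.integers(2, 5))
            profiles = {f"s{k}": [] for k in range(n_samp)}
            for i in range(n_obs):
                sid = f"s{rng.integers(n_samp)}"
                mass = float(
                    rng.choice([2000, 2000.05, 2000.2, 5000, 5000.3, 7000, 7001])
                    + rng.normal(0, 0.15)
                )
                t = float(rng.uniform(20, 45))
                profiles[sid].append(
                    PeptideObservation(f"o{i}", mass, t, float(rng.uniform(1, 100)))
                )
            oracle = brute_force_partition(profiles, params, run_span)
            mat = pp.match_profiles(profiles, params, run_span=run_span)
            ours = {frozenset(c) for c in mat.match_stats["partition"]}
            assert ours == oracle

    def test_matching_is_sample_order_invariant(self):
        config = pp.SimulationConfig(n_per_group=3, n_master_peptides=40, seed=5)
        profiles, design, _ = pp.generate_cohort(config)
        ref = pp.reference_standards(config)
        norm = pp.normalize_cohort(profiles, ref)
        mat1 = pp.match_profiles(norm, PARAMS, reference=ref)
        shuffled = {k: norm[k] for k in reversed(list(norm))}
        mat2 = pp.match_profiles(shuffled, PARAMS, reference=ref)
        assert mat1.peptides.equals(mat2.peptides)
        assert mat1.amplitudes.equals(mat2.amplitudes[mat1.sample_ids])

    def test_observation_counts_reconcile(self, matched_default_cohort):
        _, mat, _, _ = matched_default_cohort
        s = mat.match_stats
        assert (
            s["n_assigned"]
            + s["n_dropped_duplicate_in_sample"]
            + s["n_dropped_presence_threshold"]
            == s["n_observations"]
        )
        assert s["n_assigned"] == int(mat.amplitudes.notna().sum().sum())

    def test_noise_free_cohort_reconstructs_exactly(self):
        config = pp.SimulationConfig(
            n_per_group=3, n_master_peptides=50, dropout_rate=0.0,
            mass_jitter_ppm=0.0, migration_warp_scale=0.0,
            sample_scale_sd_log=0.0, seed=2,
        )
        profiles, design, truth = pp.generate_cohort(config)
        ref = pp.reference_standards(config)
        mat = pp.match_profiles(pp.normalize_cohort(profiles, ref), reference=ref)
        assert mat.n_peptides == config.n_master_peptides + config.n_standards
        assert not mat.amplitudes.isna().any().any()

    def test_unnormalized_profiles_rejected(self):
        config = pp.SimulationConfig(n_per_group=2, n_master_peptides=20,
                                     migration_warp_scale=3.0, seed=4)
        profiles, _, _ = pp.generate_cohort(config)
        ref = pp.reference_standards(config)
        with pytest.raises(NormalizationError, match="unnormalized"):
            pp.match_profiles(profiles, PARAMS, reference=ref)

    def test_link_predicate_is_symmetric(self):
        span = (20.0, 45.0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            m1, m2 = rng.uniform(900, 8000, 2)
            t1, t2 = rng.uniform(20, 45, 2)
            assert link_predicate(m1, t1, m2, t2, span, PARAMS) == link_predicate(
                m2, t2, m1, t1, span, PARAMS
            )
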