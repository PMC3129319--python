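"""Tests for protocol handling, simulation, sampling and assay noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from practident import (
    NGT,
    BolusEvent,
    add_noise,
    disst_protocol,
    sample_profile,
    simulate,
)
from practident import TestProtocol as Protocol  # alias: pytest must not collect it

#: SD of a standard normal truncated to |z| <= 3
TRUNC3_SD = 0.9866101
MU_PER_U = 1000.0


class TestProtocolValidation:
    def test_samples_must_start_at_zero(self):
        with pytest.raises(ValueError):
            disst_protocol(sample_times=(5.0, 10.0))

    def test_duplicate_sample_times_rejected(self):
        with pytest.raises(ValueError):
            disst_protocol(sample_times=(0.0, 5.0, 5.0, 10.0))

    def test_samples_within_duration(self):
        with pytest.raises(ValueError):
            disst_protocol(sample_times=(0.0, 90.0))

    def test_standard_protocol_layout(self, prot5):
        assert prot5.duration == 60.0
        assert len(prot5.sample_times) == 13
        species = {b.species: b.time for b in prot5.boluses}
        assert species == {"glucose": 7.5, "insulin": 17.5}

    def test_alternative_schedules_need_no_code_change(self):
        for times in ((0, 15, 20, 60), (0, 5, 45, 60)):
            p = disst_protocol(sample_times=times)
            assert p.sample_times == tuple(float(t) for t in times)


class TestSimulate:
    def test_flat_at_basal_without_boluses(self):
        quiet = Protocol(duration=60.0, boluses=(), sample_times=(0.0, 30.0, 60.0))
        sec = NGT.secretion
        from dataclasses import replace

        basal_sec = replace(sec, U1=sec.Ub, U2=sec.Ub)
        prof = simulate(NGT.kin, basal_sec, NGT.pd, quiet)
        assert np.allclose(prof.I, prof.basal.I, rtol=1e-9)
        assert np.allclose(prof.G, NGT.pd.Gb, rtol=1e-9)

    def test_insulin_bolus_is_instantaneous_jump(self, ngt_profiles):
        g = ngt_profiles.grid
        at = np.flatnonzero(g == 17.5)
        assert len(at) == 2  # pre- and post-bolus value at the same abscissa
        jump = ngt_profiles.I[at[1]] - ngt_profiles.I[at[0]]
        assert jump == pytest.approx(1.0 * MU_PER_U / NGT.kin.VP, rel=1e-12)
        # glucose is unaffected instantaneously by the insulin bolus
        assert ngt_profiles.G[at[1]] == ngt_profiles.G[at[0]]

    def test_glucose_returns_below_basal_late_in_test(self, ngt_profiles):
        late = ngt_profiles.grid > 40
        assert ngt_profiles.G[late].min() < NGT.pd.Gb

    def test_profiles_nonnegative(self, ngt_profiles):
        assert ngt_profiles.I.min() >= 0
        assert ngt_profiles.Q.min() >= 0
        assert ngt_profiles.G.min() >= 0

    def test_grid_convergence_on_halving(self, prot5):
        a = simulate(NGT.kin, NGT.secretion, NGT.pd, prot5, grid_step=0.1)
        b = simulate(NGT.kin, NGT.secretion, NGT.pd, prot5, grid_step=0.05)
        times = np.asarray(prot5.sample_times)
        for species in ("insulin", "glucose"):
            va, vb = a.interp(species, times), b.interp(species, times)
            assert np.max(np.abs(va - vb) / np.abs(vb)) < 1e-4


class TestSampling:
    def test_grid_points_sampled_exactly(self, ngt_profiles, prot5):
        s = sample_profile(ngt_profiles, prot5.sample_times, "insulin")
        idx = np.searchsorted(ngt_profiles.grid, s.times, side="right") - 1
        assert np.allclose(s.values, ngt_profiles.I[idx])

    def test_midpoint_of_linear_segment_is_mean(self, ngt_profiles):
        # between two adjacent grid points interpolation is exactly linear
        g = ngt_profiles.grid
        i = np.flatnonzero(np.diff(g) > 0)[5]
        mid = 0.5 * (g[i] + g[i + 1])
        s = sample_profile(ngt_profiles, [0.0, mid], "glucose")
        assert s.values[1] == pytest.approx(0.5 * (ngt_profiles.G[i] + ngt_profiles.G[i + 1]))

    def test_time_outside_grid_rejected(self, ngt_profiles):
        with pytest.raises(ValueError):
            sample_profile(ngt_profiles, [0.0, 61.0])


class TestAddNoise:
    def test_eps_zero_identity(self, ngt_profiles, prot5, rng):
        s = sample_profile(ngt_profiles, prot5.sample_times, "insulin")
        out = add_noise(s, 0.0, rng)
        assert np.array_equal(out.values, s.values)

    def test_negative_eps_rejected(self, ngt_profiles, prot5, rng):
        s = sample_profile(ngt_profiles, prot5.sample_times, "insulin")
        with pytest.raises(ValueError):
            add_noise(s, -0.1, rng)

    def test_same_seed_bit_reproducible_different_seed_not(self, ngt_profiles, prot5):
        s = sample_profile(ngt_profiles, prot5.sample_times, "insulin")
        a = add_noise(s, 0.035, 1234)
        b = add_noise(s, 0.035, 1234)
        c = add_noise(s, 0.035, 1235)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_truncation_bound(self, ngt_profiles, prot5):
        s = sample_profile(ngt_profiles, prot5.sample_times, "insulin")
        for seed in range(50):
            out = add_noise(s, 0.2, seed)
            assert np.all(out.values >= s.values * (1 - 3 * 0.2) - 1e-12)
            assert np.all(out.values <= s.values * (1 + 3 * 0.2) + 1e-12)

    def test_empirical_cv_matches_truncated_normal(self, rng):
        # 1e5 draws of a single value at eps = 0.035: the empirical CV is
        # eps times the SD of a 3-sigma-truncated standard normal
        from practident.protocols import SampleSet

        base = SampleSet(np.zeros(100_000), np.full(100_000, 10.0), "insulin")
        out = add_noise(base, 0.035, rng)
        cv = out.values.std() / out.values.mean()
        assert cv == pytest.approx(0.035 * TRUNC3_SD, rel=0.01)
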