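"""Tests for surrogates, profile similarity, windowing, and distinctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormccm import (
    CrossMapConfig,
    EigenmodeRecord,
    InteractionProfile,
    ProfileSet,
    SimilarityMatrix,
    SyntheticWormSpec,
    TimeSeries,
    displayed_delay_grid,
    distinctness_test,
    lag_profile,
    phase_surrogate,
    profile_similarity,
    similarity_matrix,
    surrogate_profiles,
    synthetic_eigenmodes,
    windowed_profiles,
)

PAIRS = [(e, p) for e in ("a1", "a2", "a3", "a4")
         for p in ("a1", "a2", "a3", "a4") if e != p]


def make_set(owner, skills_by_pair, tp=None, rate=1.0):
    tp = np.arange(-8, 1) if tp is None else tp
    return ProfileSet(owner=owner, profiles={
        (e, p): InteractionProfile(e, p, tp, rate, np.asarray(skills_by_pair[(e, p)]))
        for (e, p) in skills_by_pair})


def random_set(owner, rng, n_delays=9):
    return make_set(owner, {pair: rng.uniform(-1, 1, n_delays) for pair in PAIRS})


class TestProfileSimilarity:
    def test_self_similarity_is_one(self):
        s = random_set("a", np.random.default_rng(0))
        assert profile_similarity(s, s) == pytest.approx(1.0)

    def test_reversed_monotone_profiles_anticorrelate(self):
        ramp = np.linspace(0.0, 1.0, 9)
        a = make_set("a", {pair: ramp for pair in PAIRS})
        b = make_set("b", {pair: ramp[::-1] for pair in PAIRS})
        assert profile_similarity(a, b) == pytest.approx(-1.0)

    def test_grid_mismatch_mentions_resampling(self):
        rng = np.random.default_rng(1)
        a = random_set("a", rng)
        b = make_set("b", {pair: rng.uniform(-1, 1, 5) for pair in PAIRS},
                     tp=np.arange(-4, 1))
        with pytest.raises(ValueError, match="resample"):
            profile_similarity(a, b)

    def test_rank_invariance_raw_vs_normalized(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_set("a", rng), random_set("b", rng)
            a_norm = make_set("a", {p: a.profiles[p].skill_norm for p in PAIRS})
            b_norm = make_set("b", {p: b.profiles[p].skill_norm for p in PAIRS})
            assert profile_similarity(a, b) == pytest.approx(
                profile_similarity(a_norm, b_norm), abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        sets = [random_set(f"w{i}", rng) for i in range(5)]
        sm = similarity_matrix(sets)
        assert np.array_equal(sm.values, sm.values.T)
        np.testing.assert_allclose(np.diag(sm.values), 1.0)
        assert np.all(sm.values >= -1) and np.all(sm.values <= 1)

    def test_same_model_draws_more_similar_than_cross_model(self):
        """Draws from one coupling structure correlate more with each other
        than with draws from a different structure."""
        spec_a = SyntheticWormSpec(duration_s=60.0, nan_fraction=0.0,
                                   couplings=(("a1", "a2", 3, 0.12),
                                              ("a3", "a4", 5, 0.1)))
        spec_b = SyntheticWormSpec(duration_s=60.0, nan_fraction=0.0,
                                   couplings=(("a1", "a2", 12, 0.12),
                                              ("a3", "a4", 14, 0.1)))
        cfg = CrossMapConfig(E=2, library_size=150, n_repeats=6, rng_seed=0)
        grid = np.arange(-18, 0)
        wins = 0
        from wormccm import profile_set
        for trial in range(20):
            sa1 = profile_set(synthetic_eigenmodes(spec_a, seed=4 * trial), grid, cfg)
            sa2 = profile_set(synthetic_eigenmodes(spec_a, seed=4 * trial + 1), grid, cfg)
            sb = profile_set(synthetic_eigenmodes(spec_b, seed=4 * trial + 2), grid, cfg)
            same = profile_similarity(sa1, sa2)
            cross = 0.5 * (profile_similarity(sa1, sb) + profile_similarity(sa2, sb))
            wins += same > cross
        assert wins >= 18


class TestPhaseSurrogate:
    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=16, max_value=257), st.integers(0, 10_000))
    def test_preserves_spectrum_mean_variance(self, n, seed):
        rng = np.random.default_rng(seed)
        ts = TimeSeries(rng.normal(size=n).cumsum())
        surr = phase_surrogate(ts, seed=seed)
        assert len(surr) == n
        p0 = np.abs(np.fft.rfft(ts.values)) ** 2
        p1 = np.abs(np.fft.rfft(surr.values)) ** 2
        assert np.max(np.abs(p1 - p0)) <= 1e-8 * max(p0.max(), 1.0)
        assert surr.values.mean() == pytest.approx(ts.values.mean(), abs=1e-8)
        assert surr.values.var() == pytest.approx(ts.values.var(), rel=1e-8)

    def test_sinusoid_maps_to_shifted_sinusoid(self):
        t = np.arange(200)
        ts = TimeSeries(np.sin(2 * np.pi * 10 * t / 200))
        surr = phase_surrogate(ts, seed=1)
        # still a single-frequency sinusoid of the same amplitude
        spec = np.abs(np.fft.rfft(surr.values))
        assert np.argmax(spec) == 10
        assert np.sort(spec)[-2] < 1e-8 * spec.max()
        assert 2 * spec.max() / 200 == pytest.approx(1.0, abs=1e-9)

    def test_missing_values_rejected(self):
        ts = TimeSeries([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="missing"):
            phase_surrogate(ts, seed=0)

    def test_real_coupling_beats_surrogate_band(self, box1_pair, fast_cfg):
        x, y = box1_pair
        grid = displayed_delay_grid(0, 12)
        real = lag_profile(x, y, grid, fast_cfg)
        band = surrogate_profiles(x, y, grid, fast_cfg, n_surrogates=20, seed=3)
        assert np.nanmax(real.skill_raw) > np.percentile(band.max(axis=1), 95)


def _record_from_values(rid, arrays, rate=1.0):
    return EigenmodeRecord(rid, {f"a{i+1}": TimeSeries(v, rate)
                                 for i, v in enumerate(arrays)})


@pytest.fixture(scope="module")
def long_record():
    # 500 s at 1 Hz: cheap windows for the tiling contract
    spec = SyntheticWormSpec(rate_hz=1.0, duration_s=500.0, nan_fraction=0.0)
    return synthetic_eigenmodes(spec, seed=0)


class TestWindowedProfiles:
    def test_tiling_contract(self, long_record):
        cfg = CrossMapConfig(E=2, library_size="all", n_repeats=1, rng_seed=0)
        sets = windowed_profiles(long_record, 20.0, 25, np.arange(-3, 1), cfg)
        assert len(sets) == 25
        assert len({s.owner for s in sets}) == 25

    def test_too_short_reports_feasible_count(self, long_record):
        cfg = CrossMapConfig(E=2, library_size="all", n_repeats=1, rng_seed=0)
        with pytest.raises(ValueError, match="at most 25"):
            windowed_profiles(long_record, 20.0, 26, np.arange(-3, 1), cfg)

    def test_all_missing_window_skipped(self):
        rng = np.random.default_rng(5)
        arrays = [rng.uniform(size=120) for _ in range(4)]
        for v in arrays:
            v[40:80] = np.nan     # second window fully missing
        rec = _record_from_values("gappy", arrays)
        cfg = CrossMapConfig(E=2, library_size="all", n_repeats=1, rng_seed=0)
        sets = windowed_profiles(rec, 40.0, 3, np.arange(-2, 1), cfg)
        assert len(sets) == 2

    def test_regime_switch_splits_into_clusters(self):
        """A mid-recording change of coupling delay separates window profiles."""
        spec1 = SyntheticWormSpec(rate_hz=8.0, duration_s=120.0, nan_fraction=0.0,
                                  couplings=(("a1", "a2", 2, 0.12),))
        spec2 = SyntheticWormSpec(rate_hz=8.0, duration_s=120.0, nan_fraction=0.0,
                                  couplings=(("a1", "a2", 10, 0.12),))
        r1 = synthetic_eigenmodes(spec1, seed=2)
        r2 = synthetic_eigenmodes(spec2, seed=3)
        joined = _record_from_values(
            "switch", [np.concatenate([r1.modes[m].values, r2.modes[m].values])
                       for m in ("a1", "a2", "a3", "a4")], rate=8.0)
        cfg = CrossMapConfig(E=2, library_size=200, n_repeats=3, rng_seed=1)
        sets = windowed_profiles(joined, 120.0, 2, np.arange(-12, 0), cfg)
        cross_regime = profile_similarity(sets[0], sets[1])
        # an independent draw from the first regime stays closer to the
        # first window than the second window does
        r1b = synthetic_eigenmodes(spec1, seed=4)
        ref1 = windowed_profiles(r1b, 120.0, 1, np.arange(-12, 0), cfg)[0]
        same_regime = profile_similarity(sets[0], ref1)
        assert same_regime > cross_regime


class TestDistinctness:
    @staticmethod
    def planted_matrix(rng, n_a=10, n_b=12, within_a=0.9, within_b=0.3,
                       cross=0.5, sd_a=0.05, sd_b=0.10, sd_x=0.05):
        n = n_a + n_b
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ai, aj = i < n_a, j < n_a
                if ai and aj:
                    v = within_a + rng.normal(0, sd_a)
                elif not ai and not aj:
                    v = within_b + rng.normal(0, sd_b)
                else:
                    v = cross + rng.normal(0, sd_x)
                S[i, j] = S[j, i] = v
        ids = [f"u{i}" for i in range(n)]
        return SimilarityMatrix(ids, S), ids[:n_a], ids[n_a:]

    def test_contract(self):
        sm, ga, gb = self.planted_matrix(np.random.default_rng(0))
        res = distinctness_test(sm, ga, gb, n_perm=1000, seed=0)
        assert len(res.null_pcts) == 1000
        assert 0.0 <= res.observed_pct <= 100.0
        assert 0.0 <= res.attained <= 1.0

    def test_planted_clusters_highly_distinct(self):
        rng = np.random.default_rng(1)
        n = 20
        S = rng.normal(0.1, 0.05, size=(n, n))
        S = (S + S.T) / 2
        S[:10, :10] += 0.8
        S[10:, 10:] += 0.8
        ids = [f"u{i}" for i in range(n)]
        res = distinctness_test(SimilarityMatrix(ids, S), ids[:10], ids[10:],
                                n_perm=1000, seed=2)
        assert res.attained >= 0.99

    def test_input_validation(self):
        sm, ga, gb = self.planted_matrix(np.random.default_rng(2))
        with pytest.raises(ValueError, match="overlap"):
            distinctness_test(sm, ga, ga[:1] + gb)
        with pytest.raises(ValueError, match="at least 2"):
            distinctness_test(sm, ga[:1], gb)
        with pytest.raises(ValueError, match="not in"):
            distinctness_test(sm, ga + ["ghost"], gb)

    def test_invariant_to_monotone_rescaling_and_relabeling(self):
        rng = np.random.default_rng(3)
        sm, ga, gb = self.planted_matrix(rng)
        res = distinctness_test(sm, ga, gb, n_perm=500, seed=5)
        warped = SimilarityMatrix(sm.ids, np.tanh(3.0 * sm.values))
        res_w = distinctness_test(warped, ga, gb, n_perm=500, seed=5)
        assert res_w.observed_pct == res.observed_pct
        assert res_w.attained == res.attained
        renamed = SimilarityMatrix([f"x_{u}" for u in sm.ids], sm.values)
        res_r = distinctness_test(renamed, [f"x_{u}" for u in ga],
                                  [f"x_{u}" for u in gb], n_perm=500, seed=5)
        assert res_r.attained == res.attained

    def test_directionality_nested_clusters(self):
        """Tight group inside a diffuse one: the tight group is distinct,
        the diffuse one is not (members match into the tight core)."""
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(20):
            sm, ga, gb = self.planted_matrix(rng)
            seed = int(rng.integers(2**31))
            tight = distinctness_test(sm, ga, gb, n_perm=500, seed=seed)
            diffuse = distinctness_test(sm, gb, ga, n_perm=500, seed=seed)
            wins += (tight.attained >= 0.95) and (diffuse.attained < 0.8)
        assert wins >= 16

    def test_json_round_trip(self, tmp_path):
        import json
        sm, ga, gb = self.planted_matrix(np.random.default_rng(6))
        res = distinctness_test(sm, ga, gb, n_perm=100, seed=1)
        path = tmp_path / "res.json"
        res.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["observed_pct"] == res.observed_pct
        assert loaded["n_perm"] == 100
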