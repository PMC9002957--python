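import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvkin.agreement import (
    WaveformSet,
    bland_altman,
    classify_cmc,
    cmc_interprotocol,
    pearson_pooled,
    rmse,
    rom_error_test,
    summarize,
)
from mvkin.timeseries import build_cycles


def brute_force_cmc(Y):
    """Direct triple-loop evaluation of the inter-protocol variance ratio."""
    P, G, F = Y.shape
    num = 0.0
    den = 0.0
    for g in range(G):
        ybar_g = Y[:, g, :].mean()
        for f in range(F):
            ybar_gf = Y[:, g, f].mean()
            for p in range(P):
                num += (Y[p, g, f] - ybar_gf) ** 2
                den += (Y[p, g, f] - ybar_g) ** 2
    num /= G * F * (P - 1)
    den /= G * (P * F - 1)
    rad = 1.0 - num / den
    return math.nan if rad < 0 else math.sqrt(rad)


def toy(G=3, F=101, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    base = np.sin(np.linspace(0, 2 * np.pi, F))[None] * rng.uniform(20, 40, (G, 1))
    A = base + rng.normal(0, 0.5, (G, F))
    B = A + offset + rng.normal(0, 0.5, (G, F))
    return WaveformSet(np.stack([A, B]))


class TestCmc:
    def test_identical_protocols_give_exactly_one(self):
        A = np.sin(np.linspace(0, 2 * np.pi, 101))[None] * np.array([[30.0], [32.0], [28.0]])
        w = WaveformSet(np.stack([A, A.copy()]))
        assert cmc_interprotocol(w) == 1.0

    def test_offset_exceeding_rom_goes_complex(self):
        A = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (1, 1))
        w = WaveformSet(np.stack([A, A + 10.0]))
        assert math.isnan(cmc_interprotocol(w))

    def test_small_toy_matches_hand_evaluation(self):
        A = np.array([[0.0, 1.0, 2.0, 1.0], [0.5, 1.5, 2.5, 1.0]])
        B = A + 0.5
        w = WaveformSet(np.stack([A, B]))
        assert cmc_interprotocol(w) == pytest.approx(brute_force_cmc(w.Y), abs=1e-12)

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(1)
        for i in range(50):
            G, F = rng.integers(2, 5), rng.integers(4, 9)
            A = rng.normal(0, 1, (G, F)).cumsum(axis=1)
            B = A + rng.normal(0, 0.5, (G, F)) + rng.uniform(-4, 4)
            w = WaveformSet(np.stack([A, B]))
            ours, ref = cmc_interprotocol(w), brute_force_cmc(w.Y)
            assert math.isnan(ours) == math.isnan(ref)
            if not math.isnan(ours):
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_constant_curves_return_one_with_warning(self):
        w = WaveformSet(np.full((2, 2, 5), 7.0))
        with pytest.warns(UserWarning):
            assert cmc_interprotocol(w) == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-50.0, 50.0),
        seed=st.integers(0, 100),
    )
    def test_invariant_under_common_affine_rescaling(self, scale, shift, seed):
        w = toy(seed=seed, offset=2.0)
        w2 = WaveformSet(scale * w.Y + shift)
        a, b = cmc_interprotocol(w), cmc_interprotocol(w2)
        assert math.isnan(a) == math.isnan(b)
        if not math.isnan(a):
            assert a == pytest.approx(b, abs=1e-9)

    def test_nonincreasing_in_constant_offset(self):
        base = toy(seed=3)
        values = []
        for off in np.linspace(0, 60, 13):
            w = WaveformSet(np.stack([base.Y[0], base.Y[0] + off]))
            c = cmc_interprotocol(w)
            values.append(-1.0 if math.isnan(c) else c)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.0, "excellent"),
            (0.96, "excellent"),
            (0.90, "very good"),
            (0.80, "good"),
            (0.50, "poor"),
            (math.nan, "none"),
        ],
    )
    def test_bands(self, value, expected):
        assert classify_cmc(value) == expected


class TestPearson:
    def test_identical_waveforms(self):
        w = toy(seed=4, offset=0.0)
        w2 = WaveformSet(np.stack([w.Y[0], w.Y[0].copy()]))
        assert pearson_pooled(w2) == pytest.approx(1.0)

    def test_sign_flip(self):
        A = toy(seed=5).Y[0]
        A = A - A.mean()
        w = WaveformSet(np.stack([A, -A]))
        assert pearson_pooled(w) == pytest.approx(-1.0)

    def test_textbook_eight_point_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0, 8.0, 6.0])
        r_hand = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        w = WaveformSet(np.stack([a.reshape(2, 4), b.reshape(2, 4)]))
        assert pearson_pooled(w) == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_errors(self):
        w = WaveformSet(np.stack([np.ones((2, 4)), np.zeros((2, 4))]))
        with pytest.raises(ValueError):
            pearson_pooled(w)


class TestRomError:
    def test_paired_difference_arithmetic(self):
        A = np.array([[0.0, 60.0], [0.0, 62.0]])
        B = np.array([[0.0, 58.0], [0.0, 63.0]])
        with pytest.warns(UserWarning):  # < 3 cycles: no tests
            res = rom_error_test(WaveformSet(np.stack([A, B])))
        assert res.diffs.tolist() == [2.0, -1.0]
        assert res.mean == pytest.approx(0.5)

    def test_identical_protocols_zero_error(self):
        A = toy(seed=6).Y[0]
        res = rom_error_test(WaveformSet(np.stack([A, A.copy()])))
        assert res.mean == 0.0 and np.all(res.diffs == 0.0)

    def test_type_one_error_rate_calibrated(self):
        """Under a true zero gain bias the paired t-test rejects at ~5%."""
        rng = np.random.default_rng(0)
        F, G = 21, 13
        base = 40 * np.sin(np.linspace(0, 2 * np.pi, F))
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            gains = rng.normal(0.0, 1.0, G)  # per-cycle ROM noise, zero mean
            A = np.tile(base, (G, 1))
            B = A * (1.0 + gains[:, None] / np.ptp(base))
            res = rom_error_test(WaveformSet(np.stack([A, B])))
            rejections += res.ttest_p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09


class TestBlandAltman:
    def test_identical_protocols(self):
        A = toy(seed=7).Y[0]
        res = bland_altman(WaveformSet(np.stack([A, A.copy()])))
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)
        assert not res.heteroscedastic

    def test_hand_computed_example(self):
        # d = [-2, 2, -3]: bias -1, sd 2.6458, LoA [-6.186, 4.186]
        A = np.array([[0.0, 0.0, 0.0]])
        B = np.array([[2.0, -2.0, 3.0]])
        res = bland_altman(WaveformSet(np.stack([A, B])))
        assert res.bias == pytest.approx(-1.0)
        assert res.sd == pytest.approx(2.6458, abs=1e-4)
        assert res.loa[0] == pytest.approx(-6.1857, abs=1e-3)
        assert res.loa[1] == pytest.approx(4.1857, abs=1e-3)

    def test_95_percent_coverage_for_normal_differences(self):
        rng = np.random.default_rng(42)
        n = 100_000
        A = rng.normal(20, 10, (1, n))
        B = A + rng.normal(0, 2.0, (1, n))
        res = bland_altman(WaveformSet(np.stack([A, B])))
        inside = np.mean((res.differences >= res.loa[0]) & (res.differences <= res.loa[1]))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_heteroscedasticity_detected_when_spread_tracks_magnitude(self):
        rng = np.random.default_rng(3)
        F = 2000
        A = np.abs(rng.normal(30, 10, (1, F)))
        B = A + rng.normal(0, 0.02, (1, F)) * A  # spread proportional to level
        res = bland_altman(WaveformSet(np.stack([A, B])))
        assert res.heteroscedastic

    def test_rmse_decomposition_identity(self):
        """RMSE^2 = bias^2 + population variance of the differences."""
        w = toy(seed=8, offset=3.0)
        d = (w.Y[0] - w.Y[1]).ravel()
        assert rmse(w) ** 2 == pytest.approx(d.mean() ** 2 + d.var(), abs=1e-9)


class TestSummarize:
    def test_identical_channels_all_ones_and_zero_errors(self):
        rng = np.random.default_rng(9)
        n = 240
        sig = {"knee_flexion_r": 30 + 25 * np.sin(np.linspace(0, 16 * np.pi, n))}
        cycles = build_cycles(np.arange(0, n, 30))
        table = summarize(sig, {k: v.copy() for k, v in sig.items()}, cycles)
        row = table.iloc[0]
        assert row.cmc == 1.0 and row.cmc_class == "excellent"
        assert row.mean_err == 0.0 and row.rmse == 0.0

    def test_constant_offset_shows_paper_signature(self):
        """A 15-degree offset leaves r intact, shifts the bias, degrades CMC."""
        rng = np.random.default_rng(10)
        n = 240
        base = 30 + 25 * np.sin(np.linspace(0, 16 * np.pi, n)) + rng.normal(0, 0.5, n)
        cycles = build_cycles(np.arange(0, n, 30))
        table0 = summarize({"hip_flexion_r": base}, {"hip_flexion_r": base + 0.01}, cycles)
        table15 = summarize({"hip_flexion_r": base + 15.0}, {"hip_flexion_r": base}, cycles)
        r0, r15 = table0.iloc[0], table15.iloc[0]
        assert r15.mean_err == pytest.approx(15.0, abs=0.1)
        assert r15.pearson_r == pytest.approx(r0.pearson_r, abs=0.01)
        assert (math.isnan(r15.cmc) and r15.cmc_class == "none") or r15.cmc < r0.cmc

    def test_degenerate_angle_flagged_not_fatal(self):
        n = 120
        cycles = build_cycles(np.arange(0, n, 30))
        sig = {"good": np.sin(np.linspace(0, 8 * np.pi, n)), "flat": np.zeros(n)}
        table = summarize(sig, {k: v.copy() for k, v in sig.items()}, cycles)
        flat = table[table.angle == "flat"].iloc[0]
        assert "zero-variance" in flat["flags"]
        assert len(table) == 2
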