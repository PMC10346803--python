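"""Scalar features vs brute-force oracles, analytic cases, and the
72-element vector contract."""

import numpy as np
import pytest
from scipy import stats

import oracles
from ehgpreterm import preprocess_record
from ehgpreterm.features import (FEATURE_NAMES, extract_features, hurst, kfd,
                                 mtke, rms, shannon_entropy, wle)
from ehgpreterm.io_ehg import EHGRecord

FEATURE_PAIRS = [
    (rms, oracles.rms_naive),
    (mtke, oracles.mtke_naive),
    (wle, oracles.wle_naive),
    (shannon_entropy, oracles.shannon_entropy_naive),
    (kfd, oracles.kfd_naive),
    (hurst, oracles.hurst_naive),
]


class TestBruteForceOracles:
    @pytest.mark.parametrize("func,naive", FEATURE_PAIRS,
                             ids=[f.__name__ for f, _ in FEATURE_PAIRS])
    def test_matches_naive_loops(self, func, naive):
        rng = np.random.default_rng(123)
        for _ in range(100):
            x = rng.standard_normal(rng.integers(30, 200))
            expected = naive(list(x))
            assert func(x) == pytest.approx(expected, abs=1e-10, rel=1e-10)


class TestAnalyticCases:
    def test_rms(self):
        assert rms([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert rms(np.zeros(10)) == 0.0
        t = np.arange(0, 10, 0.05)
        assert rms(np.sin(2 * np.pi * t)) == pytest.approx(2 ** -0.5,
                                                           abs=1e-3)

    def test_mtke(self):
        assert mtke(np.full(50, 3.0)) == 0.0
        assert mtke([0.0, 1.0, 0.0]) == 1.0
        w = 0.7  # rad/sample; discrete TKE of sin(wn) is sin^2(w)
        x = np.sin(w * np.arange(5000))
        assert mtke(x) == pytest.approx(np.sin(w) ** 2, rel=0.01)

    def test_wle(self):
        assert wle(np.ones(5)) == pytest.approx(0.0, abs=1e-9)
        assert wle(np.full(3, np.e)) == pytest.approx(6.0, abs=1e-9)

    def test_wle_scale_shift_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.01, 1.0, size=300) * rng.choice([-1, 1], size=300)
        c = 3.7
        expected = wle(x) + x.size * np.log(c * c)
        assert wle(c * x) == pytest.approx(expected, abs=1e-6)

    def test_shannon_entropy(self):
        assert shannon_entropy(np.full(100, 2.5)) == 0.0
        two_level = np.tile([0.0, 1.0], 50)
        assert shannon_entropy(two_level, n_bins=8) == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        se = shannon_entropy(rng.uniform(size=100_000))
        assert se == pytest.approx(7.0, abs=0.01)

    def test_kfd(self):
        assert kfd(np.array([0.0, 1.0, 2.0, 3.0, 4.0])) == 1.0
        lhs = kfd(np.array([0.0, 1.0, 0.5]))
        expected = np.log(2) / (np.log(2) + np.log(2.0 / 3.0))
        assert lhs == pytest.approx(expected, abs=1e-12)
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        assert kfd(5.0 * x) == pytest.approx(kfd(x), rel=1e-12)
        assert kfd(x) >= 1.0
        with pytest.raises(ValueError, match="constant"):
            kfd(np.full(10, 1.0))

    def test_hurst(self):
        assert 0.85 < hurst(np.arange(1000.0)) < 1.0
        rng = np.random.default_rng(3)
        values = [hurst(rng.standard_normal(10_000)) for _ in range(50)]
        assert 0.45 < np.mean(values) < 0.60
        with pytest.raises(ValueError, match="constant"):
            hurst(np.full(50, 2.0))

    def test_hurst_literal_range_variant(self):
        x = np.random.default_rng(4).standard_normal(500)
        centred = x - x.mean()
        expected = np.log(np.ptp(centred) / x.std()) / np.log(x.size)
        assert hurst(x, cumulative_range=False) == pytest.approx(expected)


def _record(channels, rid="r"):
    return EHGRecord(rid, 20.0, channels, 24.0, 39.0)


class TestExtractFeatures:
    def test_vector_has_the_full_name_grid(self):
        rng = np.random.default_rng(5)
        fv = extract_features(_record(rng.standard_normal((3, 2000))))
        assert list(fv.values) == list(FEATURE_NAMES)
        assert len(fv.values) == 72
        expected = {f"CH{c}_IMF{i}_{k}" for c in (1, 2, 3)
                    for i in (1, 2, 3, 4)
                    for k in ("RMS", "MTKE", "WLE", "SE", "KFD", "HE")}
        assert set(fv.values) == expected
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        channels = rng.standard_normal((3, 1500))
        a = extract_features(_record(channels))
        b = extract_features(_record(channels))
        assert a.values == b.values

    def test_scaled_channel_propagates_equivariance(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.standard_normal(2000))
        fv = extract_features(_record(np.stack([x, 2.0 * x, x])))
        for i in (1, 2, 3, 4):
            assert fv.values[f"CH2_IMF{i}_RMS"] == pytest.approx(
                2.0 * fv.values[f"CH1_IMF{i}_RMS"], rel=1e-9)
            assert fv.values[f"CH2_IMF{i}_KFD"] == pytest.approx(
                fv.values[f"CH1_IMF{i}_KFD"], rel=1e-9)

    def test_degenerate_channel_filled_from_residue(self):
        ramp = np.linspace(0.0, 1.0, 1000)
        rng = np.random.default_rng(8)
        wiggly = np.cumsum(rng.standard_normal(1000))
        fv = extract_features(_record(np.stack([ramp, wiggly, wiggly])))
        assert len(fv.values) == 72
        assert any(a.startswith("CH1_") for a in fv.anomalies)

    def test_preterm_mtke_exceeds_term(self, cohort_50_50):
        """Contraction premise propagated to features: first-IMF CH1 energy
        is larger for preterm cohorts (one-sided rank test, p < 0.01)."""
        from ehgpreterm.emd import decompose
        term, preterm = cohort_50_50
        def ch1_imf1_mtke(rec):
            ch1 = preprocess_record(rec).channels[0]
            return mtke(decompose(ch1, max_imfs=1).imfs[0])
        term_vals = [ch1_imf1_mtke(r) for r in term]
        pre_vals = [ch1_imf1_mtke(r) for r in preterm]
        p = stats.mannwhitneyu(pre_vals, term_vals,
                               alternative="greater").pvalue
        assert p < 0.01
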