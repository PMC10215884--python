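import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegdenoiser as ed
from eegdenoiser.metrics import DEFAULT_BANDS, MetricReport


# ---------------------------------------------------------------------------
# hand-rolled reference implementations (naive loops, no vectorization)
# ---------------------------------------------------------------------------

def naive_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov / (va * vb) ** 0.5


def naive_rrmse(z, x):
    num = (sum((a - b) ** 2 for a, b in zip(z, x)) / len(z)) ** 0.5
    den = (sum(b * b for b in x) / len(x)) ** 0.5
    return num / den


def naive_psd(w, fs):
    """One-sided rectangular periodogram from the DFT definition."""
    n = len(w)
    nfreq = n // 2 + 1
    psd = []
    for k in range(nfreq):
        re = sum(w[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = -sum(w[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        p = (re * re + im * im) / (fs * n)
        if k not in (0, n // 2) or (n % 2 and k == n // 2):
            p *= 2.0
        psd.append(p)
    return np.array(psd)


@pytest.fixture(scope="module")
def short_triplet():
    rng = np.random.default_rng(77)
    x = rng.normal(size=64)
    y = x + rng.normal(size=64)
    z = x + 0.3 * rng.normal(size=64)
    return z, x, y


class TestAgainstNaiveOracles:
    def test_cc_matches_loop(self, short_triplet):
        z, x, _ = short_triplet
        assert ed.cc_temporal(z, x) == pytest.approx(naive_pearson(z, x),
                                                     abs=1e-10)

    def test_rrmse_matches_loop(self, short_triplet):
        z, x, _ = short_triplet
        assert ed.rrmse_temporal(z, x) == pytest.approx(naive_rrmse(z, x),
                                                        abs=1e-10)

    def test_psd_matches_dft_definition(self, short_triplet):
        z, _, _ = short_triplet
        _, psd = ed.periodogram_psd(z, 256)
        assert np.allclose(psd, naive_psd(z, 256), atol=1e-10)

    def test_eta_matches_formula(self, short_triplet):
        z, x, y = short_triplet
        cc_af = naive_pearson(z, x)
        cc_bf = naive_pearson(y, x)
        expected = (1 - (1 - cc_af) / (1 - cc_bf)) * 100
        assert ed.eta(z, x, y) == pytest.approx(expected, abs=1e-10)

    def test_gamma_matches_formula(self, short_triplet):
        z, x, y = short_triplet
        cc_af = naive_pearson(naive_psd(z, 256), naive_psd(x, 256))
        cc_bf = naive_pearson(naive_psd(y, 256), naive_psd(x, 256))
        expected = (1 - (1 - cc_af) / (1 - cc_bf)) * 100
        assert ed.gamma_pct(z, x, y, 256) == pytest.approx(expected, abs=1e-8)

    def test_rrmse_spectral_matches_loop(self, short_triplet):
        z, x, _ = short_triplet
        expected = naive_rrmse(naive_psd(z, 256), naive_psd(x, 256))
        assert ed.rrmse_spectral(z, x, 256) == pytest.approx(expected,
                                                             abs=1e-8)


class TestIdentities:
    """Exact endpoint values that pin down the metric orientation."""

    def test_perfect_prediction(self, short_triplet):
        _, x, y = short_triplet
        assert ed.eta(x, x, y) == pytest.approx(100.0, abs=1e-9)
        assert ed.gamma_pct(x, x, y, 256) == pytest.approx(100.0, abs=1e-9)
        assert ed.rrmse_temporal(x, x) == 0.0
        assert ed.rrmse_spectral(x, x, 256) == 0.0
        assert ed.cc_temporal(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_identity_prediction_gives_zero_reduction(self, short_triplet):
        _, x, y = short_triplet
        assert ed.eta(y, x, y) == pytest.approx(0.0, abs=1e-9)
        assert ed.gamma_pct(y, x, y, 256) == pytest.approx(0.0, abs=1e-9)

    def test_worse_than_input_goes_negative(self, short_triplet):
        _, x, y = short_triplet
        rng = np.random.default_rng(5)
        z = y + 3.0 * rng.normal(size=x.size)
        assert ed.eta(z, x, y) < 0.0

    def test_anticorrelation_bounds(self):
        t = np.linspace(0, 1, 64)
        assert ed.cc_temporal(t, -t) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ed.cc_temporal(np.ones(8), np.arange(8.0))


class TestParsevalAndBands:
    def test_parseval_exact(self, rng):
        for fs, n in ((256, 512), (512, 1024)):
            w = rng.normal(size=n)
            _, psd = ed.periodogram_psd(w, fs)
            assert psd.sum() * fs / n == pytest.approx(np.mean(w ** 2),
                                                       abs=1e-9)

    def test_band_ratios_sum_to_one_for_band_limited_input(self, small_banks):
        for s in small_banks[0][:5]:
            ratios = ed.band_power_ratios(s.samples, s.fs)
            assert sum(ratios.values()) == pytest.approx(1.0, abs=1e-6)

    def test_pure_alpha_tone_lands_in_alpha_band(self):
        t = np.arange(512) / 256
        w = np.sin(2 * np.pi * 10 * t)
        ratios = ed.band_power_ratios(w, 256)
        assert ratios["alpha"] == pytest.approx(1.0, abs=1e-6)

    def test_band_edges_are_half_open(self):
        # an exact 8 Hz tone sits in theta's closed lower... no: [4, 8) puts
        # 8 Hz in alpha, the next band up
        t = np.arange(512) / 256
        ratios = ed.band_power_ratios(np.sin(2 * np.pi * 8 * t), 256)
        assert ratios["alpha"] == pytest.approx(1.0, abs=1e-6)
        assert ratios["theta"] == pytest.approx(0.0, abs=1e-6)

    def test_top_edge_closes_gamma(self):
        t = np.arange(512) / 256
        ratios = ed.band_power_ratios(np.sin(2 * np.pi * 80 * t), 256)
        assert ratios["gamma"] == pytest.approx(1.0, abs=1e-6)

    def test_insufficient_rate_rejected(self):
        with pytest.raises(ValueError, match="80 Hz"):
            ed.band_power_ratios(np.random.default_rng(0).normal(size=128),
                                 100)


class TestScaleInvariance:
    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_eta_invariant_under_common_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        y = x + rng.normal(size=64)
        z = x + 0.5 * rng.normal(size=64)
        base = ed.eta(z, x, y)
        assert ed.eta(scale * z, scale * x, scale * y) == pytest.approx(
            base, rel=1e-6, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_rrmse_invariant_under_common_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        z = x + 0.5 * rng.normal(size=64)
        assert ed.rrmse_temporal(scale * z, scale * x) == pytest.approx(
            ed.rrmse_temporal(z, x), rel=1e-6)


@pytest.fixture(scope="module")
def report(small_banks):
    eeg, eog, _ = small_banks
    ds = ed.build_scenario_dataset(eeg, eog, [], "EOG", [-3], seed=9)
    x, y = ds.pooled_arrays(np.arange(6))
    z = x + 0.25 * (y - x)  # partially denoised stand-in
    return ed.compute_report(z, x, y, fs=256)


class TestReports:
    def test_row_per_segment_and_columns(self, report):
        assert report.n_segments == 6
        assert set(MetricReport.METRICS) <= set(report.per_segment.columns)

    def test_partial_denoising_scores_between_endpoints(self, report):
        assert 0.0 < report.mean("eta") < 100.0
        assert report.mean("cc_temporal") > 0.5

    def test_aggregates_table(self, report):
        agg = report.aggregates
        assert list(agg.columns) == ["mean", "std"]
        assert agg.loc["eta", "mean"] == pytest.approx(report.mean("eta"))

    def test_band_ratio_roles_present(self, report):
        assert set(report.band_ratios) == {"ground_truth", "noisy",
                                           "predicted"}
        assert len(report.band_ratios["noisy"]) == 6

    def test_eog_contamination_inflates_delta_share(self, report):
        mbr = report.mean_band_ratios()
        assert mbr.loc["delta", "noisy"] > mbr.loc["delta", "ground_truth"]

    def test_summary_and_serialization(self, report, tmp_path):
        text = report.summary()
        assert "6 segments" in text and "eta" in text
        report.to_csv(tmp_path / "per_segment.csv")
        assert (tmp_path / "per_segment.csv").exists()
        payload = report.to_json(tmp_path / "report.json")
        assert '"eta"' in payload

    def test_aggregate_reports_concatenates(self, report):
        pooled = ed.aggregate_reports([report, report])
        assert pooled.n_segments == 12
        assert pooled.mean("eta") == pytest.approx(report.mean("eta"))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            ed.compute_report(rng.normal(size=(2, 64)),
                              rng.normal(size=(3, 64)),
                              rng.normal(size=(3, 64)), fs=256)
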