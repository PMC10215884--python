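"""Temporal and spectral denoising metrics.

Given normalized ground-truth x̂, noisy ŷ and predicted ẑ segments:

* ``cc_temporal`` — Pearson correlation Cov(ẑ, x̂)/√(Var(ẑ)·Var(x̂)).
* ``eta`` — temporal percentage reduction in artifacts,
  η = (1 − (1 − CC_af)/(1 − CC_bf)) · 100, where CC_af correlates prediction
  with truth and CC_bf correlates the noisy input with truth.  η = 100 for a
  perfect prediction, 0 when the "prediction" is just the noisy input.
* ``gamma_pct`` — the same construction on correlations between one-sided
  periodogram PSDs (spectral percentage reduction).
* ``rrmse_temporal`` / ``rrmse_spectral`` — RMS of the (time-domain or PSD)
  error relative to the RMS of the reference.
* ``band_power_ratios`` — periodogram power in each canonical EEG band
  (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz) relative to
  the whole 1–80 Hz band.

The PSD is the plain rectangular-window periodogram (squared DFT magnitude,
one-sided), with no Welch averaging or detrending, so Parseval's identity
holds exactly: ∑ PSD · Δf equals the signal's mean square.  Band bins are
assigned half-open [lo, hi), except that the top edge of the partition
(80 Hz) closes the last band, so the five ratios of any 1–80 Hz band-limited
signal sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .contamination import rms

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "MetricReport",
    "cc_temporal",
    "periodogram_psd",
    "cc_spectral",
    "eta",
    "gamma_pct",
    "rrmse_temporal",
    "rrmse_spectral",
    "band_power_ratios",
    "compute_report",
    "aggregate_reports",
]


class BandSpec(NamedTuple):
    name: str
    lo: float
    hi: float


DEFAULT_BANDS = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 80.0),
)


def _as1d(w, name="series"):
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or w.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D series")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{name} contains non-finite values")
    return w


def cc_temporal(a, b) -> float:
    """Pearson correlation coefficient between two series."""
    a, b = _as1d(a, "a"), _as1d(b, "b")
    if a.size != b.size or a.size < 2:
        raise ValueError("series must share a length of at least 2")
    va, vb = np.var(a), np.var(b)
    if va == 0.0 or vb == 0.0:
        raise ValueError("correlation undefined for a constant series")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov / np.sqrt(va * vb))


def periodogram_psd(w, fs):
    """One-sided rectangular-window periodogram.

    Returns ``(freqs, psd)``; ``sum(psd) * (fs/len(w))`` equals the mean
    square of ``w`` (Parseval).
    """
    w = _as1d(w)
    freqs, psd = sps.periodogram(w, fs=fs, window="boxcar", detrend=False,
                                 scaling="density")
    # scipy's density scaling is |DFT|^2/(fs·N), doubled off DC/Nyquist;
    # bin width is fs/N, so the discrete Parseval sum is exact
    return freqs, psd


def cc_spectral(a, b, fs) -> float:
    """Pearson correlation between the two series' periodogram PSDs."""
    _, pa = periodogram_psd(a, fs)
    _, pb = periodogram_psd(b, fs)
    return cc_temporal(pa, pb)


def _reduction(cc_af: float, cc_bf: float) -> float:
    if cc_bf >= 1.0:
        raise ValueError("noisy input is perfectly correlated with the truth; "
                         "percentage reduction is undefined")
    return float((1.0 - (1.0 - cc_af) / (1.0 - cc_bf)) * 100.0)


def eta(z_hat, x_hat, y_hat) -> float:
    """Temporal percentage reduction in artifacts (η), in percent."""
    return _reduction(cc_temporal(z_hat, x_hat), cc_temporal(y_hat, x_hat))


def gamma_pct(z_hat, x_hat, y_hat, fs) -> float:
    """Spectral percentage reduction in artifacts (γ), in percent."""
    return _reduction(cc_spectral(z_hat, x_hat, fs),
                      cc_spectral(y_hat, x_hat, fs))


def rrmse_temporal(z_hat, x_hat) -> float:
    """RMS(ẑ − x̂) / RMS(x̂)."""
    z, x = _as1d(z_hat, "z_hat"), _as1d(x_hat, "x_hat")
    if z.size != x.size:
        raise ValueError("series lengths differ")
    ref = rms(x)
    if ref == 0.0:
        raise ValueError("reference series has zero energy")
    return rms(z - x) / ref


def rrmse_spectral(z_hat, x_hat, fs) -> float:
    """RMS(PSD(ẑ) − PSD(x̂)) / RMS(PSD(x̂))."""
    _, pz = periodogram_psd(z_hat, fs)
    _, px = periodogram_psd(x_hat, fs)
    ref = rms(px)
    if ref == 0.0:
        raise ValueError("reference PSD has zero energy")
    return rms(pz - px) / ref


def band_power_ratios(w, fs, bands=DEFAULT_BANDS) -> dict:
    """Fraction of periodogram power in each band relative to 1–80 Hz.

    Bands are half-open [lo, hi); the band ending at the partition's top edge
    additionally includes the bin at that edge.
    """
    if fs / 2 < 80:
        raise ValueError(f"fs={fs} cannot resolve the 80 Hz band edge")
    freqs, psd = periodogram_psd(w, fs)
    top = max(b.hi for b in bands)
    lo_all = min(b.lo for b in bands)
    total_mask = (freqs >= lo_all) & (freqs <= top)
    total = psd[total_mask].sum()
    if total == 0.0:
        raise ValueError("no spectral power inside the analysis band")
    ratios = {}
    for b in bands:
        mask = (freqs >= b.lo) & (freqs < b.hi)
        if b.hi == top:
            mask |= freqs == top
        if not mask.any():
            raise ValueError(f"band {b.name} ({b.lo}-{b.hi} Hz) contains no "
                             f"DFT bins at this resolution")
        ratios[b.name] = float(psd[mask].sum() / total)
    return ratios


@dataclass
class MetricReport:
    """Per-segment metric vectors plus mean ± std aggregates.

    ``band_ratios`` maps a signal role (``ground_truth``/``noisy``/
    ``predicted``) to a DataFrame of per-segment band power ratios.
    """

    per_segment: pd.DataFrame
    band_ratios: dict = field(default_factory=dict)

    METRICS = ("cc_temporal", "eta", "gamma_pct",
               "rrmse_temporal", "rrmse_spectral")

    @property
    def n_segments(self) -> int:
        return len(self.per_segment)

    def mean(self, metric: str) -> float:
        return float(self.per_segment[metric].mean())

    def std(self, metric: str) -> float:
        return float(self.per_segment[metric].std(ddof=0))

    @property
    def aggregates(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.per_segment[list(self.METRICS)].mean(),
            "std": self.per_segment[list(self.METRICS)].std(ddof=0),
        })

    def mean_band_ratios(self) -> pd.DataFrame:
        return pd.DataFrame({role: df.mean() for role, df in
                             self.band_ratios.items()})

    def summary(self) -> str:
        lines = [f"Denoising metrics over {self.n_segments} segments",
                 self.aggregates.to_string(float_format=lambda v: f"{v:.4f}")]
        if self.band_ratios:
            lines += ["", "Mean band power ratios (fraction of 1-80 Hz power)",
                      self.mean_band_ratios().to_string(
                          float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)

    def to_csv(self, path):
        self.per_segment.to_csv(path, index=False)

    def to_json(self, path=None):
        import json

        payload = {
            "n_segments": self.n_segments,
            "metrics": {m: {"mean": self.mean(m), "std": self.std(m)}
                        for m in self.METRICS},
            "band_power_ratios": {
                role: df.mean().to_dict() for role, df in self.band_ratios.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def compute_report(z_hat, x_hat, y_hat, fs, bands=DEFAULT_BANDS) -> MetricReport:
    """Full metric suite for stacks of segments (rows are segments)."""
    z, x, y = (np.atleast_2d(np.asarray(a, dtype=np.float64))
               for a in (z_hat, x_hat, y_hat))
    if not (z.shape == x.shape == y.shape):
        raise ValueError(f"shape mismatch: z {z.shape}, x {x.shape}, y {y.shape}")
    rows = []
    ratio_rows = {"ground_truth": [], "noisy": [], "predicted": []}
    for zi, xi, yi in zip(z, x, y):
        rows.append({
            "cc_temporal": cc_temporal(zi, xi),
            "eta": eta(zi, xi, yi),
            "gamma_pct": gamma_pct(zi, xi, yi, fs),
            "rrmse_temporal": rrmse_temporal(zi, xi),
            "rrmse_spectral": rrmse_spectral(zi, xi, fs),
        })
        ratio_rows["ground_truth"].append(band_power_ratios(xi, fs, bands))
        ratio_rows["noisy"].append(band_power_ratios(yi, fs, bands))
        ratio_rows["predicted"].append(band_power_ratios(zi, fs, bands))
    return MetricReport(
        per_segment=pd.DataFrame(rows),
        band_ratios={k: pd.DataFrame(v) for k, v in ratio_rows.items()},
    )


def aggregate_reports(reports) -> MetricReport:
    """Concatenate per-segment reports into one pooled report."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    per_segment = pd.concat([r.per_segment for r in reports], ignore_index=True)
    roles = set().union(*(r.band_ratios.keys() for r in reports))
    band_ratios = {
        role: pd.concat([r.band_ratios[role] for r in reports
                         if role in r.band_ratios], ignore_index=True)
        for role in roles
    }
    return MetricReport(per_segment=per_segment, band_ratios=band_ratios)
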