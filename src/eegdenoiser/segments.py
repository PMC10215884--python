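"""Segment banks: surrogate EEG/EOG/EMG generation, container I/O, resampling.

A *segment* is one fixed-length, single-channel physiological trace in
microvolts.  The conventions follow the public EEGdenoiseNet segment banks:
EEG and EOG segments are 512 samples at 256 Hz, EMG segments are 1024 samples
at 512 Hz.  The surrogate generator produces banks with the same band limits
and qualitative amplitude ordering (EMG ≫ EEG, EOG) so the whole pipeline is
exercisable without downloading the real data.

Surrogates are synthesised by inverse-DFT spectral shaping: uniform random
phases, magnitude ∝ f^(−α) inside the passband and exactly zero outside,
inverse transform, rescale to a target RMS.  This gives exact band
containment, determinism for a fixed seed, and a tunable 1/f-type spectrum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "SurrogateSpec",
    "DEFAULT_SPECS",
    "generate_surrogate_bank",
    "load_segment_bank",
    "write_segment_bank",
    "resample_segment",
]

KINDS = ("EEG", "EOG", "EMG")

#: canonical sampling rate per segment kind (Hz)
KIND_FS = {"EEG": 256, "EOG": 256, "EMG": 512}

#: canonical segment length per sampling rate
FS_LENGTH = {256: 512, 512: 1024}


@dataclass(frozen=True)
class Segment:
    """One fixed-length single-channel trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in microvolts; finite, one-dimensional.
    fs : int
        Sampling rate in Hz (256 or 512).
    kind : str
        One of ``EEG``, ``EOG``, ``EMG``.
    id : str
        Unique label, used by manifests for leakage bookkeeping.
    """

    samples: np.ndarray
    fs: int
    kind: str
    id: str

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"segment samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"segment {self.id!r} contains non-finite samples")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.fs not in (256, 512):
            raise ValueError(f"fs must be 256 or 512 Hz, got {self.fs}")
        expected = FS_LENGTH[self.fs]
        if samples.size != expected:
            raise ValueError(
                f"segment {self.id!r}: {samples.size} samples at {self.fs} Hz; "
                f"segments are 2 s long ({expected} samples)"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self):
        return self.samples.size


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for one surrogate segment bank.

    ``spectral_exponent`` is the α of the f^(−α) magnitude profile inside the
    passband; ``amplitude_scale`` is the target per-segment RMS in microvolts.
    """

    kind: str
    count: int
    length: int
    fs: int
    passband: tuple
    spectral_exponent: float = 1.0
    amplitude_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        lo, hi = self.passband
        if not (0 < lo < hi):
            raise ValueError(f"passband must satisfy 0 < lo < hi, got {self.passband}")
        if hi > self.fs / 2:
            raise ValueError(
                f"passband upper edge {hi} Hz exceeds Nyquist {self.fs / 2} Hz "
                f"for fs={self.fs}"
            )
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


#: default bank recipes approximating the real banks' band limits and the
#: qualitative magnitude ordering (EMG has much larger amplitude than EEG/EOG)
DEFAULT_SPECS = {
    "EEG": SurrogateSpec("EEG", count=4514, length=512, fs=256,
                         passband=(1.0, 80.0), spectral_exponent=1.0,
                         amplitude_scale=10.0),
    "EOG": SurrogateSpec("EOG", count=3400, length=512, fs=256,
                         passband=(0.3, 10.0), spectral_exponent=1.5,
                         amplitude_scale=15.0),
    "EMG": SurrogateSpec("EMG", count=5598, length=1024, fs=512,
                         passband=(1.0, 120.0), spectral_exponent=0.0,
                         amplitude_scale=80.0),
}


def generate_surrogate_bank(spec: SurrogateSpec) -> list:
    """Generate ``spec.count`` band-limited surrogate segments.

    Each segment has spectral magnitude ∝ f^(−α) strictly inside
    ``spec.passband`` (zero outside, so out-of-band periodogram power is
    numerically zero) and RMS equal to ``spec.amplitude_scale``.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    lo, hi = spec.passband
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError(f"passband {spec.passband} contains no DFT bins at length {n}")
    mag = np.zeros_like(freqs)
    with np.errstate(divide="ignore"):
        mag[band] = np.where(freqs[band] > 0, freqs[band], 1.0) ** (-spec.spectral_exponent)

    segments = []
    for i in range(spec.count):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
        spectrum = mag * np.exp(1j * phases)
        # real signal: DC and (even-n) Nyquist bins must be real
        spectrum[0] = 0.0
        if n % 2 == 0:
            spectrum[-1] = spectrum[-1].real
        w = np.fft.irfft(spectrum, n=n)
        rms = np.sqrt(np.mean(w ** 2))
        w *= spec.amplitude_scale / rms
        segments.append(
            Segment(w, fs=spec.fs, kind=spec.kind, id=f"{spec.kind.lower()}-{i:05d}")
        )
    return segments


def _check_homogeneous(segments):
    if not segments:
        raise ValueError("segment bank is empty")
    length = len(segments[0])
    fs = segments[0].fs
    kind = segments[0].kind
    for s in segments:
        if len(s) != length:
            raise ValueError(
                f"heterogeneous bank: segment {s.id!r} has length {len(s)}, "
                f"expected {length}"
            )
        if s.fs != fs or s.kind != kind:
            raise ValueError(
                f"heterogeneous bank: segment {s.id!r} is {s.kind}@{s.fs} Hz, "
                f"expected {kind}@{fs} Hz"
            )
    return length, fs, kind


def write_segment_bank(segments: list, path: str) -> None:
    """Write a homogeneous bank to HDF5 (default) or NPZ (``.npz`` suffix).

    The HDF5 layout is one 2-D float64 dataset named after the lowercase kind
    (``eeg``/``eog``/``emg``) with ``fs`` and ``kind`` attributes; reload with
    :func:`load_segment_bank` is lossless.
    """
    _, fs, kind = _check_homogeneous(segments)
    data = np.stack([s.samples for s in segments])
    if str(path).endswith(".npz"):
        np.savez(path, **{kind.lower(): data, "fs": fs})
        return
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset(kind.lower(), data=data)
        ds.attrs["fs"] = fs
        ds.attrs["kind"] = kind


def load_segment_bank(path: str, kind: str) -> list:
    """Load a 2-D (segments × samples) bank; returns one Segment per row.

    ``kind`` selects the dataset (``eeg``/``eog``/``emg``) and assigns the
    sampling rate (EEG/EOG → 256 Hz, EMG → 512 Hz) unless the file carries an
    ``fs`` attribute.  Accepts HDF5 and NPZ dialects; also tolerates banks
    stored under the single generic name ``data``.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    name = kind.lower()
    if str(path).endswith(".npz"):
        with np.load(path) as z:
            key = name if name in z.files else "data"
            if key not in z.files:
                raise ValueError(f"{path}: no dataset {name!r} or 'data'")
            data = np.asarray(z[key])
            fs = int(z["fs"]) if "fs" in z.files else KIND_FS[kind]
    else:
        import h5py

        with h5py.File(path, "r") as f:
            key = name if name in f else "data"
            if key not in f:
                raise ValueError(f"{path}: no dataset {name!r} or 'data'")
            data = np.asarray(f[key])
            fs = int(f[key].attrs.get("fs", KIND_FS[kind]))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D (segments × samples) array, "
                         f"got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-numeric dtype {data.dtype}")
    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-finite values in row {bad[0]}")
    return [
        Segment(row, fs=fs, kind=kind, id=f"{name}-{i:05d}")
        for i, row in enumerate(data)
    ]


def resample_segment(segment: Segment, target_fs: int) -> Segment:
    """Resample to an integer-multiple rate by Fourier zero-padding.

    Only upsampling by an integer factor is supported (×2 in practice, taking
    256 Hz EEG/EOG to 512 Hz before mixing with EMG).  Fourier-domain
    zero-padding preserves all spectral content below the original band edge,
    so band-limited segments keep their morphology exactly.
    """
    if target_fs == segment.fs:
        return segment
    ratio = target_fs / segment.fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-12 or factor < 1:
        raise ValueError(
            f"target_fs={target_fs} is not an integer multiple of fs={segment.fs}"
        )
    n = len(segment)
    spectrum = np.fft.rfft(segment.samples)
    # zero-pad the one-sided spectrum; scale keeps amplitudes unchanged
    out_n = n * factor
    padded = np.zeros(out_n // 2 + 1, dtype=complex)
    padded[: spectrum.size] = spectrum
    if n % 2 == 0:
        # original Nyquist bin is shared between ±f; halve it when it becomes
        # an interior bin of the longer spectrum
        padded[spectrum.size - 1] *= 0.5
    samples = np.fft.irfft(padded, n=out_n) * factor
    return Segment(samples, fs=target_fs, kind=segment.kind, id=segment.id)
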