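"""SNR-controlled semi-synthetic contamination of clean EEG.

A noisy segment is built by linear mixing, y = x + λ·n, where x is a clean
EEG segment and n is one artifact segment (EOG or EMG) or the sum of one of
each.  λ is solved so that the signal-to-noise ratio

    SNR = 10 · log10( RMS(x) / RMS(λ·n) )

hits a requested integer dB level.  Before training, each (x, y) pair is
rescaled by the standard deviation σ_y of the noisy segment,
x̂ = x/σ_y, ŷ = y/σ_y, so every network input has unit standard deviation.

σ_y uses the population convention (divide by m), matching the mean-of-squares
RMS definition; the unit-variance invariant of ŷ depends on this choice.

Scenario datasets pair clean EEG with artifacts *without replacement* — every
EEG, EOG and EMG segment is used in at most one pairing — and the same
(x, n) couple is re-mixed at every SNR level.  Train/validation/test splits
are made on couple indices, so a clean segment never straddles the split at
any SNR level (no leakage between subsets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .segments import Segment, resample_segment

__all__ = [
    "ContaminatedPair",
    "DatasetManifest",
    "Split",
    "ScenarioDataset",
    "rms",
    "solve_lambda",
    "mix",
    "normalize_pair",
    "build_scenario_dataset",
    "split_dataset",
]

SCENARIOS = ("EOG", "EMG", "EOG+EMG")


def rms(w) -> float:
    """Root of the mean of squares, sqrt(mean(w_i^2))."""
    w = np.asarray(w, dtype=np.float64)
    if w.size == 0:
        raise ValueError("rms of an empty series is undefined")
    if not np.all(np.isfinite(w)):
        raise ValueError("rms requires finite input")
    return float(np.sqrt(np.mean(w ** 2)))


def solve_lambda(x, n, snr_db: float) -> float:
    """Scaling factor λ giving the requested SNR for the mix x + λ·n.

    From SNR = 10·log10(RMS(x)/RMS(λ·n)):  λ = RMS(x) / (RMS(n)·10^(SNR/10)).
    Lower λ means higher SNR.
    """
    rx, rn = rms(x), rms(n)
    if rn == 0.0:
        raise ValueError("artifact series has zero energy; lambda is undefined")
    if rx == 0.0:
        raise ValueError("clean series has zero energy; SNR is undefined")
    return rx / (rn * 10.0 ** (snr_db / 10.0))


def snr_db_of(x, scaled_n) -> float:
    """Recompute 10·log10(RMS(x)/RMS(λ·n)) from a realized mix."""
    return 10.0 * np.log10(rms(x) / rms(scaled_n))


@dataclass
class ContaminatedPair:
    """One (clean, noisy) training pair with its mixing bookkeeping."""

    x: Segment
    y: np.ndarray
    artifact_ids: tuple
    snr_db: float
    lam: float
    sigma_y: float = 0.0
    x_hat: np.ndarray = None
    y_hat: np.ndarray = None
    id: str = ""


def mix(x: Segment, artifacts, snr_db: float) -> ContaminatedPair:
    """Linearly mix one clean segment with one or two artifact segments.

    The artifacts are summed first and a single λ scales the sum, so the
    requested SNR refers to the combined artifact.  All inputs must share
    sampling rate and length (resample beforehand).
    """
    if isinstance(artifacts, Segment):
        artifacts = [artifacts]
    if not 1 <= len(artifacts) <= 2:
        raise ValueError("mix takes one or two artifact segments")
    for a in artifacts:
        if a.fs != x.fs or len(a) != len(x):
            raise ValueError(
                f"artifact {a.id!r} ({len(a)} samples @ {a.fs} Hz) does not match "
                f"clean segment {x.id!r} ({len(x)} samples @ {x.fs} Hz)"
            )
    n = np.sum([a.samples for a in artifacts], axis=0)
    lam = solve_lambda(x.samples, n, snr_db)
    y = x.samples + lam * n
    return ContaminatedPair(
        x=x,
        y=y,
        artifact_ids=tuple(a.id for a in artifacts),
        snr_db=float(snr_db),
        lam=lam,
        id=f"{x.id}+{'+'.join(a.id for a in artifacts)}@{snr_db:g}dB",
    )


def normalize_pair(pair: ContaminatedPair) -> ContaminatedPair:
    """Divide clean and noisy series by σ_y (population std of the noisy mix)."""
    sigma_y = float(np.std(pair.y))  # population convention (ddof=0)
    if sigma_y == 0.0:
        raise ValueError("noisy segment is constant; cannot normalize")
    pair.sigma_y = sigma_y
    pair.x_hat = pair.x.samples / sigma_y
    pair.y_hat = pair.y / sigma_y
    return pair


@dataclass
class Split:
    """Disjoint couple-index subsets; train excludes the validation portion."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    @property
    def training_portion(self) -> np.ndarray:
        """Train+val together — the '80%' of the 80/20 language."""
        return np.concatenate([self.train, self.val])


@dataclass
class DatasetManifest:
    """Pairings and split bookkeeping for one contamination scenario.

    ``pairings`` maps couple index -> (eeg_id, artifact_id tuple); the same
    couples are re-mixed at every SNR level, so splits are stored as couple
    indices and apply identically to all levels.
    """

    scenario: str
    snr_levels: list
    pairings: list
    seed: int
    fs: int
    length: int
    splits: dict = field(default_factory=dict)

    @property
    def n_couples(self) -> int:
        return len(self.pairings)

    @property
    def n_pairs(self) -> int:
        return len(self.pairings) * len(self.snr_levels)

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": self.scenario,
            "snr_levels": list(self.snr_levels),
            "pairings": [[e, list(a)] for e, a in self.pairings],
            "seed": self.seed,
            "fs": self.fs,
            "length": self.length,
            "splits": {
                k: {part: np.asarray(getattr(v, part)).tolist()
                    for part in ("train", "val", "test")}
                for k, v in self.splits.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "DatasetManifest":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as f:
                payload = json.load(f)
        splits = {
            k: Split(np.asarray(v["train"], dtype=int),
                     np.asarray(v["val"], dtype=int),
                     np.asarray(v["test"], dtype=int))
            for k, v in payload.pop("splits", {}).items()
        }
        pairings = [(e, tuple(a)) for e, a in payload.pop("pairings")]
        return cls(pairings=pairings, splits=splits, **payload)


class ScenarioDataset:
    """A manifest plus its source banks; pairs are materialized on demand.

    Waveforms for all couples × levels are never held in memory at once —
    count/split logic works on the manifest alone, and training code requests
    only the (x̂, ŷ) arrays it needs.
    """

    def __init__(self, manifest: DatasetManifest, eeg_bank, artifact_banks):
        self.manifest = manifest
        self._eeg = {s.id: s for s in eeg_bank}
        self._artifacts = {}
        for bank in artifact_banks:
            self._artifacts.update({s.id: s for s in bank})
        self.fs = manifest.fs
        self.length = manifest.length

    @property
    def n_pairs(self) -> int:
        return self.manifest.n_pairs

    def pair(self, snr_db, couple_index: int) -> ContaminatedPair:
        """Materialize one normalized pair."""
        if snr_db not in self.manifest.snr_levels:
            raise KeyError(f"SNR level {snr_db} dB not in manifest "
                           f"{self.manifest.snr_levels}")
        eeg_id, artifact_ids = self.manifest.pairings[couple_index]
        x = self._prepared(self._eeg[eeg_id])
        artifacts = [self._prepared(self._artifacts[a]) for a in artifact_ids]
        return normalize_pair(mix(x, artifacts, snr_db))

    def _prepared(self, seg: Segment) -> Segment:
        if seg.fs != self.fs:
            seg = resample_segment(seg, self.fs)
        if len(seg) != self.length:
            raise ValueError(
                f"segment {seg.id!r} has length {len(seg)}, scenario needs "
                f"{self.length}"
            )
        return seg

    def arrays(self, snr_db, couple_indices) -> tuple:
        """Stacked (X̂, Ŷ) float arrays for a set of couples at one level."""
        pairs = [self.pair(snr_db, i) for i in couple_indices]
        x = np.stack([p.x_hat for p in pairs])
        y = np.stack([p.y_hat for p in pairs])
        return x, y

    def pooled_arrays(self, couple_indices, snr_levels=None) -> tuple:
        """Stacked (X̂, Ŷ) over all (or given) levels for a set of couples."""
        levels = self.manifest.snr_levels if snr_levels is None else snr_levels
        xs, ys = [], []
        for level in levels:
            x, y = self.arrays(level, couple_indices)
            xs.append(x)
            ys.append(y)
        return np.concatenate(xs), np.concatenate(ys)


def build_scenario_dataset(eeg_bank, eog_bank, emg_bank, scenario: str,
                           snr_levels, seed: int = 0,
                           n_couples: int = None) -> ScenarioDataset:
    """Assemble a contamination scenario with without-replacement pairing.

    EOG scenario mixes at 256 Hz; EMG and EOG+EMG scenarios run at 512 Hz
    (EEG, and EOG when present, are upsampled ×2 before mixing).  The couple
    count defaults to the largest without-replacement pairing the banks
    support: min over the banks involved.  With the real bank sizes
    (4514 EEG / 3400 EOG / 5598 EMG) this yields 3400 couples for EOG and
    EOG+EMG and 4514 for EMG — 34,000 / 34,000 / 45,140 pairs over ten SNR
    levels.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    snr_levels = list(snr_levels)
    if not snr_levels:
        raise ValueError("need at least one SNR level")

    if scenario == "EOG":
        banks = {"EEG": eeg_bank, "EOG": eog_bank}
        fs = 256
    elif scenario == "EMG":
        banks = {"EEG": eeg_bank, "EMG": emg_bank}
        fs = 512
    else:
        banks = {"EEG": eeg_bank, "EOG": eog_bank, "EMG": emg_bank}
        fs = 512

    available = min(len(b) for b in banks.values())
    if n_couples is None:
        n_couples = available
    if n_couples > available:
        raise ValueError(
            f"scenario {scenario!r} needs {n_couples} segments per bank but the "
            f"smallest bank holds {available}"
        )
    if n_couples < 1:
        raise ValueError("need at least one couple")

    rng = np.random.default_rng(seed)
    chosen = {
        kind: [bank[i].id for i in rng.permutation(len(bank))[:n_couples]]
        for kind, bank in banks.items()
    }
    artifact_kinds = [k for k in ("EOG", "EMG") if k in banks]
    pairings = [
        (chosen["EEG"][i], tuple(chosen[k][i] for k in artifact_kinds))
        for i in range(n_couples)
    ]
    length = fs * 2  # 512 samples @256 Hz, 1024 @512 Hz (2 s segments)
    manifest = DatasetManifest(
        scenario=scenario, snr_levels=snr_levels, pairings=pairings,
        seed=seed, fs=fs, length=length,
    )
    return ScenarioDataset(manifest, eeg_bank,
                           [banks[k] for k in artifact_kinds])


def split_dataset(manifest: DatasetManifest, experiment: str,
                  train_fraction: float = 0.8,
                  val_fraction_of_train: float = 0.1) -> DatasetManifest:
    """Attach the train/val/test split for Experiment A or B to a manifest.

    Couples are permuted once (with the manifest seed) and the first
    floor(train_fraction · n) form the training portion, of which the last
    ``val_fraction_of_train`` become validation; the remainder is test.
    Because splitting is by couple index and couples are identical across SNR
    levels, the same clean segment falls on the same side of the split at
    every level.

    Experiment "A" applies the split within each single level; experiment "B"
    pools the per-level splits across all levels.  The stored indices are the
    same either way — the experiment tag records how they are to be consumed
    and is validated here.
    """
    if experiment not in ("A", "B"):
        raise ValueError(f"experiment must be 'A' or 'B', got {experiment!r}")
    if not (0 < train_fraction < 1) or not (0 < val_fraction_of_train < 1):
        raise ValueError("fractions must lie in (0, 1)")
    n = manifest.n_couples
    rng = np.random.default_rng(manifest.seed + 1)
    perm = rng.permutation(n)
    n_train_portion = int(np.floor(train_fraction * n))
    if n_train_portion < 1 or n_train_portion >= n:
        raise ValueError(f"cannot split {n} couples at fraction {train_fraction}")
    n_val = int(np.floor(val_fraction_of_train * n_train_portion))
    portion = perm[:n_train_portion]
    manifest.splits[experiment] = Split(
        train=np.sort(portion[: n_train_portion - n_val]),
        val=np.sort(portion[n_train_portion - n_val:]),
        test=np.sort(perm[n_train_portion:]),
    )
    return manifest
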