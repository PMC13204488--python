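"""Synthetic test-data generators.

Stands in for the two external corpora the pipeline was designed around:

* modular, temporally smooth regional BOLD-like time series whose
  thresholded correlation graph lands in the biological density range
  (the real inputs were resting-state fMRI series over 90 AAL regions);
* short class-distinct spoken-digit-like utterances built from two-formant
  trajectories (the real inputs were the TI46 isolated-digit subset, which
  is licensed and cannot be bundled).

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .encoding import Waveform
from .fbn import RegionalBoldMatrix, Topology

__all__ = [
    "BoldGenConfig",
    "AudioGenConfig",
    "AudioDataset",
    "gen_bold",
    "gen_audio_dataset",
    "gen_toy_fixtures",
    "DEFAULT_SEED",
]

#: Documented default seed for the acceptance experiments.
DEFAULT_SEED = 20260426


@dataclass(frozen=True)
class BoldGenConfig:
    """Modular correlated time-series generator settings.

    Regions are grouped into modules; each region mixes a global signal, a
    module-shared signal and idiosyncratic noise (all unit-variance AR(1)
    processes) so that the expected Pearson correlation is ``r_within``
    inside a module and ``r_between`` across modules.
    """

    n_regions: int = 90
    n_samples: int = 200
    sampling_interval: float = 1.5  # s (scanner TR)
    n_modules: int = 6
    r_within: float = 0.55
    r_between: float = 0.15
    ar_coefficient: float = 0.3
    n_subjects: int = 10
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not (0.0 <= self.r_between < self.r_within <= 1.0):
            raise ValueError("require 0 <= r_between < r_within <= 1")
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules must be <= n_regions")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class AudioGenConfig:
    """Synthetic spoken-digit generator settings.

    Each class has a distinct pair of formant trajectories (start/end
    frequencies); utterances add an amplitude envelope, white noise, and a
    class-independent random duration.
    """

    n_classes: int = 10
    per_class: int = 30
    sample_rate: float = 12500.0
    duration_range_ms: Tuple[float, float] = (300.0, 600.0)
    noise_level: float = 0.05
    train_fraction: float = 2.0 / 3.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        lo, hi = self.duration_range_ms
        if not (0 < lo <= hi):
            raise ValueError("durations must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class AudioDataset:
    """Waveforms with integer labels and a reproducible train/test split."""

    waveforms: List[Waveform]
    labels: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    classes: Tuple[int, ...]

    def subset(self, idx: np.ndarray) -> List[Tuple[Waveform, int]]:
        return [(self.waveforms[i], int(self.labels[i])) for i in idx]


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance AR(1) series."""
    innov_sd = np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def gen_bold(cfg: BoldGenConfig = BoldGenConfig()) -> List[RegionalBoldMatrix]:
    """Generate ``n_subjects`` modular BOLD-like matrices.

    Region signal = a*global + b*module + c*noise with a^2 = r_between,
    a^2 + b^2 = r_within, c^2 = 1 - r_within, so expected correlations hit
    the configured targets.
    """
    a = np.sqrt(cfg.r_between)
    b = np.sqrt(cfg.r_within - cfg.r_between)
    c = np.sqrt(1.0 - cfg.r_within)
    module_of = np.array_split(np.arange(cfg.n_regions), cfg.n_modules)
    labels = tuple(f"region_{i:03d}" for i in range(cfg.n_regions))
    subjects = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng((cfg.seed, s))
        g = _ar1(rng, cfg.n_samples, cfg.ar_coefficient)
        module_sig = [
            _ar1(rng, cfg.n_samples, cfg.ar_coefficient)
            for _ in range(cfg.n_modules)
        ]
        x = np.empty((cfg.n_regions, cfg.n_samples))
        for m, members in enumerate(module_of):
            for i in members:
                noise = _ar1(rng, cfg.n_samples, cfg.ar_coefficient)
                x[i] = a * g + b * module_sig[m] + c * noise
        subjects.append(
            RegionalBoldMatrix(
                values=x,
                region_labels=labels,
                sampling_interval=cfg.sampling_interval,
            )
        )
    return subjects


def _formant_tables(n_classes: int) -> List[dict]:
    """Distinct two-formant trajectories per class (Hz)."""
    tables = []
    for c in range(n_classes):
        f1_start = 300.0 + 55.0 * c
        f1_end = 800.0 - 45.0 * c
        f2_start = 2400.0 - 130.0 * c
        f2_end = 1000.0 + 110.0 * c
        tables.append(
            {
                "f1": (f1_start, f1_end),
                "f2": (f2_start, f2_end),
                "f2_gain": 0.6 + 0.03 * c,
            }
        )
    return tables


def gen_audio_dataset(cfg: AudioGenConfig = AudioGenConfig()) -> AudioDataset:
    """Synthetic spoken-digit-like dataset with a train/test split.

    Each utterance sweeps the two class formants over a random duration,
    shaped by a raised-cosine amplitude envelope, plus white noise.
    """
    tables = _formant_tables(cfg.n_classes)
    for i in range(cfg.n_classes):
        for j in range(i + 1, cfg.n_classes):
            if tables[i] == tables[j]:
                raise ValueError("class trajectories must be distinct")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.duration_range_ms
    waveforms, labels = [], []
    for c in range(cfg.n_classes):
        tab = tables[c]
        for _ in range(cfg.per_class):
            dur_ms = rng.uniform(lo, hi)
            n = int(round(dur_ms * cfg.sample_rate / 1000.0))
            t = np.arange(n) / cfg.sample_rate
            u = np.linspace(0.0, 1.0, n)
            jitter = rng.normal(1.0, 0.03)
            f1 = (tab["f1"][0] + (tab["f1"][1] - tab["f1"][0]) * u) * jitter
            f2 = (tab["f2"][0] + (tab["f2"][1] - tab["f2"][0]) * u) * jitter
            phase1 = 2 * np.pi * np.cumsum(f1) / cfg.sample_rate
            phase2 = 2 * np.pi * np.cumsum(f2) / cfg.sample_rate
            env = 0.5 * (1.0 - np.cos(2 * np.pi * np.minimum(u / 0.2, 1.0) * 0.5)) * (
                0.5 * (1.0 - np.cos(2 * np.pi * np.minimum((1 - u) / 0.2, 1.0) * 0.5))
            )
            signal = env * (np.sin(phase1) + tab["f2_gain"] * np.sin(phase2))
            signal += cfg.noise_level * rng.standard_normal(n)
            peak = np.max(np.abs(signal))
            waveforms.append(
                Waveform(samples=0.9 * signal / peak, sample_rate=cfg.sample_rate)
            )
            labels.append(c)
    labels = np.asarray(labels)
    n_total = labels.size
    order = rng.permutation(n_total)
    train_idx, test_idx = [], []
    # stratified split: per class, the first train_fraction go to training
    for c in range(cfg.n_classes):
        members = order[labels[order] == c]
        n_train = int(round(cfg.train_fraction * members.size))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return AudioDataset(
        waveforms=waveforms,
        labels=labels,
        train_idx=np.asarray(sorted(train_idx)),
        test_idx=np.asarray(sorted(test_idx)),
        classes=tuple(range(cfg.n_classes)),
    )


def gen_toy_fixtures() -> Dict[str, dict]:
    """Canonical small fixtures with hand-derived expected values.

    Returned dict maps fixture names to {"value": ..., "expected": ...}
    pairs used throughout the test suite.
    """
    triangle = Topology(n_nodes=3, edges=frozenset({(0, 1), (1, 2), (0, 2)}))
    star = Topology(n_nodes=4, edges=frozenset({(0, 1), (0, 2), (0, 3)}))
    ring6 = Topology(
        n_nodes=6,
        edges=frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)}),
    )
    complete5 = Topology(
        n_nodes=5,
        edges=frozenset(
            (i, j) for i in range(5) for j in range(i + 1, 5)
        ),
    )
    rng = np.random.default_rng(7)
    bold_3x5 = RegionalBoldMatrix(
        values=rng.standard_normal((3, 5)),
        region_labels=("r0", "r1", "r2"),
        sampling_interval=1.5,
    )
    return {
        "triangle": {"value": triangle, "expected_cw": 1.0},
        "star": {"value": star, "expected_cw": 0.0},
        "ring6": {"value": ring6, "expected_density": 0.4},
        "complete5": {"value": complete5, "expected_density": 1.0},
        "bold_3x5": {"value": bold_3x5},
        "norm_column": {"value": np.array([1.0, 2.0, 3.0]),
                        "expected": np.array([-1.22474487, 0.0, 1.22474487])},
        "sigma_delta_half": {"value": np.full(100, 0.5), "expected_spikes": 50},
    }
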