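"""Synthetic motif-planted sequences with base-resolution signal tracks.

Positive items are i.i.d. background DNA carrying one PWM draw plus a
Gaussian signal bump centered on the planted instance; negatives are
background with low absolute-Gaussian baseline noise.  Also builds the
two perturbation benchmarks: planted centers shifted to 250/500/750 bp,
and 100-bp motif-bearing cores inserted at random offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import (
    BASES,
    GenomicInterval,
    OneHotSequence,
    PeakRecord,
    Sample,
    SignalTrack,
    one_hot_encode,
)

__all__ = [
    "GeneratorSpec",
    "TruthRecord",
    "default_pwm",
    "sample_background",
    "plant_motif_with_signal",
    "shift_experiment_set",
    "insertion_experiment_set",
    "make_samples",
    "simulate_dataset",
]

_DEFAULT_CONSENSUS = "TGACGTCATGCA"


def default_pwm(dominant: float = 0.87) -> np.ndarray:
    """Packaged 12-bp probability matrix, ~1.2 bits of information per
    position at the default dominant-base probability."""
    k = len(_DEFAULT_CONSENSUS)
    pwm = np.full((k, 4), (1.0 - dominant) / 3.0)
    for i, base in enumerate(_DEFAULT_CONSENSUS):
        pwm[i, BASES.index(base)] = dominant
    return pwm


@dataclass
class GeneratorSpec:
    pwm: np.ndarray = field(default_factory=default_pwm)
    seq_len: int = 1000
    n_pos: int = 1000
    n_neg: int = 1000
    bump_amplitude: float = 2.0
    bump_sd: float = 75.0
    baseline_noise_sd: float = 0.05
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be k x 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("pwm rows must sum to 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")

    @property
    def motif_width(self) -> int:
        return self.pwm.shape[0]

    def base_probs(self) -> np.ndarray:
        gc, at = self.gc_content / 2.0, (1.0 - self.gc_content) / 2.0
        return np.array([at, gc, gc, at])  # A C G T


@dataclass
class TruthRecord:
    """Where the signal-bearing element was planted."""

    position: int  # start offset of the motif instance (or inserted core)
    center: int  # center of the motif instance == bump center


def _background_seq(spec: GeneratorSpec, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=spec.seq_len, p=spec.base_probs())
    return "".join(BASES[i] for i in idx)


def _baseline_signal(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    return np.abs(rng.normal(0.0, spec.baseline_noise_sd, size=spec.seq_len))


def _draw_motif(spec: GeneratorSpec, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=spec.pwm[i])] for i in range(spec.motif_width)
    )


def _bump(spec: GeneratorSpec, center: int) -> np.ndarray:
    x = np.arange(spec.seq_len)
    return spec.bump_amplitude * np.exp(-((x - center) ** 2) / (2.0 * spec.bump_sd**2))


def sample_background(
    spec: GeneratorSpec, n: int, rng: np.random.Generator | None = None
) -> tuple[list[str], np.ndarray]:
    """n i.i.d. background sequences with near-flat noise signals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    seqs, signals = [], np.empty((n, spec.seq_len))
    for i in range(n):
        seqs.append(_background_seq(spec, rng))
        signals[i] = _baseline_signal(spec, rng)
    return seqs, signals


def plant_motif_with_signal(
    spec: GeneratorSpec,
    position: int | str = "random",
    rng: np.random.Generator | None = None,
    margin: int = 50,
) -> tuple[str, np.ndarray, TruthRecord]:
    """One positive item: background + one PWM draw + Gaussian bump.

    The bump is centered on the planted instance's center.  With
    position="random" the motif start is uniform inside the margins.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = spec.motif_width
    if position == "random":
        lo, hi = margin, spec.seq_len - k - margin
        position = int(rng.integers(lo, hi + 1))
    if not 0 <= position <= spec.seq_len - k:
        raise ValueError(f"motif position {position} out of range")
    seq = _background_seq(spec, rng)
    seq = seq[:position] + _draw_motif(spec, rng) + seq[position + k :]
    center = position + k // 2
    signal = _baseline_signal(spec, rng) + _bump(spec, center)
    return seq, signal, TruthRecord(position, center)


SHIFT_CENTERS = (250, 500, 750)


def shift_experiment_set(
    spec: GeneratorSpec, n_per_center: int = 100
) -> list[tuple[str, np.ndarray, TruthRecord]]:
    """Benchmark with planted centers fixed at 250, 500 and 750 bp."""
    if spec.seq_len != 1000:
        raise ValueError("the shift benchmark is defined for 1000-bp sequences")
    rng = np.random.default_rng(spec.seed + 101)
    items = []
    for center in SHIFT_CENTERS:
        position = center - spec.motif_width // 2
        for _ in range(n_per_center):
            items.append(plant_motif_with_signal(spec, position, rng))
    return items


def insertion_experiment_set(
    spec: GeneratorSpec, core_width: int = 100, n: int = 100
) -> list[tuple[str, np.ndarray, TruthRecord]]:
    """Benchmark with a motif-bearing core inserted at random offsets.

    Each item is a background sequence in which a ``core_width`` window
    (motif at the core's center) replaces the original bases at a
    uniformly random valid offset; total length is preserved and the
    truth records the insertion offset.
    """
    if core_width >= spec.seq_len:
        raise ValueError("core_width must be smaller than seq_len")
    rng = np.random.default_rng(spec.seed + 202)
    k = spec.motif_width
    core_motif_at = core_width // 2 - k // 2
    items = []
    for _ in range(n):
        core = _background_seq(spec, rng)[:core_width]
        core = (
            core[:core_motif_at]
            + _draw_motif(spec, rng)
            + core[core_motif_at + k :]
        )
        offset = int(rng.integers(0, spec.seq_len - core_width + 1))
        seq = _background_seq(spec, rng)
        seq = seq[:offset] + core + seq[offset + core_width :]
        center = offset + core_motif_at + k // 2
        signal = _baseline_signal(spec, rng) + _bump(spec, center)
        items.append((seq, signal, TruthRecord(offset, center)))
    return items


def make_samples(
    spec: GeneratorSpec, chrom: str = "synth"
) -> tuple[list[Sample], list[TruthRecord | None]]:
    """Build a supervised sample list (positives first, then negatives).

    Signals are emitted on the normalized scale directly, mirroring the
    log-transformed tracks real datasets produce.  Synthetic coordinates
    tile a pseudo-chromosome so interval bookkeeping stays valid.
    """
    rng = np.random.default_rng(spec.seed)
    samples, truths = [], []
    for i in range(spec.n_pos):
        seq, signal, truth = plant_motif_with_signal(spec, "random", rng)
        iv = GenomicInterval(chrom, i * spec.seq_len, (i + 1) * spec.seq_len)
        track = SignalTrack(iv, signal, normalized=True)
        peak = PeakRecord(iv, summit=truth.center, max_signal=float(signal.max()))
        samples.append(Sample(one_hot_encode(seq), track, 1, peak))
        truths.append(truth)
    neg_seqs, neg_signals = sample_background(spec, spec.n_neg, rng)
    offset = spec.n_pos * spec.seq_len
    for i, (seq, signal) in enumerate(zip(neg_seqs, neg_signals)):
        iv = GenomicInterval(
            chrom, offset + i * spec.seq_len, offset + (i + 1) * spec.seq_len
        )
        track = SignalTrack(iv, signal, normalized=True)
        samples.append(Sample(one_hot_encode(seq), track, 0, PeakRecord(iv)))
        truths.append(None)
    return samples, truths


def simulate_dataset(spec: GeneratorSpec, out_dir) -> None:
    """Emit the prepared-dataset directory layout plus a truth TSV."""
    import os

    from .seqdata import save_dataset, split_random

    samples, truths = make_samples(spec)
    split = split_random(samples, seed=spec.seed)
    save_dataset(split, out_dir)
    truth_by_id = {id(s): t for s, t in zip(samples, truths)}
    rows = ["id\tplanted_offset\tplanted_center"]
    i = 0
    for name in ("train", "validation", "test"):
        for s in getattr(split, name):
            t = truth_by_id[id(s)]
            if t is None:
                rows.append(f"{i}\t-1\t-1")
            else:
                rows.append(f"{i}\t{t.position}\t{t.center}")
            i += 1
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
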