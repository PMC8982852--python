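"""Genomic data types and dataset assembly.

Reads FASTA / BED / bedGraph inputs and turns peak calls plus per-base
signal tracks into supervised samples: a one-hot encoded fixed-length
window, a log-normalized per-base signal, and a binary bound/unbound
label.  Coordinates are BED-style 0-based half-open throughout; summits
are offsets from the interval start.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "SignalTrack",
    "OneHotSequence",
    "Sample",
    "DatasetSplit",
    "read_fasta",
    "read_bed_intervals",
    "read_signal_track",
    "one_hot_encode",
    "decode_one_hot",
    "expand_peak",
    "make_negative",
    "normalize_signal",
    "split_random",
    "split_chromosomal",
    "build_samples",
    "save_dataset",
    "load_dataset",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FastaParseError(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakRecord:
    """A called peak, optionally carrying its signal summit."""

    interval: GenomicInterval
    summit: int | None = None  # offset from interval.start
    max_signal: float | None = None

    def __post_init__(self):
        if self.summit is not None and not (0 <= self.summit < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{self.interval.length}"
            )


@dataclass
class SignalTrack:
    """Per-base real-valued signal aligned to an interval."""

    interval: GenomicInterval
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != self.interval.length:
            raise ValueError(
                f"signal length {len(self.values)} != interval length "
                f"{self.interval.length}"
            )


@dataclass
class OneHotSequence:
    """L x 4 binary encoding of DNA; column order A, C, G, T."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("one-hot matrix must be L x 4 with L >= 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Sample:
    x: OneHotSequence
    y: SignalTrack
    label: int
    source: PeakRecord

    def __post_init__(self):
        if len(self.x) != self.y.interval.length:
            raise ValueError("sequence and signal lengths differ")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA into a dict.

    Sequences are uppercased; record order is preserved.
    """
    records = {}
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected FASTA header '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals; empty intervals are dropped with a warning."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                warnings.warn(
                    f"{path}:{lineno}: rejected record with start >= end "
                    f"({chrom}:{start}-{end})"
                )
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def read_signal_track(
    path: str | os.PathLike, interval: GenomicInterval
) -> SignalTrack:
    """Extract per-base values over `interval` from a bedGraph file.

    Uncovered bases are 0; overlapping records are resolved last-wins in
    file order.  A chromosome absent from the track yields an all-zero
    track with a warning.
    """
    values = np.zeros(interval.length, dtype=np.float64)
    seen_chrom = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            if fields[0] != interval.chrom:
                continue
            seen_chrom = True
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            lo = max(start, interval.start)
            hi = min(end, interval.end)
            if lo < hi:
                values[lo - interval.start : hi - interval.start] = value
    if not seen_chrom:
        warnings.warn(
            f"{path}: chromosome {interval.chrom} absent from track; "
            "returning zeros"
        )
    return SignalTrack(interval, values, normalized=False)


def one_hot_encode(seq: str) -> OneHotSequence:
    """Encode DNA as L x 4 {0,1}; non-ACGT symbols become all-zero rows."""
    if not seq:
        raise ValueError("cannot one-hot encode an empty sequence")
    seq = seq.upper()
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    matrix = np.zeros((len(seq), 4), dtype=np.float32)
    for base, col in _BASE_INDEX.items():
        matrix[idx == ord(base), col] = 1.0
    return OneHotSequence(matrix)


def decode_one_hot(onehot: OneHotSequence) -> str:
    """Inverse of `one_hot_encode` for ACGT-only sequences ('N' for zero rows)."""
    m = onehot.matrix
    letters = np.array(list(BASES + "N"))
    cols = np.where(m.sum(axis=1) > 0, m.argmax(axis=1), 4)
    return "".join(letters[cols])


def expand_peak(
    peak: PeakRecord, target_len: int, chrom_len: int
) -> GenomicInterval:
    """Expand/shrink a peak to exactly `target_len`, centered on its summit.

    Falls back to the interval midpoint when no summit is recorded.
    Windows running past either chromosome end are shifted inward.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if chrom_len < target_len:
        raise ValueError(
            f"chromosome length {chrom_len} < target length {target_len}"
        )
    iv = peak.interval
    if peak.summit is not None:
        center = iv.start + peak.summit
    else:
        center = iv.start + iv.length // 2
    start = center - target_len // 2
    start = min(max(start, 0), chrom_len - target_len)
    return GenomicInterval(iv.chrom, start, start + target_len, iv.strand)


def make_negative(
    peak_interval: GenomicInterval, gap: int = 3000
) -> tuple[GenomicInterval, bool]:
    """Place an equal-length negative window `gap` bp upstream of a peak.

    "Upstream" means lower coordinates regardless of strand.  When there
    is not enough room before the chromosome start the window is placed
    downstream instead and flagged.  Returns (interval, downstream_flag).
    """
    length = peak_interval.length
    start = peak_interval.start - gap - length
    if start >= 0:
        return (
            GenomicInterval(
                peak_interval.chrom, start, start + length, peak_interval.strand
            ),
            False,
        )
    ds_start = peak_interval.end + gap
    return (
        GenomicInterval(
            peak_interval.chrom, ds_start, ds_start + length, peak_interval.strand
        ),
        True,
    )


def normalize_signal(track: SignalTrack) -> SignalTrack:
    """Apply the log10(1 + v) normalization to a raw track."""
    if track.normalized:
        raise ValueError("track is already normalized")
    if np.any(track.values < 0):
        raise ValueError("raw signal values must be non-negative")
    return SignalTrack(track.interval, np.log10(1.0 + track.values), normalized=True)


def split_random(samples: list, seed: int) -> DatasetSplit:
    """80/20 train+val/test split, then 10% of the 80% as validation.

    Sizes are taken by floor with the remainder going to train; the
    permutation is deterministic under `seed`.
    """
    n = len(samples)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(n * 0.2)
    n_rest = n - n_test
    n_val = int(n_rest * 0.1)
    if n_test == 0 or n_val == 0:
        raise ValueError(f"too few samples ({n}) to populate all three splits")
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    return DatasetSplit(
        train=[samples[i] for i in train_idx],
        validation=[samples[i] for i in val_idx],
        test=[samples[i] for i in test_idx],
    )


def split_chromosomal(
    samples: list, test_chrom: str = "chr17", val_chrom: str = "chr18"
) -> DatasetSplit:
    """Hold out whole chromosomes for test and validation."""
    split = DatasetSplit()
    for s in samples:
        chrom = s.source.interval.chrom
        if chrom == test_chrom:
            split.test.append(s)
        elif chrom == val_chrom:
            split.validation.append(s)
        else:
            split.train.append(s)
    if not split.test:
        warnings.warn(f"no samples on test chromosome {test_chrom}")
    if not split.validation:
        warnings.warn(f"no samples on validation chromosome {val_chrom}")
    return split


def build_samples(
    genome: dict[str, str],
    peaks: list[PeakRecord],
    signal_path: str | os.PathLike,
    target_len: int = 1000,
    gap: int = 3000,
) -> list[Sample]:
    """Assemble positive and negative samples from peaks + a signal track.

    Each peak yields a positive window of `target_len` centered on the
    summit and a negative window `gap` bp upstream; both carry their real
    extracted signals, log10(1+v)-normalized.  Negatives overlapping
    other peaks are not filtered.
    """
    samples = []
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in genome:
            warnings.warn(f"peak chromosome {chrom} absent from genome; skipped")
            continue
        chrom_len = len(genome[chrom])
        pos_iv = expand_peak(peak, target_len, chrom_len)
        neg_iv, downstream = make_negative(pos_iv, gap)
        if neg_iv.end > chrom_len:
            warnings.warn(
                f"no room for a negative window near {chrom}:{pos_iv.start}; skipped"
            )
            neg_iv = None
        for iv, label in ((pos_iv, 1), (neg_iv, 0)):
            if iv is None:
                continue
            seq = genome[chrom][iv.start : iv.end]
            track = normalize_signal(read_signal_track(signal_path, iv))
            src = PeakRecord(iv, summit=None, max_signal=float(track.values.max()))
            samples.append(Sample(one_hot_encode(seq), track, label, src))
    return samples


# --- prepared-dataset directory layout -------------------------------------
#
#   X.npy        (N, 4, L) float32 one-hot, channels-first
#   Y.npy        (N, L) float32 normalized signal
#   manifest.tsv id, chrom, start, end, label, summit, split

_SPLIT_NAMES = ("train", "validation", "test")


def save_dataset(split: DatasetSplit, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    xs, ys, rows = [], [], []
    i = 0
    for name in _SPLIT_NAMES:
        for s in getattr(split, name):
            xs.append(s.x.matrix.T.astype(np.float32))
            ys.append(s.y.values.astype(np.float32))
            iv = s.source.interval
            summit = s.source.summit if s.source.summit is not None else -1
            rows.append(
                f"{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{s.label}\t{summit}\t{name}"
            )
            i += 1
    np.save(os.path.join(out_dir, "X.npy"), np.stack(xs))
    np.save(os.path.join(out_dir, "Y.npy"), np.stack(ys))
    with open(os.path.join(out_dir, "manifest.tsv"), "w") as fh:
        fh.write("id\tchrom\tstart\tend\tlabel\tsummit\tsplit\n")
        fh.write("\n".join(rows) + "\n")


def load_dataset(data_dir: str | os.PathLike) -> DatasetSplit:
    X = np.load(os.path.join(data_dir, "X.npy"))
    Y = np.load(os.path.join(data_dir, "Y.npy"))
    split = DatasetSplit()
    with open(os.path.join(data_dir, "manifest.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            i, chrom, start, end, label, summit, name = line.rstrip("\n").split("\t")
            i = int(i)
            iv = GenomicInterval(chrom, int(start), int(end))
            track = SignalTrack(iv, Y[i].astype(np.float64), normalized=True)
            summit = None if int(summit) < 0 else int(summit)
            sample = Sample(
                OneHotSequence(X[i].T), track, int(label), PeakRecord(iv, summit)
            )
            getattr(split, name).append(sample)
    return split
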