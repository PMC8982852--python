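"""Downstream tasks derived from predicted per-base signals.

Everything here reduces to the maximum of the predicted signal: the
binding probability is sigmoid(max), the binding region is a fixed-width
window around the argmax, chromosome scanning thresholds window maxima,
and variant scores are absolute ref/alt signal differences at the
variant position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .network import SignalModel
from .seqdata import GenomicInterval, one_hot_encode

__all__ = [
    "LocatedRegion",
    "SNPRecord",
    "predict_signal",
    "classify_sequence",
    "locate_binding_region",
    "scan_chromosome",
    "score_snp",
    "compute_openness",
]


@dataclass
class LocatedRegion:
    interval: GenomicInterval
    peak_position: int  # absolute argmax coordinate
    max_signal: float
    score: float  # sigmoid(max_signal), in [0, 1]

    def to_bed6(self, name: str = ".") -> str:
        iv = self.interval
        return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{self.score:.6f}\t."


@dataclass
class SNPRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    score: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")


def _pad_to_multiple(x: np.ndarray, multiple: int) -> np.ndarray:
    """Right-pad an (L, 4) one-hot matrix with all-zero rows ('N' bases)."""
    extra = (-x.shape[0]) % multiple
    if extra == 0:
        return x
    return np.pad(x, ((0, extra), (0, 0)))


def predict_signal(seq: str, model: SignalModel) -> np.ndarray:
    """Predict per-base signal for a sequence of arbitrary length >= the
    model's length multiple; the input is right-padded with N to the next
    multiple and the output trimmed back."""
    multiple = model.config.input_len_multiple
    if len(seq) < multiple:
        raise ValueError(
            f"sequence length {len(seq)} < {multiple}; provide at least one "
            "full window (pad with N if needed)"
        )
    x = _pad_to_multiple(one_hot_encode(seq).matrix, multiple)
    out = model.forward(x.T[None])
    return out[0, : len(seq)].astype(np.float64)


def classify_sequence(signal: np.ndarray) -> float:
    """Binding probability: sigmoid of the signal maximum."""
    signal = np.asarray(signal)
    if signal.size == 0:
        raise ValueError("empty signal")
    return float(expit(signal.max()))


def _centered_window(center: int, width: int, lo: int, hi: int) -> tuple[int, int]:
    start = center - width // 2
    start = min(max(start, lo), hi - width)
    return start, start + width


def locate_binding_region(
    signal: np.ndarray, window_offset: GenomicInterval, width: int = 60
) -> LocatedRegion:
    """Extract the fixed-width region around the signal argmax.

    First occurrence wins on ties; the extraction window is clipped
    inward at the edges of the scanned window.
    """
    signal = np.asarray(signal)
    if width > len(signal):
        raise ValueError(f"width {width} > signal length {len(signal)}")
    offset = int(signal.argmax())
    peak_abs = window_offset.start + offset
    start, end = _centered_window(
        peak_abs, width, window_offset.start, window_offset.end
    )
    mx = float(signal[offset])
    return LocatedRegion(
        GenomicInterval(window_offset.chrom, start, end),
        peak_abs,
        mx,
        float(expit(mx)),
    )


def scan_chromosome(
    chrom_seq: str,
    model: SignalModel,
    window: int = 1000,
    threshold: float = 1.5,
    width: int = 60,
    chrom: str = "chrom",
    batch_size: int = 64,
) -> list[LocatedRegion]:
    """Segment a chromosome into consecutive windows and report every
    window whose predicted maximum exceeds the threshold.

    The final partial window is N-padded rather than dropped.  Only the
    forward strand is scanned.
    """
    L = len(chrom_seq)
    if L < window:
        raise ValueError(f"sequence length {L} < window {window}")
    multiple = model.config.input_len_multiple
    if window % multiple != 0:
        raise ValueError(f"window {window} not divisible by {multiple}")
    n_windows = -(-L // window)  # ceil
    onehot = one_hot_encode(chrom_seq).matrix
    if n_windows * window > L:
        onehot = np.pad(onehot, ((0, n_windows * window - L), (0, 0)))
    X = onehot.reshape(n_windows, window, 4).transpose(0, 2, 1)

    regions = []
    for lo in range(0, n_windows, batch_size):
        preds = model.forward(X[lo : lo + batch_size])
        for j, signal in enumerate(preds):
            w = lo + j
            valid = min(window, L - w * window)  # ignore the padded tail
            signal = signal[:valid]
            if signal.max() > threshold:
                iv = GenomicInterval(chrom, w * window, w * window + valid)
                regions.append(locate_binding_region(signal, iv, width))
    return regions


def score_snp(
    genome: dict[str, str],
    snp: SNPRecord,
    model: SignalModel,
    window: int = 1000,
) -> float:
    """|alt - ref| predicted signal at the variant position, within a
    window centered on it (shifted inward at chromosome ends)."""
    seq = genome[snp.chrom]
    if snp.pos < 0 or snp.pos >= len(seq):
        raise ValueError(f"position {snp.pos} outside {snp.chrom}")
    start, end = _centered_window(snp.pos, window, 0, len(seq))
    ref_seq = seq[start:end].upper()
    i = snp.pos - start
    if ref_seq[i] != snp.ref.upper():
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: genome has "
            f"{ref_seq[i]!r}, record says {snp.ref!r}"
        )
    alt_seq = ref_seq[:i] + snp.alt.upper() + ref_seq[i + 1 :]
    y_ref = predict_signal(ref_seq, model)
    y_alt = predict_signal(alt_seq, model)
    return float(abs(y_alt[i] - y_ref[i]))


def compute_openness(peak: GenomicInterval, reads: list[GenomicInterval]) -> float:
    """log10(1 + number of reads overlapping the peak by >= 1 bp)."""
    if reads:
        chroms = np.array([r.chrom for r in reads])
        starts = np.array([r.start for r in reads])
        ends = np.array([r.end for r in reads])
        count = int(
            np.sum((chroms == peak.chrom) & (starts < peak.end) & (ends > peak.start))
        )
    else:
        count = 0
    return float(np.log10(1.0 + count))
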