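"""Position-frequency-matrix extraction from first-layer convolution scores.

High-signal 100-bp regions are located from per-base signals; the
trained first convolutional layer is slid over each region (both
strands) and, for the best-scoring filter overall, each region's
maximal-activation k-mer is collected.  Aligned k-mers give the PFM,
written out in minimal MEME motif format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .network import SignalModel
from .seqdata import BASES, one_hot_encode

__all__ = [
    "PFMotif",
    "reverse_complement",
    "filter_activations",
    "select_subregions",
    "build_pfm",
    "write_meme_motif",
    "read_meme_motif",
    "best_alignment_correlation",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PFMotif:
    """Per-position base counts over aligned equal-length sequences."""

    counts: np.ndarray  # k x 4 integers, A C G T
    n_sequences: int
    pseudocount: float = 0.25

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be k x 4")
        if not np.all(self.counts.sum(axis=1) == self.n_sequences):
            raise ValueError("every counts row must sum to n_sequences")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        p = (self.counts + self.pseudocount) / (
            self.n_sequences + 4.0 * self.pseudocount
        )
        return p

    def reverse_complement(self) -> "PFMotif":
        return PFMotif(self.counts[::-1, ::-1].copy(), self.n_sequences, self.pseudocount)


def filter_activations(region_onehot: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid-mode activations of all filters over a region.

    region_onehot: (L, 4); W: (F, 4, k); b: (F,).  Returns (F, L-k+1).
    """
    L, _ = region_onehot.shape
    F, _, k = W.shape
    if L < k:
        raise ValueError(f"region length {L} < filter width {k}")
    sw = np.lib.stride_tricks.sliding_window_view(region_onehot, k, axis=0)  # P,4,k
    return np.einsum("pck,fck->fp", sw, W) + b[:, None]


def _region_bounds(center: int, width: int, length: int) -> tuple[int, int]:
    start = center - width // 2
    start = min(max(start, 0), max(length - width, 0))
    return start, min(start + width, length)


def select_subregions(
    samples: list[tuple[str, np.ndarray]],
    model: SignalModel,
    region_width: int = 100,
    top_filters: int = 1,
    both_strands: bool = True,
) -> list[list[str]]:
    """Collect each sample's maximal-activation k-mer for the best filter(s).

    For every (sequence, signal) pair the ``region_width`` window centered
    on the signal argmax is scanned with all first-layer filters; filters
    are ranked by the mean of per-sample maximal activations and each
    sample contributes its best k-mer window (leftmost on ties, forward
    strand preferred) for each of the ``top_filters`` best filters.
    Returns one k-mer list per selected filter, best filter first.
    """
    if not samples:
        raise ValueError("no samples supplied")
    conv = model.enc[0].conv
    W = np.asarray(conv.params["W"], dtype=np.float64)
    b = np.asarray(conv.params["b"], dtype=np.float64)
    F, _, k = W.shape

    best_scores = np.empty((len(samples), F))
    best_kmers: list[list[str]] = []
    for si, (seq, signal) in enumerate(samples):
        seq = seq.upper()
        signal = np.asarray(signal)
        if len(seq) != len(signal):
            raise ValueError("sequence and signal lengths differ")
        lo, hi = _region_bounds(int(signal.argmax()), region_width, len(seq))
        region = seq[lo:hi]
        acts = filter_activations(one_hot_encode(region).matrix, W, b)
        pos = acts.argmax(axis=1)
        score = np.take_along_axis(acts, pos[:, None], axis=1)[:, 0]
        kmers = [region[p : p + k] for p in pos]
        if both_strands:
            region_rc = reverse_complement(region)
            acts_rc = filter_activations(one_hot_encode(region_rc).matrix, W, b)
            pos_rc = acts_rc.argmax(axis=1)
            score_rc = np.take_along_axis(acts_rc, pos_rc[:, None], axis=1)[:, 0]
            for f in range(F):
                if score_rc[f] > score[f]:  # forward strand wins ties
                    score[f] = score_rc[f]
                    kmers[f] = region_rc[pos_rc[f] : pos_rc[f] + k]
        best_scores[si] = score
        best_kmers.append(kmers)

    ranking = np.argsort(-best_scores.mean(axis=0), kind="stable")
    return [
        [best_kmers[si][f] for si in range(len(samples))]
        for f in ranking[:top_filters]
    ]


def build_pfm(kmers: list[str], pseudocount: float = 0.25) -> PFMotif:
    """Positional base counts of equal-length ACGT k-mers.

    K-mers containing non-ACGT symbols are dropped with a warning.
    """
    import warnings

    clean = [s.upper() for s in kmers if set(s.upper()) <= set(BASES)]
    if len(clean) < len(kmers):
        warnings.warn(f"dropped {len(kmers) - len(clean)} k-mers with non-ACGT symbols")
    if not clean:
        raise ValueError("no valid k-mers to build a PFM from")
    widths = {len(s) for s in clean}
    if len(widths) != 1:
        raise ValueError(f"k-mers have unequal lengths: {sorted(widths)}")
    k = widths.pop()
    counts = np.zeros((k, 4), dtype=np.int64)
    for s in clean:
        for j, base in enumerate(s):
            counts[j, BASES.index(base)] += 1
    return PFMotif(counts, len(clean), pseudocount)


def write_meme_motif(
    motif: PFMotif, name: str, path: str | os.PathLike, background=None
) -> None:
    """Write one motif in minimal MEME format."""
    bg = background or (0.25, 0.25, 0.25, 0.25)
    probs = motif.probabilities
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {motif.width} "
        f"nsites= {motif.n_sequences} E= 0",
    ]
    for row in probs:
        lines.append(" " + " ".join(f"{v:.6f}" for v in row))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme_motif(path: str | os.PathLike) -> tuple[str, np.ndarray, int]:
    """Read back a minimal MEME motif file: (name, probabilities, nsites)."""
    name, nsites, width = None, 0, 0
    probs: list[list[float]] = []
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix:"):
                fields = line.replace("=", " = ").split()
                width = int(fields[fields.index("w") + 2])
                if "nsites" in fields:
                    nsites = int(fields[fields.index("nsites") + 2])
                for _ in range(width):
                    probs.append([float(v) for v in next(lines).split()])
    if name is None or not probs:
        raise ValueError(f"{path}: no MEME motif found")
    return name, np.asarray(probs), nsites


def best_alignment_correlation(
    probs_a: np.ndarray, probs_b: np.ndarray, min_overlap: int | None = None
) -> tuple[float, int]:
    """Best gapless-alignment mean per-position Pearson r of two k x 4
    probability matrices.

    By default the shorter matrix must lie fully inside the longer one
    (for equal widths only offset 0 is tested); ``min_overlap`` relaxes
    this to partial overlaps of at least that many columns.  Returns
    (mean r, offset of the shorter within the longer; negated when the
    first matrix is the longer one).
    """
    a, b = np.asarray(probs_a, dtype=np.float64), np.asarray(probs_b, dtype=np.float64)
    flip = a.shape[0] > b.shape[0]
    short, long_ = (b, a) if flip else (a, b)
    k, K = short.shape[0], long_.shape[0]
    lo, hi = 0, K - k
    if min_overlap is not None:
        if not 1 <= min_overlap <= k:
            raise ValueError("min_overlap must be in [1, shorter width]")
        lo, hi = min_overlap - k, K - min_overlap
    best_r, best_off = -np.inf, 0
    for off in range(lo, hi + 1):
        rs = []
        for i in range(k):
            j = off + i
            if not 0 <= j < K:
                continue
            u, v = short[i] - short[i].mean(), long_[j] - long_[j].mean()
            denom = np.sqrt((u @ u) * (v @ v))
            rs.append(u @ v / denom if denom > 0 else 0.0)
        r = float(np.mean(rs))
        if r > best_r:
            best_r, best_off = r, off
    return best_r, (-best_off if flip else best_off)
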