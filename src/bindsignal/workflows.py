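"""End-to-end synthetic workflows shared by the acceptance suite and the
acceptance report script.

Everything here is deterministic given a seed: dataset generation,
training, the perturbation benchmarks, motif extraction and SNP scoring
all derive their randomness from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import evaluation as ev
from .inference import SNPRecord, predict_signal, score_snp
from .motifs import best_alignment_correlation, build_pfm, select_subregions
from .network import ModelConfig, SignalModel
from .seqdata import DatasetSplit, decode_one_hot, split_random
from .synthdata import (
    GeneratorSpec,
    insertion_experiment_set,
    make_samples,
    shift_experiment_set,
)
from .training import TrainConfig, TrainingHistory, stack_samples, train_model

__all__ = [
    "SyntheticRun",
    "default_train_config",
    "run_synthetic_training",
    "heldout_metrics",
    "argmax_hit_rate",
    "benchmark_hit_rate",
    "insertion_hit_rate",
    "motif_recovery",
    "snp_discrimination",
]


def default_train_config(seed: int) -> TrainConfig:
    """Desk-scale defaults: batch size reduced from the published 500 so a
    single CPU gets enough optimizer steps per epoch."""
    return TrainConfig(
        learning_rate=0.01,
        adam_beta1=0.9,
        alpha=0.0,
        dropout=0.2,
        batch_size=64,
        max_epochs=8,
        patience=4,
        seed=seed,
    )


@dataclass
class SyntheticRun:
    spec: GeneratorSpec
    split: DatasetSplit
    model: SignalModel
    history: TrainingHistory
    truths: list = field(default_factory=list)


def run_synthetic_training(
    seed: int,
    n_pos: int = 2000,
    n_neg: int = 2000,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
) -> SyntheticRun:
    spec = GeneratorSpec(n_pos=n_pos, n_neg=n_neg, seed=seed)
    samples, truths = make_samples(spec)
    split = split_random(samples, seed=seed)
    config = train_config or default_train_config(seed)
    model, history = train_model(split, config, model_config)
    return SyntheticRun(spec, split, model, history, truths)


def heldout_metrics(run: SyntheticRun) -> dict:
    """AUC via sigmoid(max), pooled per-base Pearson r, MSE on the test split."""
    X, Y, labels = stack_samples(run.split.test)
    preds = np.concatenate(
        [run.model.forward(X[i : i + 200]) for i in range(0, len(X), 200)]
    )
    scores = expit(preds.max(axis=1))
    return {
        "auc": ev.auc(scores, labels),
        "prauc": ev.prauc(scores, labels),
        "pearson": ev.pearsonr(preds.ravel(), Y.ravel()),
        "mse": ev.mse_metric(preds.ravel(), Y.ravel()),
        "preds": preds,
        "labels": labels,
        "Y": Y,
    }


def argmax_hit_rate(run: SyntheticRun, tolerance: int = 50) -> float:
    """Fraction of held-out positives whose predicted argmax lies within
    ``tolerance`` bp of the planted center (truth from the sample summit)."""
    positives = [s for s in run.split.test if s.label == 1]
    X = np.stack([s.x.matrix.T for s in positives]).astype(np.float32)
    preds = np.concatenate(
        [run.model.forward(X[i : i + 200]) for i in range(0, len(X), 200)]
    )
    centers = np.array([s.source.summit for s in positives])
    return float(np.mean(np.abs(preds.argmax(axis=1) - centers) <= tolerance))


def _batch_items(items, model):
    X = np.stack(
        [np.asarray(_onehot(seq)) for seq, _, _ in items]
    )
    return np.concatenate(
        [model.forward(X[i : i + 200]) for i in range(0, len(X), 200)]
    )


def _onehot(seq):
    from .seqdata import one_hot_encode

    return one_hot_encode(seq).matrix.T.astype(np.float32)


def benchmark_hit_rate(run: SyntheticRun, n_per_center: int = 100, tolerance: int = 50):
    """Shift benchmark: predicted argmax within tolerance of 250/500/750."""
    items = shift_experiment_set(run.spec, n_per_center)
    preds = _batch_items(items, run.model)
    centers = np.array([t.center for _, _, t in items])
    hits = np.abs(preds.argmax(axis=1) - centers) <= tolerance
    return float(hits.mean()), {
        c: float(hits[centers == c].mean()) for c in sorted(set(centers.tolist()))
    }


def insertion_hit_rate(
    run: SyntheticRun, n: int = 100, core_width: int = 100, tolerance: int = 50
) -> float:
    """Insertion benchmark: argmax inside the inserted core +- tolerance."""
    items = insertion_experiment_set(run.spec, core_width, n)
    preds = _batch_items(items, run.model)
    hits = []
    for (seq, _, truth), pred in zip(items, preds):
        am = int(pred.argmax())
        hits.append(truth.position - tolerance <= am < truth.position + core_width + tolerance)
    return float(np.mean(hits))


def motif_recovery(run: SyntheticRun, n_samples: int = 300) -> dict:
    """Extract a PFM from high-signal regions and align it to the planted PWM."""
    positives = [s for s in run.split.train if s.label == 1][:n_samples]
    pairs = []
    for s in positives:
        seq = decode_one_hot(s.x)
        pairs.append((seq, predict_signal(seq, run.model)))
    (kmers,) = select_subregions(pairs, run.model, region_width=100)
    pfm = build_pfm(kmers)
    r_fwd, off_fwd = best_alignment_correlation(pfm.probabilities, run.spec.pwm)
    r_rc, off_rc = best_alignment_correlation(
        pfm.reverse_complement().probabilities, run.spec.pwm
    )
    if r_rc > r_fwd:
        return {"pfm": pfm, "r": r_rc, "offset": off_rc, "orientation": "rc"}
    return {"pfm": pfm, "r": r_fwd, "offset": off_fwd, "orientation": "fwd"}


class TruthRecordView:
    """Planted-motif coordinates reconstructed from a sample's summit."""

    def __init__(self, center: int, k: int):
        self.center = center
        self.position = center - k // 2


def snp_discrimination(run: SyntheticRun, n_each: int = 100, seed: int = 0) -> dict:
    """Scores of motif-core-disrupting substitutions vs background ones.

    Returns the two score arrays and the one-sided rank-sum p-value for
    motif scores exceeding background scores.
    """
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(seed + 77)
    pwm = run.spec.pwm
    k = pwm.shape[0]
    # positives carry the planted center as their summit; the motif start
    # is center - k//2 (do NOT pair split samples with the pre-split truth
    # list: the random split reorders samples)
    positives = []
    for s in run.split.train + run.split.validation + run.split.test:
        if s.label == 1 and s.source.summit is not None:
            positives.append((s, TruthRecordView(s.source.summit, k)))
    info = 2.0 + np.sum(pwm * np.log2(np.maximum(pwm, 1e-12)), axis=1)
    top_pos = int(np.argmax(info))  # highest-information motif column

    motif_scores, bg_scores = [], []
    idx = rng.permutation(len(positives))
    for which, scores in (("motif", motif_scores), ("background", bg_scores)):
        for j in idx:
            if len(scores) >= n_each:
                break
            sample, truth = positives[j]
            seq = decode_one_hot(sample.x)
            genome = {"v": seq}
            if which == "motif":
                pos = truth.position + top_pos
            else:
                # substitution placed >= 200 bp from the motif
                valid = [
                    p
                    for p in range(len(seq))
                    if abs(p - truth.center) >= 200
                ]
                pos = int(valid[rng.integers(len(valid))])
            ref = seq[pos]
            if which == "motif":
                consensus = "ACGT"[int(np.argmax(pwm[top_pos]))]
                if ref != consensus:
                    continue  # only disrupt intact consensus bases
                alt_choices = [b for b in "ACGT" if b != ref and pwm[top_pos]["ACGT".index(b)] < 0.5]
            else:
                alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[int(rng.integers(len(alt_choices)))]
            snp = SNPRecord("v", pos, ref, alt)
            scores.append(score_snp(genome, snp, run.model, window=1000))
    stat = mannwhitneyu(motif_scores, bg_scores, alternative="greater")
    return {
        "motif_scores": np.array(motif_scores),
        "background_scores": np.array(bg_scores),
        "p_value": float(stat.pvalue),
    }
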