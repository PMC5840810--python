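"""Discriminative additive motif optimization by perceptron error correction.

Starting from a probability matrix seed (log-odds transformed), the trainer
looks for the additive weight matrix — mononucleotide or adjacent
dinucleotide — that maximizes AUROC between positive and negative binding
sites.  Each epoch identifies the misclassified sites: positives scoring
below the best negative, and negatives scoring above the worst positive
(strict inequalities, so ties are not misclassified).  The weights of each
misclassified positive's observed bases (or adjacent pairs) are incremented
by the learning rate, and a misclassified negative's decremented, applied
sequentially in a seeded shuffled order.  Training AUROC is recorded after
every epoch and the returned model is the best snapshot seen — including the
untouched seed, so the optimized matrix can never rank worse than its seed
on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .metrics import auroc
from .motif_models import (
    PFM,
    PWM,
    DinucPWM,
    embed_mono_in_dinuc,
    pfm_to_seed_pwm,
    _checked_indices,
)

Model = Union[PWM, DinucPWM]


@dataclass
class TrainConfig:
    """Knobs of the perceptron trainer.

    learning_rate is the additive step applied per misclassified site and
    feature; it should be small relative to the log-odds scale of the seed
    (a Laplace-smoothed probability column spans at most a few nats).
    patience is the number of consecutive epochs without a new best training
    AUROC tolerated before stopping; None disables early stopping.
    """

    seed: int
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: Optional[int] = 45
    mode: str = "mono"  # "mono" | "dinuc"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience is not None and not 1 <= self.patience <= self.max_epochs:
            raise ValueError("patience must be in [1, max_epochs] or None")
        if self.mode not in ("mono", "dinuc"):
            raise ValueError(f"mode must be 'mono' or 'dinuc', got {self.mode!r}")


@dataclass
class TrainingTrace:
    """Per-epoch training AUROC plus the best snapshot.

    epoch_auroc[0] is the seed matrix's AUROC; best_epoch is the first epoch
    attaining best_auroc == max(epoch_auroc).
    """

    epoch_auroc: List[float]
    best_epoch: int
    best_auroc: float
    best_model: Model


def _site_matrix(sites: Sequence, width: int) -> np.ndarray:
    """(n, width) base-index matrix from sites (strings or ScoredSite)."""
    seqs = [s if isinstance(s, str) else s.site_seq for s in sites]
    if not seqs:
        raise ValueError("site list is empty")
    return np.stack([_checked_indices(s, width) for s in seqs])


def _feature_matrix(idx: np.ndarray, mode: str) -> np.ndarray:
    """Row indices of the updated/scored weights for each site."""
    if mode == "mono":
        return idx
    return 4 * idx[:, :-1] + idx[:, 1:]


def _scores(weights: np.ndarray, feats: np.ndarray) -> np.ndarray:
    return weights[feats, np.arange(feats.shape[1])].sum(axis=1)


def misclassified_sites(
    pos_scores, neg_scores
) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of positives below the best negative and negatives above the
    worst positive (strict comparisons: tied scores are not misclassified)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    pos_idx = np.nonzero(pos < neg.max())[0]
    neg_idx = np.nonzero(neg > pos.min())[0]
    return pos_idx, neg_idx


def perceptron_epoch(
    model: Model,
    pos_sites: Sequence,
    neg_sites: Sequence,
    learning_rate: float,
    rng: np.random.Generator,
) -> Model:
    """One error-correction pass; returns the updated model.

    Misclassified sites are identified once against the incoming model, then
    their updates are applied sequentially in an rng-shuffled order (the
    updates are additive, so the order only matters for reproducibility of
    the rng stream).
    """
    mode = "mono" if isinstance(model, PWM) else "dinuc"
    pos_feats = _feature_matrix(_site_matrix(pos_sites, model.width), mode)
    neg_feats = _feature_matrix(_site_matrix(neg_sites, model.width), mode)
    return _epoch_inplace(
        model.copy(), pos_feats, neg_feats, learning_rate, rng
    )


def _epoch_inplace(model, pos_feats, neg_feats, lr, rng):
    pos_idx, neg_idx = misclassified_sites(
        _scores(model.weights, pos_feats), _scores(model.weights, neg_feats)
    )
    updates = [(+1, i) for i in pos_idx] + [(-1, j) for j in neg_idx]
    if updates:
        order = rng.permutation(len(updates))
        cols = np.arange(pos_feats.shape[1])
        for k in order:
            sign, i = updates[k]
            feats = pos_feats[i] if sign > 0 else neg_feats[i]
            model.weights[feats, cols] += sign * lr
    return model


def train_damo(
    seed_pfm: PFM,
    pos_sites: Sequence,
    neg_sites: Sequence,
    config: TrainConfig,
    background=None,
) -> TrainingTrace:
    """Optimize a PWM (or adjacent-dinucleotide PWM) for training AUROC.

    The seed PFM is log-odds transformed; in dinuc mode the mono seed is
    embedded in the dinucleotide parameter space, which scores every site
    identically, so both modes start from the same ranking.  Epochs run until
    max_epochs, or until the best training AUROC has not improved for
    ``patience`` consecutive epochs.
    """
    if not pos_sites or not neg_sites:
        raise ValueError("both site classes must be non-empty")
    model: Model = pfm_to_seed_pwm(seed_pfm, background)
    if config.mode == "dinuc":
        model = embed_mono_in_dinuc(model)
    pos_feats = _feature_matrix(_site_matrix(pos_sites, model.width), config.mode)
    neg_feats = _feature_matrix(_site_matrix(neg_sites, model.width), config.mode)

    rng = np.random.default_rng(config.seed)

    def training_auroc(m):
        return auroc(_scores(m.weights, pos_feats), _scores(m.weights, neg_feats))

    trace = [training_auroc(model)]  # epoch 0 = seed
    best_auroc, best_epoch = trace[0], 0
    best_model = model.copy()
    stale = 0
    work = model.copy()
    for epoch in range(1, config.max_epochs + 1):
        work = _epoch_inplace(work, pos_feats, neg_feats, config.learning_rate, rng)
        a = training_auroc(work)
        if not np.isfinite(a):
            raise RuntimeError("non-finite training AUROC")
        trace.append(a)
        if a > best_auroc:
            best_auroc, best_epoch = a, epoch
            best_model = work.copy()
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale >= config.patience:
                break
    return TrainingTrace(trace, best_epoch, best_auroc, best_model)


def write_trace(trace: TrainingTrace, handle) -> None:
    """Tab-delimited (epoch, train_auroc) history."""
    handle.write("epoch\ttrain_auroc\n")
    for epoch, value in enumerate(trace.epoch_auroc):
        handle.write(f"{epoch}\t{repr(value)}\n")
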