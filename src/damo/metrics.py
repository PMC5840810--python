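"""Ranking metrics and cross-validated evaluation of binding-site scorers.

AUROC follows the Mann-Whitney convention (a tied positive/negative pair
counts one half), computed from rank sums.  AUPRC is non-interpolated average
precision with tied scores grouped, so a decision threshold can never split a
tie group — matrix scores over short sites tie often enough that the
convention is part of the contract, not a detail.

``cross_validate`` evaluates any scorer factory fold by fold and reports the
per-fold values along with mean and standard deviation (n-1 denominator) for
both metrics on both the training and the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .dataset_prep import SiteDataset

METRICS = ("auroc", "auprc")
SPLITS = ("train", "test")


def _check_scores(scores, what: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{what} score list is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} scores contain non-finite values")
    return arr


def auroc(pos_scores, neg_scores) -> float:
    """Probability a random positive outscores a random negative, ties half.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg, i.e.
    ``(#{pos > neg} + 0.5 * #{pos == neg}) / (n_pos * n_neg)``.
    """
    pos = _check_scores(pos_scores, "positive")
    neg = _check_scores(neg_scores, "negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auprc(pos_scores, neg_scores) -> float:
    """Non-interpolated average precision with tie groups.

    Sites are ranked by descending score; precision and recall are evaluated
    after each complete group of tied scores and AP accumulates
    precision x delta-recall over those steps.
    """
    pos = _check_scores(pos_scores, "positive")
    neg = _check_scores(neg_scores, "negative")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = pos.size
    ap = 0.0
    tp = 0.0
    seen = 0.0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        group_tp = labels[i:j].sum()
        prev_recall = tp / n_pos
        tp += group_tp
        seen += j - i
        recall = tp / n_pos
        precision = tp / seen
        ap += precision * (recall - prev_recall)
        i = j
    return float(ap)


@dataclass
class EvalSummary:
    """Cross-validation result for one model on one dataset.

    ``per_fold[(split, metric)]`` holds the per-fold values;
    ``mean[(split, metric)]`` and ``sd[(split, metric)]`` are their arithmetic
    mean and sample standard deviation.
    """

    model_name: str
    per_fold: dict
    dataset_id: str = ""

    def __post_init__(self):
        self.mean = {k: float(np.mean(v)) for k, v in self.per_fold.items()}
        self.sd = {
            k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for k, v in self.per_fold.items()
        }

    def gap(self, metric: str = "auprc") -> np.ndarray:
        """Per-fold train - test differences: the overfitting signature."""
        return np.asarray(self.per_fold[("train", metric)]) - np.asarray(
            self.per_fold[("test", metric)]
        )


ScorerFactory = Callable[[list, list], Callable[[list], np.ndarray]]


def cross_validate(
    scorer_factory: ScorerFactory,
    dataset: SiteDataset,
    model_name: str = "model",
    dataset_id: str = "",
) -> EvalSummary:
    """Train and evaluate a scorer on every fold of a paired site dataset.

    ``scorer_factory(train_pos, train_neg)`` must return a function mapping a
    list of sites to scores.  Untrained scorers (e.g. the raw seed PFM) are
    factories that ignore their training arguments.  For each fold the scorer
    is fitted on the other k-1 folds and both splits are scored, giving
    per-fold train/test AUROC and AUPRC.
    """
    per_fold = {(s, m): [] for s in SPLITS for m in METRICS}
    for fold in range(dataset.n_folds):
        tr_pos, tr_neg, te_pos, te_neg = dataset.split(fold)
        if not te_pos or not te_neg or not tr_pos or not tr_neg:
            raise ValueError(f"fold {fold} has an empty class")
        scorer = scorer_factory(tr_pos, tr_neg)
        for split, (p, n) in zip(SPLITS, [(tr_pos, tr_neg), (te_pos, te_neg)]):
            ps, ns = scorer(p), scorer(n)
            per_fold[("%s" % split, "auroc")].append(auroc(ps, ns))
            per_fold[("%s" % split, "auprc")].append(auprc(ps, ns))
    return EvalSummary(model_name, per_fold, dataset_id)


# ---------------------------------------------------------------------------
# comparison reports
# ---------------------------------------------------------------------------

def _group_by_model(summaries: Sequence[EvalSummary]) -> dict:
    groups: dict = {}
    for s in summaries:
        groups.setdefault(s.model_name, []).append(s)
    datasets = None
    for name, group in groups.items():
        ids = tuple(s.dataset_id for s in group)
        if datasets is None:
            datasets = ids
        elif ids != datasets:
            raise ValueError(
                f"model {name!r} evaluated on a different dataset collection"
            )
    return groups


def _model_stats(group: list, split: str, metric: str):
    """Mean/sd for a model: over datasets when several, else over folds."""
    if len(group) == 1:
        s = group[0]
        return s.mean[(split, metric)], s.sd[(split, metric)]
    vals = np.array([s.mean[(split, metric)] for s in group])
    return float(vals.mean()), float(vals.std(ddof=1))


def comparison_report(
    summaries: Sequence[EvalSummary],
    out_dir,
    metric: str = "auprc",
    pairs: Optional[Sequence[tuple]] = None,
) -> dict:
    """Write the standard model-comparison artifacts for one metric.

    Produces (a) ``comparison_table.tsv`` — one row per model with train and
    test mean (sd) formatted to three decimals, (b) ``train_test_gap.png`` —
    per-model boxplots of the train-test difference, and (c) for each
    requested model pair a scatter of per-dataset test scores plus the sorted
    per-dataset differences.  Models are grouped by name; every model must
    cover the same dataset collection.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = _group_by_model(summaries)
    if len(groups) < 2:
        raise ValueError("need summaries for at least 2 models")
    names = list(groups)
    written = {}

    # (a) table in the "0.812 (0.132)" style
    table_path = out_dir / f"comparison_table_{metric}.tsv"
    with open(table_path, "w") as fh:
        fh.write("model\ttraining\ttesting\n")
        for name in names:
            cells = [
                "%.3f (%.3f)" % _model_stats(groups[name], split, metric)
                for split in SPLITS
            ]
            fh.write(name + "\t" + "\t".join(cells) + "\n")
    written["table"] = table_path

    # (b) train - test gap distributions
    gaps = []
    for name in names:
        g = np.concatenate([s.gap(metric) for s in groups[name]])
        gaps.append(g)
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot(gaps, tick_labels=names, whis=1.5)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_ylabel(f"training - testing {metric.upper()}")
    fig.autofmt_xdate(rotation=30)
    gap_path = out_dir / f"train_test_gap_{metric}.png"
    fig.savefig(gap_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written["gap_plot"] = gap_path

    # (c) pairwise scatter + sorted differences
    if pairs is None:
        pairs = [(names[0], other) for other in names[1:]]
    pair_paths = []
    for a, b in pairs:
        xa = np.array([s.mean[("test", metric)] for s in groups[a]])
        xb = np.array([s.mean[("test", metric)] for s in groups[b]])
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        lo, hi = min(xa.min(), xb.min()) - 0.02, max(xa.max(), xb.max()) + 0.02
        ax1.plot([lo, hi], [lo, hi], color="grey", lw=0.5)
        ax1.scatter(xb, xa, s=12)
        ax1.set_xlabel(f"{b} test {metric.upper()}")
        ax1.set_ylabel(f"{a} test {metric.upper()}")
        diffs = np.sort(xa - xb)
        ax2.plot(np.arange(diffs.size), diffs, marker=".", lw=0.8)
        ax2.axhline(0.0, color="grey", lw=0.5)
        ax2.set_xlabel("dataset (sorted)")
        ax2.set_ylabel(f"{a} - {b} test {metric.upper()}")
        fig.tight_layout()
        path = out_dir / f"pair_{a}_vs_{b}_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        pair_paths.append(path)
    written["pair_plots"] = pair_paths
    return written
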