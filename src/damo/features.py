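"""Feature vectors for classifier-based binding-site models.

Binding sites can be fed to a generic binary classifier instead of a matrix
model.  Supported feature blocks, in fixed order:

* ``matrix_score`` — a single matrix-model score of the site;
* ``fourbit`` — the 4-bit sequence encoding (A=1000, T=0100, G=0010, C=0001;
  note the bit order is A,T,G,C, not alphabetical);
* ``shape`` — 8 per-position DNA structural descriptors (HelT, MGW, ProT,
  Roll and their second-order variants), min-max normalized on training data.

Shape values are consumed from files produced by external structure
predictors; this package never computes them from sequence.

The classifier itself is a pluggable contract: anything with
``fit(X, y, seed)`` returning an object whose ``predict_score(X)`` is
monotone in positive-class confidence.  The default adapter wraps
scikit-learn's gradient boosting classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .motif_models import MatrixModel, score_site

SHAPE_FEATURES = ("HelT", "MGW", "ProT", "Roll", "HelT2", "MGW2", "ProT2", "Roll2")

# bit order of the 4-bit code: A=1000, T=0100, G=0010, C=0001
_FOURBIT_POS = {"A": 0, "T": 1, "G": 2, "C": 3}

VARIANTS = ("4bit", "4bit+shape", "shape_only", "matrixscore+shape")


@dataclass
class ShapeTrack:
    """8 x width structural feature values for one site, rows in
    SHAPE_FEATURES order."""

    site_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 8:
            raise ValueError("shape track must be 8 x width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite shape values for {self.site_id!r}")

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureVector:
    site_id: str
    values: np.ndarray
    layout: tuple  # ((block_name, length), ...)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = sum(n for _, n in self.layout)
        if self.values.size != expected:
            raise ValueError(
                f"vector length {self.values.size} != layout total {expected}"
            )


def encode_4bit(site: str) -> FeatureVector:
    """Concatenated 4-bit one-hot codes, one per position."""
    out = np.zeros(4 * len(site))
    for i, base in enumerate(site.upper()):
        if base not in _FOURBIT_POS:
            raise ValueError(f"ambiguous base {base!r} in site {site!r}")
        out[4 * i + _FOURBIT_POS[base]] = 1.0
    return FeatureVector("", out, (("fourbit", out.size),))


@dataclass
class ShapeStats:
    """Per-feature min/max fitted on training tracks."""

    minima: np.ndarray
    maxima: np.ndarray


def normalize_shape(
    tracks: Sequence[ShapeTrack], stats: Optional[ShapeStats] = None
):
    """Min-max normalize shape tracks per feature.

    When ``stats`` is None the tracks are the training set and the per-feature
    min/max are fitted over all positions of all tracks; otherwise the given
    training statistics are applied and values outside [0, 1] are clamped.
    Features with zero range map to 0.5.
    """
    if stats is None:
        if not tracks:
            raise ValueError("cannot fit normalization on an empty track list")
        stacked = np.concatenate([t.values for t in tracks], axis=1)
        stats = ShapeStats(stacked.min(axis=1), stacked.max(axis=1))
    span = stats.maxima - stats.minima
    normalized = []
    for t in tracks:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (t.values - stats.minima[:, None]) / span[:, None]
        v = np.where(span[:, None] > 0, v, 0.5)
        normalized.append(ShapeTrack(t.site_id, np.clip(v, 0.0, 1.0)))
    return normalized, stats


def assemble_features(
    site,
    variant: str,
    model: Optional[MatrixModel] = None,
    shape: Optional[ShapeTrack] = None,
) -> FeatureVector:
    """Build one site's feature vector for a named model variant.

    Block order is fixed: [matrix_score] then/or [fourbit] then/or [shape].
    ``site`` may be a ScoredSite or a plain sequence string.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick from {VARIANTS}")
    seq = site if isinstance(site, str) else site.site_seq
    site_id = "" if isinstance(site, str) else site.parent_id
    blocks, layout = [], []
    if variant == "matrixscore+shape":
        if model is None:
            raise ValueError("variant 'matrixscore+shape' requires a matrix model")
        blocks.append(np.array([score_site(model, seq)]))
        layout.append(("matrix_score", 1))
    if variant in ("4bit", "4bit+shape"):
        fb = encode_4bit(seq)
        blocks.append(fb.values)
        layout.append(("fourbit", fb.values.size))
    if variant in ("4bit+shape", "shape_only", "matrixscore+shape"):
        if shape is None:
            raise ValueError(f"variant {variant!r} requires a shape track")
        if shape.width != len(seq):
            raise ValueError("shape track width does not match the site width")
        blocks.append(shape.values.reshape(-1))
        layout.append(("shape", shape.values.size))
    return FeatureVector(site_id, np.concatenate(blocks), tuple(layout))


def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Stack vectors sharing one layout into an (n, d) design matrix."""
    if not vectors:
        raise ValueError("no feature vectors")
    layout = vectors[0].layout
    for v in vectors:
        if v.layout != layout:
            raise ValueError("feature vectors have mismatched layouts")
    return np.stack([v.values for v in vectors])


# ---------------------------------------------------------------------------
# classifier contract
# ---------------------------------------------------------------------------

class GradientBoostingAdapter:
    """Default classifier: scikit-learn gradient boosting.

    Deterministic given the seed; ``predict_score`` is the positive-class
    probability, used downstream only for ranking.
    """

    def __init__(self, **params):
        self.params = params
        self._model = None

    def fit(self, vectors, labels, seed: int) -> "GradientBoostingAdapter":
        from sklearn.ensemble import GradientBoostingClassifier

        X = vectors if isinstance(vectors, np.ndarray) else feature_matrix(vectors)
        y = np.asarray(labels)
        clf = GradientBoostingClassifier(random_state=seed, **self.params)
        clf.fit(X, y)
        fitted = GradientBoostingAdapter(**self.params)
        fitted._model = clf
        return fitted

    def predict_score(self, vectors) -> np.ndarray:
        if self._model is None:
            raise ValueError("classifier has not been fitted")
        X = vectors if isinstance(vectors, np.ndarray) else feature_matrix(vectors)
        if X.ndim == 1:
            X = X[None, :]
        return self._model.predict_proba(X)[:, 1]


class LogisticAdapter:
    """Linear alternative classifier, useful as a PWM-equivalent baseline
    on the 4-bit encoding (a PWM is a linear function of that encoding)."""

    def __init__(self, **params):
        self.params = {"max_iter": 2000, **params}
        self._model = None

    def fit(self, vectors, labels, seed: int) -> "LogisticAdapter":
        from sklearn.linear_model import LogisticRegression

        X = vectors if isinstance(vectors, np.ndarray) else feature_matrix(vectors)
        clf = LogisticRegression(random_state=seed, **self.params)
        clf.fit(X, np.asarray(labels))
        fitted = LogisticAdapter(**self.params)
        fitted._model = clf
        return fitted

    def predict_score(self, vectors) -> np.ndarray:
        if self._model is None:
            raise ValueError("classifier has not been fitted")
        X = vectors if isinstance(vectors, np.ndarray) else feature_matrix(vectors)
        if X.ndim == 1:
            X = X[None, :]
        return self._model.decision_function(X)


# ---------------------------------------------------------------------------
# shape track file I/O
# ---------------------------------------------------------------------------

def write_shape_tracks(tracks: Sequence[ShapeTrack], handle: TextIO) -> None:
    """Tab-delimited: one row per (site_id, feature), width value columns."""
    if tracks:
        width = tracks[0].width
        cols = "\t".join(f"pos{i}" for i in range(width))
        handle.write(f"site_id\tfeature\t{cols}\n")
    for t in tracks:
        for f, row in zip(SHAPE_FEATURES, t.values):
            handle.write(
                t.site_id + "\t" + f + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def read_shape_tracks(handle: Union[TextIO, str, Path]) -> list:
    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            return read_shape_tracks(fh)
    handle.readline()  # header
    rows: dict = {}
    order: list = []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        site_id, feature = parts[0], parts[1]
        if site_id not in rows:
            rows[site_id] = {}
            order.append(site_id)
        rows[site_id][feature] = [float(v) for v in parts[2:]]
    tracks = []
    for site_id in order:
        feats = rows[site_id]
        missing = [f for f in SHAPE_FEATURES if f not in feats]
        if missing:
            raise ValueError(f"site {site_id!r} missing shape features {missing}")
        tracks.append(ShapeTrack(site_id, np.array([feats[f] for f in SHAPE_FEATURES])))
    return tracks
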