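"""Matrix models of transcription-factor binding specificity.

Three model families are supported:

* :class:`PFM` — position frequency matrix: per-position base probabilities,
  the probabilistic model distributed by motif databases such as JASPAR and
  the seed for discriminative optimization.
* :class:`PWM` — position weight matrix: additive per-position base weights.
  A site's score is the sum of the weights of its bases, so any strictly
  increasing transform of the weights' scale leaves rankings unchanged.
* :class:`DinucPWM` — adjacent-dinucleotide weight matrix: additive weights
  over the 16 possible base pairs at each pair of adjacent positions,
  capturing nearest-neighbour dependence that a mononucleotide matrix cannot.

Base order is fixed as A, C, G, T throughout; dinucleotide rows are ordered
first-base-major (AA, AC, AG, AT, CA, ..., TT).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO, Union

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G
DINUCS = [x + y for x in BASES for y in BASES]

_COL_SUM_TOL = 1e-9


class MotifFormatError(ValueError):
    """Raised when a motif file does not parse as the declared dialect."""


def _as_matrix(values, rows: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != rows:
        raise ValueError(f"{what} must be a {rows}xW matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite entries")
    return arr


@dataclass
class PFM:
    """Position frequency matrix: columns are base probability distributions."""

    probs: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.probs = _as_matrix(self.probs, 4, "PFM probs")
        if np.any(self.probs < 0):
            raise ValueError("PFM probabilities must be non-negative")
        colsums = self.probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COL_SUM_TOL):
            raise ValueError("every PFM column must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]


@dataclass
class PWM:
    """Additive position weight matrix over single bases (4 x width)."""

    weights: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.weights = _as_matrix(self.weights, 4, "PWM weights")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "PWM":
        return PWM(self.weights.copy(), self.name)


@dataclass
class DinucPWM:
    """Additive weight matrix over adjacent base pairs (16 x (width-1)).

    Column ``i`` holds the weights of the 16 possible dinucleotides spanning
    site positions ``(i, i+1)``; the model scores sites of length ``width``,
    one more than its number of columns.
    """

    weights: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.weights = _as_matrix(self.weights, 16, "DinucPWM weights")
        if self.weights.shape[1] < 1:
            raise ValueError("DinucPWM needs at least one dinucleotide column")

    @property
    def width(self) -> int:
        return self.weights.shape[1] + 1

    def copy(self) -> "DinucPWM":
        return DinucPWM(self.weights.copy(), self.name)


MatrixModel = Union[PFM, PWM, DinucPWM]


# ---------------------------------------------------------------------------
# sequence encoding helpers
# ---------------------------------------------------------------------------

_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to base indices (A=0,C=1,G=2,T=3); others become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw].astype(np.int64)


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


def _checked_indices(site: str, width: int) -> np.ndarray:
    if len(site) != width:
        raise ValueError(
            f"site length {len(site)} does not match model width {width}"
        )
    idx = encode_sequence(site)
    if np.any(idx < 0):
        raise ValueError(f"site {site!r} contains ambiguous bases")
    return idx


def dinuc_indices(idx: np.ndarray) -> np.ndarray:
    """Row indices of adjacent pairs given per-position base indices."""
    return 4 * idx[:-1] + idx[1:]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pfm(
    source: Union[str, TextIO],
    dialect: str = "auto",
    pseudocount: float = 1.0,
) -> PFM:
    """Read a JASPAR-style matrix and normalize counts to probabilities.

    Two dialects are understood: ``jaspar-raw`` (four unlabeled numeric rows
    in A, C, G, T order, optionally preceded by a ``>`` header) and
    ``jaspar-pfm`` (rows labeled ``A [ 1 2 ... ]``).  ``auto`` detects the
    labeled form.  Counts ``c`` are normalized per column as
    ``(c + pseudocount) / (sum(c) + 4 * pseudocount)``; the default
    pseudocount of 1 (Laplace) guarantees strictly positive probabilities so
    the result can seed a log-odds matrix.
    """
    if dialect not in ("auto", "jaspar-raw", "jaspar-pfm"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if isinstance(source, str):
        source = io.StringIO(source)
    name = ""
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            continue
        label = None
        body = line
        first = line.split(None, 1)[0]
        if first.upper() in BASE_INDEX and (len(line.split(None, 1)) > 1):
            rest = line.split(None, 1)[1]
            if dialect in ("jaspar-pfm", "auto"):
                label = first.upper()
                body = rest
        if dialect == "jaspar-pfm" and label is None:
            raise MotifFormatError(f"line {lineno}: expected a base label")
        body = body.replace("[", " ").replace("]", " ").replace(",", " ")
        try:
            values = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise MotifFormatError(f"line {lineno}: non-numeric entry") from exc
        if not values:
            continue
        key = label if label is not None else str(len(order))
        if key in rows:
            raise MotifFormatError(f"duplicate row for {key!r}")
        rows[key] = values
        order.append(key)
    if len(order) != 4:
        raise MotifFormatError(f"expected 4 numeric rows, found {len(order)}")
    labeled = all(k in BASE_INDEX for k in order)
    if labeled:
        matrix = [rows[b] for b in BASES]
    else:
        if any(k in BASE_INDEX for k in order):
            raise MotifFormatError("mixture of labeled and unlabeled rows")
        matrix = [rows[k] for k in order]
    lengths = {len(r) for r in matrix}
    if len(lengths) != 1:
        raise MotifFormatError(f"rows have unequal lengths {sorted(lengths)}")
    counts = np.asarray(matrix, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts in matrix")
    counts = counts + pseudocount
    colsums = counts.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError(
            "a column sums to zero; re-read with pseudocount > 0"
        )
    return PFM(counts / colsums, name=name)


def write_pfm(pfm: PFM, handle: TextIO) -> None:
    """Write a PFM in the labeled JASPAR dialect (probabilities, not counts)."""
    if pfm.name:
        handle.write(f">{pfm.name}\n")
    for i, base in enumerate(BASES):
        vals = " ".join(repr(float(v)) for v in pfm.probs[i])
        handle.write(f"{base} [ {vals} ]\n")


def write_matrix(model: MatrixModel, handle: TextIO) -> None:
    """Serialize any matrix model as tab-delimited text with a header line.

    Floats are written at repr precision, so a read/write round trip is
    bit-exact.
    """
    kind = type(model).__name__
    mat = model.probs if isinstance(model, PFM) else model.weights
    handle.write(f"#{kind}\twidth={model.width}\tname={model.name}\n")
    labels = BASES if mat.shape[0] == 4 else DINUCS
    for label, row in zip(labels, mat):
        handle.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(handle: TextIO) -> MatrixModel:
    """Inverse of :func:`write_matrix`."""
    header = handle.readline().strip()
    if not header.startswith("#"):
        raise MotifFormatError("missing model header line")
    fields = header[1:].split("\t")
    kind = fields[0]
    meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    name = meta.get("name", "")
    rows = []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    mat = np.asarray(rows, dtype=float)
    if kind == "PFM":
        return PFM(mat, name=name)
    if kind == "PWM":
        return PWM(mat, name=name)
    if kind == "DinucPWM":
        return DinucPWM(mat, name=name)
    raise MotifFormatError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def pfm_to_seed_pwm(pfm: PFM, background=None) -> PWM:
    """Log-odds seed matrix: ``w(b,i) = ln(p(b,i) / bg(b))``.

    The default background is uniform.  All probabilities must be strictly
    positive; read the PFM with a pseudocount > 0 to guarantee that.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > _COL_SUM_TOL or np.any(bg <= 0):
        raise ValueError("background must be 4 positive reals summing to 1")
    if np.any(pfm.probs <= 0):
        raise ValueError(
            "PFM has zero-probability entries; re-read it with pseudocount > 0"
        )
    return PWM(np.log(pfm.probs / bg[:, None]), name=pfm.name)


def pwm_to_pfm(pwm: PWM) -> PFM:
    """Boltzmann-normalize a PWM: weights as energies, softmax per column.

    Stabilized by subtracting each column's maximum before exponentiation,
    which leaves the result unchanged (softmax shift invariance).
    """
    w = pwm.weights - pwm.weights.max(axis=0, keepdims=True)
    e = np.exp(w)
    return PFM(e / e.sum(axis=0, keepdims=True), name=pwm.name)


def embed_mono_in_dinuc(pwm: PWM) -> DinucPWM:
    """Embed a mononucleotide PWM in the dinucleotide parameter space.

    The first base of each adjacent pair carries that position's mono weight;
    the last pair column additionally carries the final position's weight.
    Every site then scores identically under both models, so the embedding
    is the natural seed for dinucleotide training.
    """
    if pwm.width < 2:
        raise ValueError("dinucleotide embedding requires width >= 2")
    w = pwm.width
    out = np.zeros((16, w - 1))
    mono = pwm.weights
    for i in range(w - 1):
        for x in range(4):
            for y in range(4):
                val = mono[x, i]
                if i == w - 2:
                    val += mono[y, i + 1]
                out[4 * x + y, i] = val
    return DinucPWM(out, name=pwm.name)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_site(model: MatrixModel, site: str) -> float:
    """Score one site of exactly the model's width.

    PWM: sum of per-position base weights.  DinucPWM: sum of adjacent-pair
    weights.  PFM: log-probability of the site (sum of log column entries;
    zero-probability bases score -inf).
    """
    idx = _checked_indices(site, model.width)
    return float(_score_indices(model, idx[None, :])[0])


def _score_indices(model: MatrixModel, idx: np.ndarray) -> np.ndarray:
    """Score an (n, width) array of base-index rows; no validity checks."""
    pos = np.arange(idx.shape[1])
    if isinstance(model, PWM):
        return model.weights[idx, pos].sum(axis=1)
    if isinstance(model, DinucPWM):
        pairs = 4 * idx[:, :-1] + idx[:, 1:]
        return model.weights[pairs, np.arange(idx.shape[1] - 1)].sum(axis=1)
    if isinstance(model, PFM):
        with np.errstate(divide="ignore"):
            logp = np.log(model.probs)
        return logp[idx, pos].sum(axis=1)
    raise TypeError(f"cannot score with {type(model).__name__}")


def score_sites(model: MatrixModel, sites) -> np.ndarray:
    """Vectorized :func:`score_site` over a list of equal-length sites."""
    if len(sites) == 0:
        return np.empty(0)
    idx = np.stack([_checked_indices(s, model.width) for s in sites])
    return _score_indices(model, idx)


def reverse_complement_model(model: MatrixModel) -> MatrixModel:
    """Model scoring each site as the original scores its reverse complement.

    For all sites ``s``: ``score(rc_model, s) == score(model, rc(s))``
    exactly.  Applying the operation twice returns the original matrix.
    """
    if isinstance(model, (PFM, PWM)):
        mat = model.probs if isinstance(model, PFM) else model.weights
        flipped = mat[COMPLEMENT_INDEX][:, ::-1]
        cls = type(model)
        return cls(flipped, name=model.name)
    if isinstance(model, DinucPWM):
        w = model.weights
        ncol = w.shape[1]
        out = np.empty_like(w)
        for i in range(ncol):
            for x in range(4):
                for y in range(4):
                    # pair (x, y) at position i of a site corresponds to pair
                    # (comp(y), comp(x)) at mirrored position in its rev-comp
                    cx, cy = COMPLEMENT_INDEX[x], COMPLEMENT_INDEX[y]
                    out[4 * cy + cx, ncol - 1 - i] = w[4 * x + y, i]
        return DinucPWM(out, name=model.name)
    raise TypeError(f"cannot reverse-complement {type(model).__name__}")
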