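"""Build paired positive/negative site datasets from peaks and a genome.

The protocol mirrors common ChIP-seq benchmarking practice: each peak's
point-source (narrowPeak summit when present, else interval midpoint) centers
a fixed-width positive window; the paired negative window of the same width
sits a fixed distance downstream on the same chromosome.  Each sequence is
then reduced to its single best-scoring site under a seed matrix — scanning
both strands — and those frozen sites, not the full windows, are what models
are trained and tested on.  Cross-validation folds are assigned to
positive/negative *pairs* so a site and its partner never straddle folds.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .motif_models import (
    MatrixModel,
    encode_sequence,
    reverse_complement,
    reverse_complement_model,
    _score_indices,
)


class BedFormatError(ValueError):
    """Raised on a malformed BED/narrowPeak line."""


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: Optional[int] = None  # offset from start, narrowPeak column 10

    @property
    def point_source(self) -> int:
        if self.summit is not None and self.summit >= 0:
            return self.start + self.summit
        return (self.start + self.end) // 2


@dataclass
class GenomicWindow:
    chrom: str
    start: int
    end: int
    label: str  # "positive" | "negative"
    pair_id: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class ScoredSite:
    """A fixed-width subsequence of a parent sequence, with score and label.

    ``site_seq`` is the parent subsequence starting at ``offset``,
    reverse-complemented when ``strand`` is '-'.
    """

    parent_id: str
    offset: int
    strand: str
    site_seq: str
    score: float
    label: str


@dataclass
class SiteDataset:
    """Paired positive/negative best sites with optional fold assignments.

    ``positives[i]`` and ``negatives[i]`` form pair ``i``; ``fold_of[i]`` is
    that pair's cross-validation fold.
    """

    positives: list
    negatives: list
    fold_of: Optional[np.ndarray] = None

    def __post_init__(self):
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be paired 1:1")

    @property
    def n_pairs(self) -> int:
        return len(self.positives)

    @property
    def n_folds(self) -> int:
        if self.fold_of is None:
            raise ValueError("dataset has no fold assignment")
        return int(self.fold_of.max()) + 1

    def split(self, fold: int):
        """Return (train_pos, train_neg, test_pos, test_neg) for one fold."""
        if self.fold_of is None:
            raise ValueError("dataset has no fold assignment")
        test = self.fold_of == fold
        tr_pos = [s for s, t in zip(self.positives, test) if not t]
        tr_neg = [s for s, t in zip(self.negatives, test) if not t]
        te_pos = [s for s, t in zip(self.positives, test) if t]
        te_neg = [s for s, t in zip(self.negatives, test) if t]
        return tr_pos, tr_neg, te_pos, te_neg


# ---------------------------------------------------------------------------
# BED / window extraction
# ---------------------------------------------------------------------------

def read_bed(handle: Union[TextIO, str, Path]) -> list:
    """Parse BED3/BED6/narrowPeak records; summit taken from column 10."""
    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            return read_bed(fh)
    peaks = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise BedFormatError(f"line {lineno}: fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedFormatError(f"line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise BedFormatError(f"line {lineno}: end < start")
        summit = None
        if len(parts) >= 10:
            try:
                s = int(parts[9])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: bad summit column") from exc
            if s >= 0:
                summit = s
        peaks.append(Peak(parts[0], start, end, summit))
    return peaks


def extract_windows(
    peaks: Sequence[Peak],
    genome,
    window: int = 100,
    negative_offset: int = 100,
) -> list:
    """Paired positive/negative windows around each peak's point-source.

    The positive window is ``[p - window//2, p - window//2 + window)`` around
    point-source ``p`` (odd widths place the extra base to the right); the
    negative window starts ``negative_offset`` bp after the positive window's
    end.  ``negative_offset=5000`` gives the distal-negative variant.  Pairs
    whose positive or negative window runs off the chromosome are dropped
    together.  ``genome`` is a mapping chrom -> sequence (e.g. pyfaidx.Fasta
    or a plain dict of strings).
    """
    out = []
    pair_id = 0
    for peak in peaks:
        try:
            chrom_seq = genome[peak.chrom]
        except KeyError as exc:
            raise KeyError(f"chromosome {peak.chrom!r} not in genome") from exc
        chrom_len = len(chrom_seq)
        p = peak.point_source
        pos_start = p - window // 2
        pos_end = pos_start + window
        neg_start = pos_end + negative_offset
        neg_end = neg_start + window
        if pos_start < 0 or neg_end > chrom_len:
            continue  # drop the pair with its partner
        out.append(GenomicWindow(peak.chrom, pos_start, pos_end, "positive", pair_id))
        out.append(GenomicWindow(peak.chrom, neg_start, neg_end, "negative", pair_id))
        pair_id += 1
    return out


def window_sequence(genome, win: GenomicWindow) -> str:
    seq = genome[win.chrom][win.start : win.end]
    return str(seq).upper()


# ---------------------------------------------------------------------------
# best-site scanning
# ---------------------------------------------------------------------------

def best_site(
    model: MatrixModel,
    sequence: str,
    both_strands: bool = True,
    parent_id: str = "",
    label: str = "positive",
) -> ScoredSite:
    """The maximum-scoring model-width window of a sequence.

    All offsets are scanned; with ``both_strands`` the reverse complement of
    each window is scored too.  Windows containing ambiguous bases are
    skipped.  Ties break to the smaller offset, then to the forward strand.
    """
    w = model.width
    if len(sequence) < w:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than model width {w}"
        )
    idx = encode_sequence(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = ~np.any(windows < 0, axis=1)
    if not np.any(valid):
        raise ValueError(
            f"no ambiguity-free window of width {w} in sequence {parent_id or sequence!r}"
        )
    offsets = np.nonzero(valid)[0]
    plus = _score_indices(model, windows[valid])
    if both_strands:
        # scoring the rev-comp model on the forward window equals scoring the
        # original model on the window's reverse complement
        minus = _score_indices(reverse_complement_model(model), windows[valid])
        best = max(plus.max(), minus.max())
    else:
        minus = None
        best = plus.max()
    plus_hits = offsets[plus == best]
    first_plus = int(plus_hits[0]) if plus_hits.size else None
    first_minus = None
    if minus is not None:
        minus_hits = offsets[minus == best]
        first_minus = int(minus_hits[0]) if minus_hits.size else None
    if first_minus is None or (first_plus is not None and first_plus <= first_minus):
        off, strand = first_plus, "+"
    else:
        off, strand = first_minus, "-"
    window_seq = sequence[off : off + w].upper()
    site_seq = window_seq if strand == "+" else reverse_complement(window_seq)
    return ScoredSite(parent_id, off, strand, site_seq, float(best), label)


def build_site_dataset(
    model: MatrixModel,
    positive_seqs: Sequence[str],
    negative_seqs: Sequence[str],
    both_strands: bool = True,
    pos_ids: Optional[Sequence[str]] = None,
    neg_ids: Optional[Sequence[str]] = None,
) -> SiteDataset:
    """Scan each paired sequence once with the seed matrix and freeze sites."""
    if len(positive_seqs) != len(negative_seqs):
        raise ValueError("positive and negative sequence lists must pair 1:1")
    pos_ids = pos_ids or [f"pos_{i}" for i in range(len(positive_seqs))]
    neg_ids = neg_ids or [f"neg_{i}" for i in range(len(negative_seqs))]
    positives = [
        best_site(model, s, both_strands, parent_id=pid, label="positive")
        for pid, s in zip(pos_ids, positive_seqs)
    ]
    negatives = [
        best_site(model, s, both_strands, parent_id=nid, label="negative")
        for nid, s in zip(neg_ids, negative_seqs)
    ]
    return SiteDataset(positives, negatives)


# ---------------------------------------------------------------------------
# folds and subsampling
# ---------------------------------------------------------------------------

def make_folds(dataset: SiteDataset, k: int = 10, seed: int = 0) -> SiteDataset:
    """Assign pairs to k folds: seeded shuffle, then round-robin deal.

    Fold f's test set is fold f and its training set is the other k-1 folds,
    so train:test sizes are in ratio (k-1):1 up to the remainder, and fold
    sizes differ by at most one pair.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = dataset.n_pairs
    if n < k:
        raise ValueError(f"need at least k={k} pairs, have {n}")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    fold_of = np.empty(n, dtype=int)
    for rank, pair in enumerate(order):
        fold_of[pair] = rank % k
    return SiteDataset(dataset.positives, dataset.negatives, fold_of)


def small_training_variant(
    dataset: SiteDataset, fraction: float = 0.1, seed: int = 0
):
    """Two disjoint random pair subsets of size floor(fraction * n_pairs).

    Emulates training on a set no larger than the test set: both returned
    datasets keep the paired structure and share no pairs.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = dataset.n_pairs
    m = int(fraction * n)
    if m < 1:
        raise ValueError("fraction too small for the dataset")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    take = lambda ids: SiteDataset(
        [dataset.positives[i] for i in ids], [dataset.negatives[i] for i in ids]
    )
    return take(sorted(order[:m])), take(sorted(order[m : 2 * m]))


# ---------------------------------------------------------------------------
# text I/O for windows and sites
# ---------------------------------------------------------------------------

def write_windows_fasta(genome, windows: Sequence[GenomicWindow], handle: TextIO):
    for win in windows:
        handle.write(f">{win.chrom}:{win.start}-{win.end}|{win.label}|{win.pair_id}\n")
        handle.write(window_sequence(genome, win) + "\n")


SITE_COLUMNS = ("parent_id", "offset", "strand", "site_seq", "score", "label")


def write_sites(dataset: SiteDataset, handle: TextIO) -> None:
    """Tab-delimited site table; fold column included when assigned."""
    has_folds = dataset.fold_of is not None
    cols = SITE_COLUMNS + (("fold",) if has_folds else ())
    handle.write("\t".join(cols) + "\n")
    for i in range(dataset.n_pairs):
        for site in (dataset.positives[i], dataset.negatives[i]):
            row = [
                site.parent_id,
                str(site.offset),
                site.strand,
                site.site_seq,
                repr(site.score),
                site.label,
            ]
            if has_folds:
                row.append(str(int(dataset.fold_of[i])))
            handle.write("\t".join(row) + "\n")


def read_sites(handle: Union[TextIO, str, Path]) -> SiteDataset:
    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            return read_sites(fh)
    header = handle.readline().rstrip("\n").split("\t")
    has_folds = "fold" in header
    positives, negatives, folds = [], [], []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        site = ScoredSite(
            parts[0], int(parts[1]), parts[2], parts[3], float(parts[4]), parts[5]
        )
        if site.label == "positive":
            positives.append(site)
            if has_folds:
                folds.append(int(parts[6]))
        else:
            negatives.append(site)
    fold_of = np.asarray(folds, dtype=int) if has_folds else None
    return SiteDataset(positives, negatives, fold_of)
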