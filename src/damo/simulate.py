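"""Seeded generators for every input the pipeline consumes.

Everything downstream — window extraction, best-site scanning, perceptron
training, feature classifiers — can be exercised without any download:

* :func:`sample_pfm` draws a ground-truth probability matrix with tunable
  column sharpness (symmetric Dirichlet; smaller concentration = sharper).
* :func:`generate_dataset` plants one site drawn from that matrix into each
  positive background sequence and leaves negatives as pure background,
  emulating peak-versus-flank classification data.  An optional adjacent-pair
  coupling reweights the joint distribution of one dinucleotide, creating
  exactly the nearest-neighbour dependence a dinucleotide model should
  capture and a mononucleotide matrix cannot.
* :func:`genome_fixture` writes a toy multi-chromosome genome plus a
  narrowPeak file with summit columns, including deliberate edge-case peaks.
* :func:`fabricate_shape_tracks` produces base-determined structural tracks
  plus Gaussian noise — a stand-in (synthetic, not physical) for external
  structure predictions, reproducing the key property that shape encodes
  sequence.

All generators are bit-reproducible from their configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, TextIO

import numpy as np

from .motif_models import BASES, PFM
from .features import SHAPE_FEATURES, ShapeTrack


@dataclass
class SimConfig:
    """Settings of the planted-site generator.

    ``concentration`` is the symmetric-Dirichlet parameter of the generating
    PFM's columns (0.1 gives sharp, motif-like columns).  ``coupling``, when
    set, is ``(position, 16 log-weights)``: the joint distribution of the
    adjacent pair at (position, position+1) is reweighted by exp(log-weight)
    and renormalized.  ``bg_order`` selects an i.i.d. (0) or first-order
    Markov (1) background; the Markov option adds same-base persistence for
    stress-testing dinucleotide specificity.
    """

    width: int = 8
    n_pos: int = 500
    n_neg: int = 500
    seq_len: int = 100
    gc: float = 0.5
    concentration: float = 0.1
    coupling: Optional[tuple] = None  # (position, 16 log-weights)
    seed: int = 0
    bg_order: int = 0
    bg_persistence: float = 0.3

    def __post_init__(self):
        if self.seq_len < self.width:
            raise ValueError("seq_len must be >= width")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sequence per class")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.coupling is not None:
            pos, w = self.coupling
            if not 0 <= pos < self.width - 1:
                raise ValueError("coupling position out of range")
            if len(w) != 16:
                raise ValueError("coupling needs 16 pair log-weights")
        if self.bg_order not in (0, 1):
            raise ValueError("bg_order must be 0 or 1")


def sample_pfm(width: int, concentration: float, rng: np.random.Generator) -> PFM:
    """Ground-truth PFM with i.i.d. symmetric-Dirichlet columns."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    cols = rng.dirichlet(np.full(4, concentration), size=width)
    return PFM(cols.T, name=f"dirichlet_{concentration}")


def _background_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _sample_background(n: int, length: int, cfg: SimConfig, rng) -> np.ndarray:
    probs = _background_probs(cfg.gc)
    if cfg.bg_order == 0:
        return rng.choice(4, size=(n, length), p=probs)
    # first-order: blend toward repeating the previous base
    trans = (1 - cfg.bg_persistence) * np.tile(probs, (4, 1)) + (
        cfg.bg_persistence * np.eye(4)
    )
    out = np.empty((n, length), dtype=int)
    out[:, 0] = rng.choice(4, size=n, p=probs)
    for j in range(1, length):
        u = rng.random(n)
        cum = np.cumsum(trans[out[:, j - 1]], axis=1)
        out[:, j] = (u[:, None] > cum).sum(axis=1)
    return out


def _pair_joint(pfm: PFM, coupling) -> Optional[np.ndarray]:
    if coupling is None:
        return None
    pos, logw = coupling
    joint = np.outer(pfm.probs[:, pos], pfm.probs[:, pos + 1]) * np.exp(
        np.asarray(logw, float).reshape(4, 4)
    )
    return joint / joint.sum()


def _sample_sites(pfm: PFM, n: int, coupling, rng) -> np.ndarray:
    w = pfm.width
    sites = np.empty((n, w), dtype=int)
    for i in range(w):
        sites[:, i] = rng.choice(4, size=n, p=pfm.probs[:, i])
    joint = _pair_joint(pfm, coupling)
    if joint is not None:
        pos = coupling[0]
        flat = rng.choice(16, size=n, p=joint.reshape(-1))
        sites[:, pos] = flat // 4
        sites[:, pos + 1] = flat % 4
    return sites


def _decode(idx: np.ndarray) -> list:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in idx]


def generate_dataset(config: SimConfig, pfm: Optional[PFM] = None):
    """Planted-site positives and background negatives.

    Returns ``(pos_seqs, neg_seqs, truth)`` where truth records the
    generating PFM, per-positive plant offsets and planted site sequences,
    and the full configuration — enough to recompute every planted site.
    A caller-supplied ``pfm`` overrides the Dirichlet-sampled one (useful
    for experiments that need specific marginals, e.g. uniform columns under
    an adjacent-pair coupling).
    """
    rng = np.random.default_rng(config.seed)
    if pfm is None:
        pfm = sample_pfm(config.width, config.concentration, rng)
    elif pfm.width != config.width:
        raise ValueError("supplied PFM width does not match config.width")
    pos_bg = _sample_background(config.n_pos, config.seq_len, config, rng)
    neg_bg = _sample_background(config.n_neg, config.seq_len, config, rng)
    sites = _sample_sites(pfm, config.n_pos, config.coupling, rng)
    offsets = rng.integers(0, config.seq_len - config.width + 1, size=config.n_pos)
    for i in range(config.n_pos):
        pos_bg[i, offsets[i] : offsets[i] + config.width] = sites[i]
    pos_seqs = _decode(pos_bg)
    neg_seqs = _decode(neg_bg)
    truth = {
        "pfm": pfm.probs.tolist(),
        "offsets": offsets.tolist(),
        "planted_sites": _decode(sites),
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "coupling"},
            "coupling": None
            if config.coupling is None
            else [int(config.coupling[0]), list(map(float, config.coupling[1]))],
        },
    }
    return pos_seqs, neg_seqs, truth


def write_fasta(seqs: Sequence[str], handle: TextIO, prefix: str = "seq") -> None:
    for i, s in enumerate(seqs):
        handle.write(f">{prefix}_{i}\n{s}\n")


def read_fasta(path) -> list:
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def genome_fixture(
    n_chroms: int,
    chrom_len: int,
    n_peaks: int,
    rng: np.random.Generator,
    window: int = 100,
    negative_offset: int = 100,
    n_edge_peaks: int = 0,
    gc: float = 0.5,
):
    """Random genome (dict chrom -> sequence) plus narrowPeak records.

    Regular peak summits keep ``window + negative_offset + window`` clear of
    the chromosome end and ``window//2`` clear of the start, so their window
    pairs always fit; ``n_edge_peaks`` additional peaks are deliberately
    placed too close to a chromosome start so their pairs get dropped.
    """
    margin_left = window // 2
    margin_right = window - window // 2 + negative_offset + window
    if chrom_len <= margin_left + margin_right:
        raise ValueError("chrom_len too small for any valid peak")
    probs = _background_probs(gc)
    genome = {}
    for c in range(n_chroms):
        idx = rng.choice(4, size=chrom_len, p=probs)
        genome[f"chr{c + 1}"] = _decode(idx[None, :])[0]
    bed_lines = []
    chroms = sorted(genome)
    for _ in range(n_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        summit = int(rng.integers(margin_left, chrom_len - margin_right))
        start = max(0, summit - 25)
        end = min(chrom_len, summit + 25)
        bed_lines.append(_narrowpeak_line(chrom, start, end, summit - start))
    for _ in range(n_edge_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        summit = int(rng.integers(0, max(1, margin_left)))  # positive runs off
        start, end = 0, min(chrom_len, summit + 25)
        bed_lines.append(_narrowpeak_line(chrom, start, end, summit - start))
    return genome, "\n".join(bed_lines) + "\n"


def _narrowpeak_line(chrom, start, end, summit):
    return "\t".join(
        [chrom, str(start), str(end), ".", "0", ".", "0", "-1", "-1", str(summit)]
    )


# fixed arbitrary per-base means for the 8 structural features; only the fact
# that they differ between bases matters (shape determines sequence up to noise)
_DEFAULT_SHAPE_SIGNAL = {
    "A": np.array([34.0, 5.0, -8.0, 1.0, 33.0, 5.5, -7.0, 0.5]),
    "C": np.array([36.0, 4.2, -12.0, 3.0, 35.0, 4.0, -11.0, 2.5]),
    "G": np.array([31.0, 5.8, -5.0, -2.0, 32.0, 6.0, -4.5, -1.5]),
    "T": np.array([38.0, 3.5, -15.0, 5.0, 37.0, 3.8, -14.0, 4.5]),
}


def fabricate_shape_tracks(
    sites: Sequence,
    rng: np.random.Generator,
    signal: Optional[dict] = None,
    noise_sd: float = 0.5,
) -> list:
    """Synthetic structural tracks: base-dependent means plus Gaussian noise.

    Because the values are determined by the underlying sequence up to noise,
    a shape-only classifier retains discriminative power on planted-site
    data, mirroring the fact that real structural descriptors encode the
    sequence they were predicted from.
    """
    if not sites:
        raise ValueError("site list is empty")
    signal = signal or _DEFAULT_SHAPE_SIGNAL
    tracks = []
    for k, site in enumerate(sites):
        seq = site if isinstance(site, str) else site.site_seq
        sid = f"site_{k}" if isinstance(site, str) else site.parent_id
        means = np.stack([signal[b] for b in seq], axis=1)  # 8 x width
        values = means + rng.normal(0.0, noise_sd, size=means.shape)
        tracks.append(ShapeTrack(sid, values))
    return tracks


def write_truth(truth: dict, handle: TextIO) -> None:
    json.dump(truth, handle, indent=1)
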