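"""From peaks and a genome to a cross-validation-ready site dataset.

Builds a toy genome with narrowPeak calls, extracts 100 bp positive windows
centered on each summit with paired negatives 100 bp downstream, reduces
each window to its best site under a seed motif (scanning both strands),
and deals the pairs into ten folds.
"""

import io

import numpy as np

import damo
from damo.dataset_prep import window_sequence
from damo.simulate import genome_fixture, sample_pfm

rng = np.random.default_rng(7)
genome, bed_text = genome_fixture(2, 20000, 60, rng, n_edge_peaks=2)
peaks = damo.read_bed(io.StringIO(bed_text))
windows = damo.extract_windows(peaks, genome, window=100, negative_offset=100)
print(f"{len(peaks)} peaks -> {len(windows) // 2} window pairs "
      f"({len(peaks) - len(windows) // 2} dropped at chromosome edges)")

seed_pfm = sample_pfm(8, 0.1, rng)
seed_pwm = damo.pfm_to_seed_pwm(seed_pfm)
pos = [w for w in windows if w.label == "positive"]
neg = [w for w in windows if w.label == "negative"]
dataset = damo.build_site_dataset(
    seed_pwm,
    [window_sequence(genome, w) for w in pos],
    [window_sequence(genome, w) for w in neg],
)
dataset = damo.make_folds(dataset, k=10, seed=3)

site = dataset.positives[0]
print(f"first positive best site: offset {site.offset}, strand {site.strand}, "
      f"{site.site_seq}, score {site.score:.3f}")
sizes = np.bincount(dataset.fold_of, minlength=10)
print(f"fold sizes (pairs): {sizes.tolist()} -> train:test = 9:1 per fold")
print("Each fold holds positive/negative pairs together, so a site and its")
print("matched control are never split across training and testing.")
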