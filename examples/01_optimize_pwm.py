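"""Optimize a PWM discriminatively on planted-motif data.

Generates 500 positive sequences (100 bp, one site from a sharp ground-truth
motif planted at a random offset) and 500 background negatives, degrades the
truth into an imperfect seed motif, freezes each sequence's best site under
the seed, then perceptron-trains a PWM to maximize training AUROC.
"""

import numpy as np

import damo
from damo.motif_models import PFM
from damo.optimizer import TrainConfig, train_damo
from damo.simulate import SimConfig, generate_dataset

cfg = SimConfig(width=8, n_pos=500, n_neg=500, seq_len=100, concentration=0.1, seed=0)
pos_seqs, neg_seqs, truth = generate_dataset(cfg)
true_pfm = PFM(np.asarray(truth["pfm"]))

# imperfect seed: truth mixed with an unrelated random motif
noise = np.random.default_rng(1000).dirichlet(np.full(4, 1.0), size=8).T
mixed = 0.6 * true_pfm.probs + 0.4 * noise
seed_pfm = PFM(mixed / mixed.sum(axis=0, keepdims=True), name="degraded_seed")

seed_pwm = damo.pfm_to_seed_pwm(seed_pfm)
dataset = damo.build_site_dataset(seed_pwm, pos_seqs, neg_seqs)
dataset = damo.make_folds(dataset, k=10, seed=1)
tr_pos, tr_neg, te_pos, te_neg = dataset.split(0)

trace = train_damo(seed_pfm, tr_pos, tr_neg, TrainConfig(seed=2))

score = lambda model, sites: damo.score_sites(model, [s.site_seq for s in sites])
seed_auroc = damo.auroc(score(seed_pwm, te_pos), score(seed_pwm, te_neg))
opt_auroc = damo.auroc(
    score(trace.best_model, te_pos), score(trace.best_model, te_neg)
)

print(f"seed PWM   held-out AUROC: {seed_auroc:.4f}")
print(f"trained PWM held-out AUROC: {opt_auroc:.4f} (best epoch {trace.best_epoch})")
print("AUROC is the probability a random positive site outscores a random")
print("negative; the gain over the seed is what discriminative training buys.")
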