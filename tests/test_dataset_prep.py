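"""Window extraction, best-site scanning, folds, and site table I/O."""

import io

import numpy as np
import pytest

from damo.dataset_prep import (
    BedFormatError,
    Peak,
    SiteDataset,
    best_site,
    build_site_dataset,
    extract_windows,
    make_folds,
    read_bed,
    read_sites,
    small_training_variant,
    write_sites,
)
from damo.motif_models import (
    PWM,
    reverse_complement,
    score_site,
)
from conftest import random_pwm, random_seq


def exhaustive_best(model, sequence, both_strands=True):
    """Independent oracle: enumerate every window and strand with score_site."""
    w = model.width
    best = None
    for off in range(len(sequence) - w + 1):
        window = sequence[off : off + w].upper()
        if any(b not in "ACGT" for b in window):
            continue
        candidates = [("+", window)]
        if both_strands:
            candidates.append(("-", reverse_complement(window)))
        for strand, seq in candidates:
            score = score_site(model, seq)
            if best is None or score > best[0]:
                best = (score, off, strand, seq)
    return best


class TestExtractWindows:
    def make_genome(self, length=10000):
        return {"chr1": "A" * length}

    def test_window_arithmetic(self):
        peaks = [Peak("chr1", 450, 550, None)]  # midpoint 500
        wins = extract_windows(peaks, self.make_genome(), window=100, negative_offset=100)
        pos, neg = wins
        assert (pos.start, pos.end) == (450, 550)
        assert (neg.start, neg.end) == (650, 750)
        assert pos.pair_id == neg.pair_id

    def test_distal_negative_variant(self):
        peaks = [Peak("chr1", 450, 550, None)]
        wins = extract_windows(peaks, self.make_genome(), negative_offset=5000)
        assert (wins[1].start, wins[1].end) == (5550, 5650)

    def test_summit_overrides_midpoint(self):
        peaks = [Peak("chr1", 400, 600, 100)]  # summit at 500
        wins = extract_windows(peaks, self.make_genome())
        assert (wins[0].start, wins[0].end) == (450, 550)

    def test_odd_window_extends_right(self):
        wins = extract_windows([Peak("chr1", 500, 500, None)], self.make_genome(), window=101)
        assert (wins[0].start, wins[0].end) == (450, 551)

    def test_pair_dropped_when_positive_runs_off_start(self):
        peaks = [Peak("chr1", 30, 30, None), Peak("chr1", 500, 500, None)]
        wins = extract_windows(peaks, self.make_genome())
        assert len(wins) == 2 and wins[0].start == 450

    def test_pair_dropped_when_negative_runs_off_end(self):
        peaks = [Peak("chr1", 9900, 9900, None)]
        assert extract_windows(peaks, self.make_genome()) == []

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(KeyError, match="chrMissing"):
            extract_windows([Peak("chrMissing", 500, 500, None)], self.make_genome())

    def test_negative_offset_invariant(self):
        rng = np.random.default_rng(4)
        peaks = [Peak("chr1", int(p), int(p) + 10, None) for p in rng.integers(300, 9000, 40)]
        for off in (100, 5000):
            wins = extract_windows(peaks, self.make_genome(20000), negative_offset=off)
            pos = {w.pair_id: w for w in wins if w.label == "positive"}
            neg = {w.pair_id: w for w in wins if w.label == "negative"}
            assert set(pos) == set(neg)
            for pid in pos:
                assert neg[pid].start - pos[pid].end == off


class TestReadBed:
    def test_narrowpeak_summit_parsed(self):
        line = "chr1\t100\t200\tpk\t0\t.\t5.0\t-1\t-1\t30\n"
        peaks = read_bed(io.StringIO(line))
        assert peaks[0].point_source == 130

    def test_bed3_uses_midpoint(self):
        peaks = read_bed(io.StringIO("chr2\t10\t21\n"))
        assert peaks[0].point_source == 15

    def test_missing_summit_sentinel_falls_back(self):
        line = "chr1\t100\t200\tpk\t0\t.\t5.0\t-1\t-1\t-1\n"
        assert read_bed(io.StringIO(line))[0].point_source == 150

    def test_malformed_line_reports_number(self):
        with pytest.raises(BedFormatError, match="line 2"):
            read_bed(io.StringIO("chr1\t1\t2\nchr1\tx\t2\n"))


class TestBestSite:
    def test_single_candidate_window(self, rng):
        pwm = random_pwm(rng, 6)
        site = best_site(pwm, "ACGTAC")
        assert site.offset == 0 and site.site_seq in ("ACGTAC", reverse_complement("ACGTAC"))

    def test_strong_motif_found_at_plant(self):
        w = np.full((4, 4), -5.0)
        for i, b in enumerate("ACGT"):
            w["ACGT".index(b), i] = 5.0
        pwm = PWM(w)
        site = best_site(pwm, "TTACGTTT")
        assert (site.offset, site.strand, site.site_seq) == (2, "+", "ACGT")

    def test_sequence_shorter_than_width_raises(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            best_site(random_pwm(rng, 8), "ACGT")

    def test_no_valid_window_raises(self, rng):
        with pytest.raises(ValueError, match="ambiguity-free"):
            best_site(random_pwm(rng, 4), "ANNNTNNNA", parent_id="s1")

    def test_windows_with_n_skipped(self, rng):
        pwm = random_pwm(rng, 3)
        site = best_site(pwm, "NNACGNN")
        assert site.offset == 2

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            w = int(rng.integers(2, 10))
            seq = random_seq(rng, int(rng.integers(w, 60)), alphabet="ACGTN")
            pwm = random_pwm(rng, w)
            oracle = exhaustive_best(pwm, seq)
            if oracle is None:
                with pytest.raises(ValueError):
                    best_site(pwm, seq)
                continue
            found = best_site(pwm, seq)
            assert found.score == pytest.approx(oracle[0], abs=1e-12)
            assert score_site(pwm, found.site_seq) == pytest.approx(found.score, abs=1e-12)

    def test_reverse_complement_mirror(self, rng):
        """Scanning rc(sequence) gives the same score, mirrored offset, flipped strand."""
        for _ in range(50):
            w = int(rng.integers(2, 8))
            seq = random_seq(rng, int(rng.integers(w + 3, 40)))
            pwm = random_pwm(rng, w)
            fwd = best_site(pwm, seq)
            rev = best_site(pwm, reverse_complement(seq))
            assert rev.score == pytest.approx(fwd.score, abs=1e-12)

    def test_tie_breaks_leftmost_then_plus(self):
        pwm = PWM(np.zeros((4, 2)))  # every window ties at 0
        site = best_site(pwm, "ACGTAC")
        assert (site.offset, site.strand) == (0, "+")


class TestFolds:
    def make_dataset(self, n):
        from damo.dataset_prep import ScoredSite

        mk = lambda i, lbl: ScoredSite(f"{lbl}_{i}", 0, "+", "ACGT", 0.0, lbl)
        return SiteDataset(
            [mk(i, "positive") for i in range(n)],
            [mk(i, "negative") for i in range(n)],
        )

    def test_even_split_and_ratio(self):
        ds = make_folds(self.make_dataset(100), k=10, seed=1)
        sizes = np.bincount(ds.fold_of, minlength=10)
        assert list(sizes) == [10] * 10
        tr, _, te, _ = ds.split(0)
        assert len(tr) == 9 * len(te)

    def test_remainder_distribution(self):
        ds = make_folds(self.make_dataset(101), k=10, seed=1)
        sizes = sorted(np.bincount(ds.fold_of, minlength=10))
        assert sizes == [10] * 9 + [11]

    def test_seed_determinism(self):
        base = self.make_dataset(37)
        a = make_folds(base, k=5, seed=9).fold_of
        b = make_folds(base, k=5, seed=9).fold_of
        c = make_folds(base, k=5, seed=10).fold_of
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_folds_partition_dataset(self):
        ds = make_folds(self.make_dataset(53), k=10, seed=0)
        seen = []
        for f in range(10):
            _, _, te_pos, _ = ds.split(f)
            seen.extend(s.parent_id for s in te_pos)
        assert sorted(seen) == sorted(s.parent_id for s in ds.positives)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            make_folds(self.make_dataset(5), k=10, seed=0)

    def test_small_training_variant_disjoint(self):
        ds = self.make_dataset(100)
        train, test = small_training_variant(ds, fraction=0.1, seed=3)
        assert train.n_pairs == test.n_pairs == 10
        tr_ids = {s.parent_id for s in train.positives}
        te_ids = {s.parent_id for s in test.positives}
        assert not tr_ids & te_ids

    def test_small_training_variant_half_partitions(self):
        ds = self.make_dataset(10)
        train, test = small_training_variant(ds, fraction=0.5, seed=3)
        ids = {s.parent_id for s in train.positives} | {
            s.parent_id for s in test.positives
        }
        assert len(ids) == 10

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            small_training_variant(self.make_dataset(10), fraction=0.6, seed=0)


class TestSiteTableIO:
    def test_roundtrip_with_folds(self, rng):
        pwm = random_pwm(rng, 5)
        pos = [random_seq(rng, 30) for _ in range(12)]
        neg = [random_seq(rng, 30) for _ in range(12)]
        ds = make_folds(build_site_dataset(pwm, pos, neg), k=4, seed=2)
        buf = io.StringIO()
        write_sites(ds, buf)
        buf.seek(0)
        back = read_sites(buf)
        assert back.n_pairs == ds.n_pairs
        np.testing.assert_array_equal(back.fold_of, ds.fold_of)
        for a, b in zip(back.positives, ds.positives):
            assert (a.parent_id, a.offset, a.strand, a.site_seq, a.label) == (
                b.parent_id,
                b.offset,
                b.strand,
                b.site_seq,
                b.label,
            )
            assert a.score == b.score  # repr round-trip is bit-exact
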