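import itertools

import numpy as np
import pytest

from haplofoot.errors import UndefinedStatisticError, ValidationError
from haplofoot.genome_intervals import GenomicInterval, IntervalSet
from haplofoot.motif_scan import (
    ALPHABET,
    PWM,
    SCORE_BIN,
    MotifHit,
    ScoreDistribution,
    is_disruptive,
    pvalue_score_threshold,
    read_meme,
    scan,
    shuffle_footprints_within_dhs,
    write_meme,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def random_pwm(rng, k, tf="tf", sharp=False):
    if sharp:
        mat = np.full((k, 4), 0.02)
        mat[np.arange(k), rng.integers(0, 4, k)] = 0.94
    else:
        mat = rng.dirichlet(np.ones(4), size=k)
    return PWM(tf, mat)


def enumeration_threshold(pwm, p):
    """Exhaustive 4^k oracle on the same discretised score grid."""
    s = pwm.int_scores()
    bg = pwm.background
    scores, probs = [], []
    for kmer in itertools.product(range(4), repeat=len(pwm)):
        scores.append(sum(s[i, b] for i, b in enumerate(kmer)))
        probs.append(np.prod([bg[b] for b in kmer]))
    scores = np.asarray(scores)
    probs = np.asarray(probs)
    order = np.argsort(scores)
    scores, probs = scores[order], probs[order]
    # tail probability at each achievable score
    tail = np.cumsum(probs[::-1])[::-1]
    uniq = np.unique(scores)
    tails = np.asarray([tail[np.searchsorted(scores, u)] for u in uniq])
    ok = uniq[tails <= p + 1e-15]
    return int(ok[0]) if ok.size else int(uniq[-1])


class TestScoreDistribution:
    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_dp_equals_enumeration(self, k):
        rng = np.random.default_rng(k)
        for trial in range(3):
            pwm = random_pwm(rng, k, sharp=trial == 0)
            dist = ScoreDistribution(pwm)
            assert dist.total() == pytest.approx(1.0, abs=1e-6)
            for p in (1e-2, 1e-3, 1e-4):
                assert dist.threshold_for(p) == enumeration_threshold(pwm, p)

    def test_p_one_gives_minimum_score(self):
        pwm = random_pwm(np.random.default_rng(0), 5)
        dist = ScoreDistribution(pwm)
        achievable = np.flatnonzero(dist.pmf > 0) + dist.min_score
        assert dist.threshold_for(1.0) == achievable[0]

    def test_degenerate_pwm_returns_zero_with_warning(self):
        pwm = PWM("flat", np.full((5, 4), 0.25))
        with pytest.warns(UserWarning):
            assert pvalue_score_threshold(pwm, 1e-4) == 0.0

    def test_threshold_monotone_in_p(self):
        pwm = random_pwm(np.random.default_rng(1), 6)
        dist = ScoreDistribution(pwm)
        ts = [dist.threshold_for(p) for p in (0.5, 0.1, 1e-2, 1e-3, 1e-4)]
        assert ts == sorted(ts)


class TestScan:
    def test_near_deterministic_pwm_single_hit(self):
        mat = np.full((6, 4), 1e-9 / 3)
        for i, b in enumerate("ACGTAC"):
            mat[i] = 1e-9 / 3
            mat[i, ALPHABET.index(b)] = 1 - 1e-9
        pwm = PWM("exact", mat / mat.sum(axis=1, keepdims=True))
        seq = "TTTTT" + "ACGTAC" + "TTTTT"
        hits = [h for h in scan(seq, pwm, p=1e-3) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].interval.start == 5

    def test_masked_sequence_has_no_hits(self):
        pwm = random_pwm(np.random.default_rng(2), 5, sharp=True)
        assert scan("acgtacgtacgtacgt", pwm, p=0.5) == []
        assert scan("ACGNACGNACGNACGN", pwm, p=0.5) == []

    def test_short_sequence_empty(self):
        pwm = random_pwm(np.random.default_rng(3), 8)
        assert scan("ACG", pwm) == []

    def test_matches_per_window_rescoring_oracle(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 6, sharp=True)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        p = 1e-3
        hits = scan(seq, pwm, p=p)
        dist = ScoreDistribution(pwm)
        thr = dist.threshold_for(p)
        s_fwd = pwm.int_scores()
        s_rev = pwm.reverse_complement().int_scores()
        expected = []
        for i in range(len(seq) - 5):
            window = seq[i : i + 6]
            for strand, s in (("+", s_fwd), ("-", s_rev)):
                score = sum(s[j, ALPHABET.index(b)] for j, b in enumerate(window))
                if score >= thr:
                    expected.append((i, strand, score))
        got = [
            (h.interval.start, h.strand, round(h.score / SCORE_BIN))
            for h in hits
        ]
        assert sorted(got) == sorted(expected)

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 5, sharp=True)
        seq = "".join(rng.choice(list("ACGT"), 300))
        rc = seq.translate(_COMPLEMENT)[::-1]
        fwd = scan(seq, pwm, p=1e-2)
        rev = scan(rc, pwm, p=1e-2)
        mirrored = sorted(
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand],
             round(h.score / SCORE_BIN))
            for h in rev
        )
        direct = sorted(
            (h.interval.start, h.strand, round(h.score / SCORE_BIN))
            for h in fwd
        )
        assert direct == mirrored


class TestDisruption:
    def make_sharp(self):
        mat = np.full((6, 4), 0.05)
        for i, b in enumerate("ACGTAC"):
            mat[i] = 0.05
            mat[i, ALPHABET.index(b)] = 0.85
        return PWM("sharp", mat)

    def hit_for(self, pwm, seq="ACGTAC"):
        dist = ScoreDistribution(pwm)
        s = pwm.int_scores()
        score = sum(s[i, ALPHABET.index(b)] for i, b in enumerate(seq))
        return MotifHit(
            pwm.tf_id, GenomicInterval("chr1", 100, 106), "+",
            score * SCORE_BIN, dist.p_value(score), seq,
        )

    def test_low_probability_alt_disrupts(self):
        pwm = self.make_sharp()
        hit = self.hit_for(pwm)
        assert is_disruptive(hit, pwm, "A", "T", 0, p=1e-3)

    def test_ref_equals_alt_never_disrupts(self):
        pwm = self.make_sharp()
        hit = self.hit_for(pwm)
        assert not is_disruptive(hit, pwm, "A", "A", 0, p=1e-3)

    def test_ref_mismatch_raises(self):
        pwm = self.make_sharp()
        hit = self.hit_for(pwm)
        with pytest.raises(ValidationError):
            is_disruptive(hit, pwm, "C", "T", 0, p=1e-3)

    def test_enumerated_snvs_match_rescoring_oracle(self):
        pwm = self.make_sharp()
        hit = self.hit_for(pwm)
        dist = ScoreDistribution(pwm)
        thr = dist.threshold_for(1e-3)
        s = pwm.int_scores()
        base_score = round(hit.score / SCORE_BIN)
        for off in range(6):
            ref = hit.sequence[off]
            for alt in "ACGT":
                new = (
                    base_score - s[off, ALPHABET.index(ref)]
                    + s[off, ALPHABET.index(alt)]
                )
                expected = (base_score >= thr) != (new >= thr)
                assert is_disruptive(hit, pwm, ref, alt, off, p=1e-3) == expected


class TestFootprintShuffle:
    def test_lengths_and_containment_preserved(self, small_dataset):
        rng = np.random.default_rng(0)
        fps = small_dataset.footprints
        dhs = small_dataset.dhs
        for _ in range(20):
            shuffled = shuffle_footprints_within_dhs(fps, dhs, rng)
            assert [len(iv) for iv in shuffled] == [len(iv) for iv in fps]
            inside = shuffled.intersect_any(dhs)
            assert inside.all()
            for iv in shuffled:
                # fully contained in some DHS, not merely overlapping
                s, e = dhs.merged(iv.chrom)
                j = np.searchsorted(s, iv.start, side="right") - 1
                assert j >= 0 and e[j] >= iv.end

    def test_no_capable_dhs_raises(self):
        fps = IntervalSet([GenomicInterval("chr1", 0, 500)])
        dhs = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(UndefinedStatisticError):
            shuffle_footprints_within_dhs(fps, dhs, np.random.default_rng(0))


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        pwms = [random_pwm(rng, 8, tf=f"tf{i}") for i in range(3)]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.tf_id for p in back] == [p.tf_id for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)
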