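import math

import numpy as np
import pandas as pd
import pytest

from haplofoot.conservation_calibration import (
    ExpressionTable,
    calibrate_threshold,
    classify_tfs,
    delta_log_conservation,
    tp_fp_ratio,
)
from haplofoot.errors import ConfigurationError
from haplofoot.footprint_processing import ScoredTrack
from haplofoot.genome_intervals import GenomicInterval, IntervalSet


def expr_table(rows):
    return ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index",
                               columns=["s1", "s2", "s3"]).astype(float)
    )


class TestClassifyTFs:
    def test_highly_expressed(self):
        t = expr_table({"tfA": [12, 15, 11]})
        classes = classify_tfs(t)
        assert classes.highly_expressed == {"tfA"}
        assert classes.brain_expressed == {"tfA"}

    def test_undetectable(self):
        t = expr_table({"tfB": [0, 0, 0]})
        classes = classify_tfs(t)
        assert classes.undetectable == {"tfB"}
        assert classes.brain_expressed == set()

    def test_mixed_fixture_by_direct_rule(self):
        rng = np.random.default_rng(0)
        rows = {f"tf{i}": rng.uniform(0, 20, 3) for i in range(10)}
        rows["tf0"] = np.zeros(3)
        rows["tf1"] = np.asarray([11.0, 12.0, 13.0])
        rows["tf2"] = np.asarray([0.0, 5.0, 0.0])  # expressed but not highly
        t = expr_table(rows)
        classes = classify_tfs(t)
        for tf, v in rows.items():
            assert (tf in classes.highly_expressed) == bool(np.all(v > 10))
            assert (tf in classes.undetectable) == bool(np.max(v) == 0)
            assert (tf in classes.brain_expressed) == bool(np.any(v >= 1))
        # classes need not partition the universe
        assert "tf2" not in classes.highly_expressed | classes.undetectable


class TestDeltaLogConservation:
    def test_uniform_track_is_zero(self):
        track = ScoredTrack({"chr1": np.full(1000, 0.7)})
        m = GenomicInterval("chr1", 400, 410)
        assert delta_log_conservation(m, track) == pytest.approx(0.0)

    def test_step_track(self):
        arr = np.full(1000, 0.2)
        arr[400:410] = 0.5
        track = ScoredTrack({"chr1": arr})
        m = GenomicInterval("chr1", 400, 410)
        assert delta_log_conservation(m, track) == pytest.approx(0.3)

    def test_insufficient_flank_skipped_with_warning(self):
        track = ScoredTrack({"chr1": np.zeros(1000)})
        m = GenomicInterval("chr1", 10, 20)
        with pytest.warns(UserWarning, match="skipped"):
            assert delta_log_conservation(m, track, flank_bp=50) is None


def motif(start, tf, chrom="chr1", length=8):
    return GenomicInterval(chrom, start, start + length, name=tf,
                           tags={"tf_id": tf})


class TestTpFpRatio:
    def setup_method(self):
        self.track = ScoredTrack({"chr1": np.full(100_000, 1.0)})

    def test_symmetric_tracks_give_one(self):
        fps = IntervalSet(
            [GenomicInterval("chr1", 1000 + i * 100, 1020 + i * 100)
             for i in range(20)]
        )
        motifs = IntervalSet(
            [motif(1000 + i * 100, "hi") for i in range(20)]
            + [motif(1000 + i * 100, "und") for i in range(20)]
        )
        r = tp_fp_ratio(fps, motifs, {"hi"}, {"und"}, track=None)
        assert r == pytest.approx(1.0)

    def test_no_und_overlap_is_infinite(self):
        fps = IntervalSet([GenomicInterval("chr1", 1000, 1020)])
        motifs = IntervalSet([motif(1005, "hi"), motif(50_000, "und")])
        assert math.isinf(tp_fp_ratio(fps, motifs, {"hi"}, {"und"}, track=None))

    def test_zero_und_track_is_error(self):
        fps = IntervalSet([GenomicInterval("chr1", 1000, 1020)])
        motifs = IntervalSet([motif(1005, "hi")])
        with pytest.raises(ConfigurationError):
            tp_fp_ratio(fps, motifs, {"hi"}, {"und"}, track=None)

    def test_hand_computed_fixture(self):
        # 20 footprints; 5 overlap one 8-bp hi motif, 10 overlap an 8-bp und
        # motif; hi track = 2 motifs (16 bp), und track = 1 motif (8 bp)
        fps = IntervalSet(
            [GenomicInterval("chr1", 1000 + i * 100, 1020 + i * 100)
             for i in range(20)]
        )
        motifs = IntervalSet([motif(1000, "hi"), motif(50_000, "hi")])
        und = IntervalSet(
            [motif(1000 + i * 100, "und") for i in range(5, 15)]
        )
        all_motifs = IntervalSet(list(motifs) + list(und))
        # overlap: hi -> footprint 0 only (1/20); und -> 10/20
        got = tp_fp_ratio(fps, all_motifs, {"hi"}, {"und"}, track=None)
        hi_density = (1 / 20) / 16
        und_density = (10 / 20) / 80
        assert got == pytest.approx(hi_density / und_density)

    def test_doubling_und_track_doubles_ratio(self):
        fps = IntervalSet(
            [GenomicInterval("chr1", 1000 + i * 100, 1020 + i * 100)
             for i in range(10)]
        )
        base = [motif(1000, "hi"), motif(1100, "und")]
        extra_und = motif(90_000, "und")  # adds bp, no new overlap
        r1 = tp_fp_ratio(fps, IntervalSet(base), {"hi"}, {"und"}, track=None)
        r2 = tp_fp_ratio(
            fps, IntervalSet(base + [extra_und]), {"hi"}, {"und"}, track=None
        )
        assert r2 == pytest.approx(2 * r1)

    def test_conservation_gate_excludes_unconserved_hi_motifs(self):
        arr = np.zeros(100_000)
        track = ScoredTrack({"chr1": arr})  # flat: delta = 0 <= 0.1
        fps = IntervalSet([GenomicInterval("chr1", 1000, 1020)])
        motifs = IntervalSet([motif(1005, "hi"), motif(1010, "und")])
        # hi motif fails the conservation gate -> numerator 0
        assert tp_fp_ratio(fps, motifs, {"hi"}, {"und"}, track=track) == 0.0


class TestCalibrateThreshold:
    def make_scored(self, scores):
        return IntervalSet(
            [GenomicInterval("chr1", 1000 + i * 100, 1020 + i * 100,
                             score=float(s)) for i, s in enumerate(scores)]
        )

    def test_target_zero_returns_first_grid_point(self):
        fps = self.make_scored([1, 2, 3, 4])
        motifs = IntervalSet([motif(1005, "hi"), motif(1105, "und")])
        chosen, _ = calibrate_threshold(
            fps, motifs, _classes(), None, target_ratio=0.0,
            centile_grid=[0, 50],
        )
        assert chosen == 0

    def test_constant_scores_give_constant_curve(self):
        fps = self.make_scored([5] * 10)
        motifs = IntervalSet([motif(1005, "hi"), motif(1305, "und")])
        _, curve = calibrate_threshold(
            fps, motifs, _classes(), None, centile_grid=[0, 25, 50, 75]
        )
        assert len(set(curve.ratio)) == 1
        assert len(set(curve.n_footprints)) == 1

    def test_footprint_counts_non_increasing(self, small_dataset):
        from haplofoot.conservation_calibration import classify_tfs

        classes = classify_tfs(small_dataset.expression)
        _, curve = calibrate_threshold(
            small_dataset.footprints, small_dataset.motif_occurrences,
            classes, small_dataset.conservation_track,
        )
        assert all(
            a >= b for a, b in zip(curve.n_footprints, curve.n_footprints[1:])
        )

    def test_unreachable_target_returns_none_with_curve(self):
        fps = self.make_scored([1, 2, 3, 4])
        motifs = IntervalSet(
            [motif(1000 + i * 100, "und") for i in range(4)]
            + [motif(90_000, "hi")]
        )
        chosen, curve = calibrate_threshold(
            fps, motifs, _classes(), None, target_ratio=2.0,
            centile_grid=[0, 50],
        )
        assert chosen is None
        assert len(curve.ratio) == 2


def _classes():
    from haplofoot.conservation_calibration import TFClasses

    return TFClasses({"hi"}, {"und"}, {"hi"})
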