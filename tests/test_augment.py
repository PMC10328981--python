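import numpy as np
import pytest

import beatwise as bw
from beatwise.augment import NVB, VB, assign_folds, beat_examples
from beatwise._util import round_half_up


class TestTripletGeometry:
    def test_printed_length_rule(self):
        g = bw.triplet_geometry(0, 100, 220)
        assert (g.d1, g.d2, g.s) == (100, 120, 122)   # s = 0.5*100 + 0.6*120

    def test_equal_spacing(self):
        assert bw.triplet_geometry(0, 200, 400).s == 220

    def test_degenerate_triplet_rejected(self):
        with pytest.raises(ValueError):
            bw.triplet_geometry(0, 100, 100)
        with pytest.raises(ValueError):
            bw.triplet_geometry(100, 50, 200)

    def test_margins_bracket_main_point_and_span_s(self):
        g = bw.triplet_geometry(0, 100, 220)
        assert g.bl < g.cpm < g.br and g.br - g.bl == g.s
        assert g.tl == 0 + round_half_up(0.1 * g.s)
        assert g.tr == 220 - round_half_up(0.1 * g.s)


def _mid_triplet(rec):
    idx = rec.annotation_indices()
    k = len(idx) // 2
    return bw.triplet_geometry(int(idx[k - 1]), int(idx[k]), int(idx[k + 1]))


class TestVariants:
    def test_positive_shift_ladder_rounding(self):
        # s=110 -> shifts round(4.4), round(8.8), round(13.2)
        s = 110
        shifts = [round_half_up(f * s) for f in (0.04, 0.08, 0.12)]
        assert shifts == [4, 9, 13]

    def test_twelve_positives_all_valid_beat(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        pos = bw.make_positives(annotated_short_record, g)
        assert len(pos) == 12 and all(p.label == VB for p in pos)
        assert all(len(p.values) <= 512 for p in pos)

    def test_zero_shift_variant_is_the_main_slice(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        pos = bw.make_positives(annotated_short_record, g)
        np.testing.assert_array_equal(
            pos[0].values, annotated_short_record.signal[g.bl:g.br])

    def test_twelve_negatives_all_non_valid(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        neg = bw.make_negatives(annotated_short_record, g)
        assert len(neg) == 12 and all(n.label == NVB for n in neg)

    def test_half_beat_cut_leaves_cpm_on_boundary(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        neg = bw.make_negatives(annotated_short_record, g)
        left_half, right_half = neg[0], neg[1]
        assert len(left_half.values) == g.cpm - g.bl       # [bl, cpm)
        np.testing.assert_array_equal(
            right_half.values, annotated_short_record.signal[g.cpm:g.br])

    def test_two_cp_spans_contain_both_points(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        sig = annotated_short_record.signal
        neg = bw.make_negatives(annotated_short_record, g)
        pad = max(round_half_up(0.15 * g.s), 1)
        span_lm = neg[8]
        np.testing.assert_array_equal(span_lm.values,
                                      sig[g.cpl - pad:g.cpm + pad])

    def test_positives_contain_cpm_strictly_interior(self, annotated_short_record):
        for j, g in self._all_triplets(annotated_short_record):
            pos = bw.make_positives(annotated_short_record, g, j=j)
            main_lengths = {len(p.values) for p in pos[:7]}
            assert main_lengths == {g.s}
        # interior check on the shift windows themselves
        g = _mid_triplet(annotated_short_record)
        for f in (0.04, 0.08, 0.12):
            sh = round_half_up(f * g.s)
            assert g.bl + sh < g.cpm < g.br + sh
            assert g.bl - sh < g.cpm < g.br - sh

    @staticmethod
    def _all_triplets(rec):
        idx = rec.annotation_indices()
        for j in range(1, len(idx) - 1):
            yield j, bw.triplet_geometry(int(idx[j - 1]), int(idx[j]),
                                         int(idx[j + 1]))

    def test_all_24_variants_distinct(self, annotated_short_record):
        g = _mid_triplet(annotated_short_record)
        segs = (bw.make_positives(annotated_short_record, g)
                + bw.make_negatives(annotated_short_record, g))
        keys = {tuple(s.values.tolist()) for s in segs}
        assert len(keys) == 24


class TestDataset:
    def test_example_count_is_24_per_eligible_beat(self, annotated_short_record):
        B = len(annotated_short_record.annotations)
        assert len(beat_examples(annotated_short_record)) == 24 * (B - 2)

    def test_class_balance_per_beat(self, annotated_short_record):
        ds = bw.build_dataset([annotated_short_record], folds=2)
        for j in np.unique(ds.j):
            labels = ds.y[ds.j == j]
            assert (labels == VB).sum() == 12 and (labels == NVB).sum() == 12

    def test_each_record_in_exactly_one_fold(self):
        recs = [bw.generate(bw.SynthConfig(seed=s, duration=15,
                                           noise_snr=None)).record
                for s in range(3)]
        for i, r in enumerate(recs):
            object.__setattr__(r, "record_id", f"rec{i}")
        ds = bw.build_dataset(recs, folds=3)
        for rid in np.unique(ds.record_id):
            assert np.unique(ds.fold[ds.record_id == rid]).size == 1

    def test_round_robin_fold_assignment_balances(self):
        ids = [f"r{i:02d}" for i in range(10)]
        folds = assign_folds(ids, 10)
        assert sorted(folds.values()) == list(range(10))

    def test_explicit_fold_table_wins(self):
        folds = assign_folds(["a", "b"], 2, fold_table={"a": 1, "b": 0})
        assert folds == {"a": 1, "b": 0}

    def test_record_with_too_few_beats_skipped(self, annotated_short_record):
        tiny = bw.EcgRecord(record_id="tiny", fs=360.0,
                            signal=np.zeros(1000),
                            annotations=[bw.AnnotatedBeat(500, "N")])
        ds = bw.build_dataset([annotated_short_record, tiny], folds=2)
        assert "tiny" not in set(ds.record_id)
        with pytest.raises(ValueError):
            bw.build_dataset([tiny], folds=2)

    def test_hdf5_round_trip(self, annotated_short_record, tmp_path):
        ds = bw.build_dataset([annotated_short_record], folds=2)
        p = tmp_path / "ds.h5"
        ds.save(p)
        back = bw.BeatDataset.load(p)
        np.testing.assert_array_equal(ds.X, back.X)
        np.testing.assert_array_equal(ds.y, back.y)
        assert list(ds.record_id) == list(back.record_id)
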