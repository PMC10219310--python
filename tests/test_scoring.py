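"""GRAVY, predictor-table ingest, window reduction, normalization and
the weighted aggregate f(n)."""

import numpy as np
import pandas as pd
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from neovax.scoring import (
    DEFAULT_DIRECTIONS,
    VARIABLES,
    PredictionIndex,
    PredictionRecord,
    WeightConfig,
    aggregate_f,
    gravy,
    load_prediction_table,
    minmax_normalize,
    reduce_to_neoantigen,
    score_candidates,
)
from neovax.windows import PeptideWindow, enumerate_9mers

# independent oracle: Kyte-Doolittle hydropathy values, literal
KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
      "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
      "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2}

AA = "".join(sorted(KD))


class TestGravy:
    @pytest.mark.parametrize("seq,expected", [("A", 1.8), ("AAA", 1.8), ("R", -4.5)])
    def test_single_residue_equals_scale_entry(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    def test_random_peptides_match_scale_mean_and_biopython(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list(AA), size=int(rng.integers(5, 30))))
            expected = sum(KD[a] for a in seq) / len(seq)
            assert gravy(seq) == pytest.approx(expected)
            assert gravy(seq) == pytest.approx(ProteinAnalysis(seq).gravy())

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="X"):
            gravy("AAXA")


class TestPredictionTable:
    def _write(self, path, rows, cols=("allele", "peptide", "percentile_rank")):
        pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)

    def test_round_trip(self, tmp_path):
        rows = [("HLA-A*01:01", "AAAAAAAAA", 0.5), ("HLA-A*01:01", "CCCCCCCCC", 12.0),
                ("HLA-B*07:02", "AAAAAAAAA", 3.25)]
        p = tmp_path / "t.tsv"
        self._write(p, rows)
        recs = load_prediction_table(p, "hla1_rank")
        assert [(r.allele, r.seq, r.value) for r in recs] == rows

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        self._write(p, [("HLA-A*01:01", "AAAAAAAAA", 0.5), ("HLA-A*01:01", "AAAAAAAAA", 1.0)])
        with pytest.raises(ValueError, match="AAAAAAAAA"):
            load_prediction_table(p, "hla1_rank")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "t.tsv"
        self._write(p, [("HLA-A*01:01", "AAAAAAAAA", 0.5)], cols=("allele", "peptide", "rankk"))
        with pytest.raises(ValueError, match="percentile_rank"):
            load_prediction_table(p, "hla1_rank")

    def test_non_numeric_value_with_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        self._write(p, [("HLA-A*01:01", "AAAAAAAAA", "abc")])
        with pytest.raises(ValueError, match="row"):
            load_prediction_table(p, "hla1_rank")

    def test_rank_outside_range_rejected(self):
        with pytest.raises(ValueError):
            PredictionRecord(seq="AAAAAAAAA", allele="x", metric="hla1_rank", value=101.0)


def _neo(seq="DWLEWLRQLSLELLK"):
    return PeptideWindow(seq=seq, parent_id="p", start=0, length=15,
                         mhc_class="II", is_mutated=True)


class TestReduce:
    def test_min_over_alleles_and_brute_force(self, rng):
        neo = _neo()
        sub9 = enumerate_9mers(neo)
        c1 = ["HLA-A*01:01", "HLA-B*07:02"]
        c2 = ["HLA-DRB1*15:01"]
        records = []
        h1 = {}
        for w in sub9:
            for a in c1:
                val = float(rng.uniform(0, 100))
                h1[(w.seq, a)] = val
                records.append(PredictionRecord(w.seq, a, "hla1_rank", val))
        records.append(PredictionRecord(neo.seq, c2[0], "hla2_rank", 7.5))
        imm, tap = {}, {}
        for w in sub9:
            imm[w.seq] = float(rng.uniform(0, 1))
            tap[w.seq] = float(rng.uniform(0, 1))
            records.append(PredictionRecord(w.seq, "", "immunogenicity", imm[w.seq]))
            records.append(PredictionRecord(w.seq, "", "tap_proteasome", tap[w.seq]))
        records.append(PredictionRecord(neo.seq, "", "vaxijen", 0.42))
        raw = reduce_to_neoantigen(neo, sub9, records, c1, c2, vaf=0.3)
        # exhaustive oracle over the 14 hla1 cells and 7 score cells
        assert raw[1] == pytest.approx(min(h1.values()))
        assert raw[2] == 7.5
        assert raw[0] == pytest.approx(max(imm.values()))
        assert raw[6] == pytest.approx(max(tap.values()))
        assert raw == (raw[0], raw[1], raw[2], 0.3, 0.42, pytest.approx(gravy(neo.seq)), raw[6])

    def test_missing_coverage_listed(self):
        neo = _neo()
        sub9 = enumerate_9mers(neo)
        with pytest.raises(ValueError, match="missing hla1_rank"):
            reduce_to_neoantigen(neo, sub9, [], ["HLA-A*01:01"], ["HLA-DRB1*15:01"], 0.5)

    def test_two_alleles_minimum(self):
        neo = _neo()
        sub9 = enumerate_9mers(neo)
        records = [PredictionRecord(w.seq, a, "hla1_rank", v)
                   for w in sub9 for a, v in (("a1", 0.4), ("a2", 2.0))]
        idx = PredictionIndex(records)
        assert min(idx.require([(w.seq, a) for w in sub9 for a in ("a1", "a2")], "hla1_rank")) == 0.4


class TestNormalize:
    @pytest.mark.parametrize("direction,expected",
                             [("higher_better", [0, 0.5, 1]), ("lower_better", [1, 0.5, 0])])
    def test_affine_map(self, direction, expected):
        assert minmax_normalize([2, 4, 6], direction) == pytest.approx(expected)

    def test_constant_column_neutral(self):
        assert minmax_normalize([3, 3, 3], "higher_better") == pytest.approx([0.5] * 3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20, unique=True))
    def test_rank_order_preserved(self, xs):
        up = minmax_normalize(xs, "higher_better")
        down = minmax_normalize(xs, "lower_better")
        assert up[int(np.argmax(xs))] == 1.0 and up[int(np.argmin(xs))] == 0.0
        order = np.argsort(xs)
        assert (np.diff(np.asarray(up)[order]) >= -1e-12).all()  # order preserved
        assert np.allclose(up + down, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([], "higher_better")


class TestAggregate:
    def test_all_ones_is_one(self):
        assert aggregate_f([1] * 7) == pytest.approx(1.0)

    def test_published_rows_hand_sums(self):
        # norm order: (imm, hlaI, hlaII, vf, ap, hpl, tap)
        row1 = (0.556, 0.875, 1, 0.199, 0.516, 0.366, 0.722)
        row5 = (1, 0.366, 0.432, 0.762, 0, 0, 0.603)
        assert aggregate_f(row1) == pytest.approx(0.6665)
        assert aggregate_f(row5) == pytest.approx(0.4961)

    def test_uniform_weights_equal_mean(self, rng):
        w = WeightConfig(*([1 / 7] * 7))
        x = rng.uniform(0, 1, 7)
        assert aggregate_f(x, w) == pytest.approx(float(x.mean()))

    def test_monotone_in_each_component(self, rng):
        x = rng.uniform(0, 0.9, 7)
        base = aggregate_f(x)
        for i in range(7):
            y = x.copy()
            y[i] += 0.1
            assert aggregate_f(y) >= base

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValueError):
            aggregate_f([1.2] + [0.5] * 6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(w_imm=0.9)  # sums to 1.7


class TestScoreCandidates:
    def _table(self, rng, n=10):
        return pd.DataFrame(rng.uniform(0, 1, (n, 7)), columns=list(VARIABLES),
                            index=[f"N{i:02d}" for i in range(n)])

    def test_permutation_equivariance(self, rng):
        t = self._table(rng)
        perm = rng.permutation(len(t))
        s1 = {s.neoantigen: s.f for s in score_candidates(t)}
        s2 = {s.neoantigen: s.f for s in score_candidates(t.iloc[perm])}
        assert s1 == pytest.approx(s2)

    def test_extremes_attained_per_column(self, rng):
        t = self._table(rng)
        svs = score_candidates(t)
        for j in range(7):
            col = [s.norm[j] for s in svs]
            assert max(col) == pytest.approx(1.0) and min(col) == pytest.approx(0.0)

    def test_missing_values_not_imputed(self, rng):
        t = self._table(rng)
        t.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="N00"):
            score_candidates(t)
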