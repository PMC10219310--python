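"""Synthetic cohort generator: determinism, construction guarantees,
the rank-model distributions, and optimum planting."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from neovax.scoring import VARIABLES, score_candidates
from neovax.selection import select_subset
from neovax.simulate import (
    CohortSpec,
    counts_from_ranks,
    expected_pass_rate,
    hla2_rank_tensor,
    make_cohort,
    make_prediction_tables,
    plant_optimum,
    simulate_hla2_counts,
    write_cohort,
)
from neovax.stats import count_passing
from neovax.variants import contexts_from_variants, somatic_filter
from neovax.windows import enumerate_pairs


class TestCohort:
    def test_construction_counts_and_full_contexts(self, small_cohort):
        spec = small_cohort.spec
        for s in small_cohort.sample_ids:
            som = somatic_filter(small_cohort.tumor[s], small_cohort.germline[s])
            assert len(som) == spec.n_mutations_per_patient
            ctxs = contexts_from_variants(som, small_cohort.models,
                                          spec.context_len, spec.mut_position)
            assert len(ctxs) == spec.n_mutations_per_patient
            assert all(len(c) == spec.context_len for c in ctxs)
            assert all(c.mut_offset == spec.mut_position - 1 for c in ctxs)

    def test_germline_duplication_fraction_exact(self):
        c = make_cohort(CohortSpec(n_patients=2, n_mutations_per_patient=12,
                                   germline_dup_fraction=0.25, seed=3))
        for s in c.sample_ids:
            tumor = c.tumor[s]
            kept = somatic_filter(tumor, c.germline[s])
            assert len(kept) / len(tumor) == pytest.approx(0.75)

    def test_seeded_determinism_byte_identical(self, tmp_path):
        spec = CohortSpec(n_patients=2, n_mutations_per_patient=4, seed=7)
        write_cohort(make_cohort(spec), tmp_path / "a")
        write_cohort(make_cohort(spec), tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f.name

    def test_seed_changes_outputs(self):
        a = make_cohort(CohortSpec(n_patients=1, n_mutations_per_patient=3, seed=1))
        b = make_cohort(CohortSpec(n_patients=1, n_mutations_per_patient=3, seed=2))
        assert [m.cds for m in a.models] != [m.cds for m in b.models]

    def test_allele_shape(self, small_cohort):
        for alleles in small_cohort.alleles.values():
            assert len(alleles) == 2 * small_cohort.spec.alleles_per_class
            assert all(a.startswith("HLA-") and "*" in a for a in alleles)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)
        with pytest.raises(ValueError):
            CohortSpec(rank_shift_delta=-0.1)


class TestRankModel:
    def test_closed_form_pass_rates(self):
        assert expected_pass_rate(0.0, 10.0) == pytest.approx(0.10)
        assert expected_pass_rate(0.5, 10.0) == pytest.approx(0.20)
        assert expected_pass_rate(0.0, 1.0) == pytest.approx(0.01)

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(123)
        draws = rng.uniform(0, 100, 10_000)
        rate = float((draws <= 1.0).mean())
        se = np.sqrt(0.01 * 0.99 / 10_000)
        assert abs(rate - 0.01) < 4 * se

    def test_shifted_tables_double_pass_rate(self, small_cohort):
        """delta=0.5 doubles the mutated Class II per-draw pass rate at
        threshold 10 while leaving wild-type at 10%."""
        spec = CohortSpec(n_patients=1, n_mutations_per_patient=60,
                          rank_shift_delta=0.5, seed=5)
        c = make_cohort(spec)
        s = c.sample_ids[0]
        ctxs = contexts_from_variants(c.tumor[s], c.models, 17, 9)
        windows = [w for w in enumerate_pairs(ctxs) if w.mhc_class == "II"]
        tables = make_prediction_tables(windows, c.alleles[s], spec,
                                        np.random.default_rng(5))
        t = tables["hla2_rank"]
        mut_seqs = {w.seq for w in windows if w.is_mutated}
        mut = t[t["peptide"].isin(mut_seqs)]["percentile_rank"]
        wt = t[~t["peptide"].isin(mut_seqs)]["percentile_rank"]
        assert abs((mut <= 10).mean() - 0.20) < 0.05  # 360 draws
        assert abs((wt <= 10).mean() - 0.10) < 0.05

    def test_vectorized_counts_equal_count_passing(self):
        """The fast calibration path and the DataFrame path agree on the
        same rank draws."""
        rng = np.random.default_rng(9)
        ranks = rng.uniform(0, 100, size=(1, 2, 30, 2))  # 1 cohort, 2 patients
        fast = counts_from_ranks(ranks, threshold=10.0)[0]
        rows = []
        for p in range(2):
            for w in range(30):
                for a in range(2):
                    rows.append((f"P{p}", "II", True, f"w{w}", f"a{a}", ranks[0, p, w, a]))
        df = pd.DataFrame(rows, columns=["sample_id", "mhc_class", "is_mutated",
                                         "window_id", "allele", "rank"])
        slow = [c.n_pass for c in sorted(count_passing(df, "II", 10.0),
                                         key=lambda c: c.sample_id)]
        assert list(fast) == slow

    def test_simulated_counts_shape_and_determinism(self):
        spec = CohortSpec(seed=0)
        m1, w1 = simulate_hla2_counts(spec, 5, seed=42)
        m2, w2 = simulate_hla2_counts(spec, 5, seed=42)
        assert m1.shape == w1.shape == (5, 6)
        assert (m1 == m2).all() and (w1 == w2).all()

    def test_tensor_shrinks_only_mutated(self):
        spec = CohortSpec(rank_shift_delta=0.5)
        mut, wt = hla2_rank_tensor(spec, 2, np.random.default_rng(0))
        assert mut.max() <= 50.0 + 1e-9 and wt.max() > 50.0


class TestPlantOptimum:
    def _table(self, rng, n=30):
        return pd.DataFrame(rng.uniform(0, 1, (n, 7)), columns=list(VARIABLES),
                            index=[f"N{i:02d}" for i in range(n)])

    def _recovers(self, rng, margin, n=30, k=6):
        t = self._table(rng, n)
        planted = [f"N{i:02d}" for i in rng.choice(n, k, replace=False)]
        adj = plant_optimum(t, planted, margin)
        scores = [(s.neoantigen, s.f) for s in score_candidates(adj)]
        return set(select_subset(scores, k).sequences) == set(planted)

    def test_recovery_margin_010(self, rng):
        assert self._recovers(rng, margin=0.1)

    def test_repeated_recovery_margin_005(self):
        hits = sum(self._recovers(np.random.default_rng(seed), margin=0.05)
                   for seed in range(20))
        assert hits == 20

    def test_noop_when_planted_already_dominate(self, rng):
        t = self._table(rng, 10)
        scores = [(s.neoantigen, s.f) for s in score_candidates(t)]
        top = select_subset(scores, 2)
        fs = sorted((f for _, f in scores), reverse=True)
        margin = (fs[1] - fs[2]) / 2
        if margin > 0:
            adj = plant_optimum(t, top.sequences, margin)
            pd.testing.assert_frame_equal(adj, t)

    def test_infeasible_margin_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_optimum(self._table(rng, 5), ["N00"], margin=1.5)

    def test_unknown_candidate_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_optimum(self._table(rng, 5), ["missing"], margin=0.1)
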