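"""Tests for contingency statistics, FDR, and cohort scans."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cskit.cohort_stats import (
    AssociationResult,
    ContingencyTable2x2,
    bh_fdr,
    build_contingency,
    cooccurrence_matrix,
    exposure_enrichment,
    fisher_exact,
    mutation_frequency,
    odds_ratio_woolf,
)
from cskit.synthetic import CohortSpec, generate_cohort

from conftest import fisher_two_sided_oracle


class TestBuildContingency:
    def test_study_counts(self, study_cohort):
        df = study_cohort.copy()
        df["is_tmn"] = (df["group"] == "t-MN").astype(int)
        t = build_contingency(df, factor="PPM1D", outcome="is_tmn")
        assert t.cells == (31, 125, 1, 227)
        assert t.n_excluded == 0

    def test_all_zero_outcome(self):
        df = pd.DataFrame({"f": [1, 1, 0, 0, 0], "o": [0, 0, 0, 0, 0]})
        t = build_contingency(df, "f", "o")
        assert t.cells == (0, 0, 2, 3)

    def test_missing_rows_excluded_and_counted(self):
        df = pd.DataFrame(
            {
                "f": [1, 0, 1, None, 0, 1, None, 0, 1, 0],
                "o": [1, 1, 0, 1, None, 1, 1, 0, 1, 0],
            }
        )
        t = build_contingency(df, "f", "o")
        assert t.total == 7
        assert t.n_excluded == 3

    def test_non_binary_column_names_values(self):
        df = pd.DataFrame({"f": [0, 1, 2], "o": [0, 1, 0]})
        with pytest.raises(ValueError, match="2"):
            build_contingency(df, "f", "o")


class TestWoolfOddsRatio:
    def test_study_table_prints_published_values(self):
        res = odds_ratio_woolf(ContingencyTable2x2(31, 125, 1, 227))
        assert round(res.odds_ratio) == 56
        assert round(res.ci_low, 1) == 7.6
        assert abs(res.ci_high - 417.3) <= 0.1
        assert not res.corrected

    def test_uniform_table_symmetric_in_log_space(self):
        res = odds_ratio_woolf(ContingencyTable2x2(1, 1, 1, 1))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_haldane_correction_hand_value(self):
        # (0,10,5,5) + 0.5 everywhere: (0.5*5.5)/(10.5*5.5) = 0.047619
        res = odds_ratio_woolf(ContingencyTable2x2(0, 10, 5, 5), zero_correction=True)
        assert res.corrected
        assert res.odds_ratio == pytest.approx(0.5 * 5.5 / (10.5 * 5.5))

    def test_zero_cell_without_correction_raises(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio_woolf(ContingencyTable2x2(0, 10, 5, 5), zero_correction=False)

    def test_matches_statsmodels_interval(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = ContingencyTable2x2(31, 125, 1, 227)
        res = odds_ratio_woolf(t)
        sm = Table2x2(t.as_array())
        lo, hi = sm.oddsratio_confint(0.05)
        assert res.odds_ratio == pytest.approx(sm.oddsratio)
        assert res.ci_low == pytest.approx(lo, rel=1e-4)
        assert res.ci_high == pytest.approx(hi, rel=1e-4)

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    def test_axis_flip_antisymmetry(self, a, b, c, d):
        r1 = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        r2 = odds_ratio_woolf(ContingencyTable2x2(b, a, d, c))
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0)
        assert r1.se_log_or == pytest.approx(r2.se_log_or)


class TestFisherExact:
    def test_study_table_significant(self):
        p = fisher_exact(ContingencyTable2x2(31, 125, 1, 227))
        assert round(p, 4) <= 0.0001

    def test_uniform_table(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle_small_tables(self):
        # exhaustive sweep: every table with total <= 12 (hence margins <= 12)
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if not 0 < a + b + c + d <= 12:
                continue
            p = fisher_exact(ContingencyTable2x2(a, b, c, d))
            oracle = fisher_two_sided_oracle(a, b, c, d)
            assert p == pytest.approx(oracle, abs=1e-10), (a, b, c, d)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        # a spread-out vector, worked by hand: q_i = min_{j>=i} p_j * m / j
        assert bh_fdr([0.005, 0.04, 0.2, 0.9]) == pytest.approx(
            [0.02, 0.08, 4 * 0.2 / 3, 0.9]
        )

    def test_equal_ps_unchanged_and_singleton_identity(self):
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
        assert bh_fdr([0.3]) == [0.3]
        assert bh_fdr([]) == []

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12), st.randoms())
    def test_permutation_equivariance(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        q = bh_fdr(ps)
        q_perm = bh_fdr([ps[i] for i in idx])
        assert q_perm == pytest.approx([q[i] for i in idx])

    @given(
        st.lists(st.floats(0.0, 0.9), min_size=2, max_size=8),
        st.integers(0, 7),
        st.floats(0.01, 0.1),
    )
    def test_monotone_in_each_p(self, ps, which, bump):
        which %= len(ps)
        bumped = list(ps)
        bumped[which] = min(1.0, bumped[which] + bump)
        q0, q1 = bh_fdr(ps), bh_fdr(bumped)
        assert all(b >= a - 1e-12 for a, b in zip(q0, q1))


class TestMutationFrequency:
    def test_study_frequencies(self, study_cohort):
        freq = mutation_frequency(study_cohort, "PPM1D", by="subtype")
        k, n, f = freq["t-AML"]
        assert (k, n) == (15, 77)
        assert round(100 * f, 1) == 19.5


class TestCooccurrence:
    def test_matrix_symmetric_with_masked_diagonal(self):
        spec = CohortSpec(n_case=120, n_control=120, base_rate=0.2, seed=3)
        cohort, variants = generate_cohort(spec)
        m = cooccurrence_matrix(variants, cohort, list(spec.genes))
        for frame in (m.log_or, m.p, m.q):
            assert frame.equals(frame.T)
            assert np.isnan(np.diag(frame.to_numpy())).all()

    def test_missing_gene_listed(self):
        spec = CohortSpec(n_case=10, n_control=10, seed=0)
        cohort, variants = generate_cohort(spec)
        with pytest.raises(ValueError, match="NPM1"):
            cooccurrence_matrix(variants, cohort, ["PPM1D", "NPM1"])

    def test_clonal_stratum_item_added(self):
        spec = CohortSpec(n_case=300, n_control=300, base_rate=0.3, seed=4)
        cohort, variants = generate_cohort(spec)
        m = cooccurrence_matrix(
            variants, cohort, list(spec.genes), clonal_only_for={"PPM1D": 0.2}
        )
        assert "PPM1D clonal" in m.items
        # the clonal stratum is a strict subset of the mutated samples, so it
        # co-occurs positively with the parent gene flag
        assert m.log_or.loc["PPM1D clonal", "PPM1D"] > 0

    def test_planted_cooccurrence_recovered(self):
        hits = 0
        for s in range(50):
            spec = CohortSpec(
                n_case=250, n_control=250, base_rate=0.15,
                cooccur_log_or={("PPM1D", "TP53"): 2.0}, seed=s,
            )
            cohort, variants = generate_cohort(spec)
            m = cooccurrence_matrix(variants, cohort, list(spec.genes))
            hits += (m.log_or.loc["PPM1D", "TP53"] > 0) and (
                m.q.loc["PPM1D", "TP53"] < 0.1
            )
        assert hits >= 45

    def test_independent_genes_controlled(self):
        fracs = []
        for s in range(50):
            spec = CohortSpec(n_case=250, n_control=250, base_rate=0.15, seed=700 + s)
            cohort, variants = generate_cohort(spec)
            m = cooccurrence_matrix(variants, cohort, list(spec.genes))
            qs = [
                m.q.iloc[i, j]
                for i, j in itertools.combinations(range(len(m.items)), 2)
            ]
            fracs.append(np.mean([q < 0.1 for q in qs]))
        assert np.mean(fracs) <= 0.10


class TestExposureEnrichment:
    def test_empty_exposures_rejected(self):
        spec = CohortSpec(n_case=10, n_control=10, seed=0)
        cohort, _ = generate_cohort(spec)
        with pytest.raises(ValueError, match="non-empty"):
            exposure_enrichment(cohort, "PPM1D", [])

    def test_exposure_identical_to_outcome_guarded(self):
        spec = CohortSpec(n_case=100, n_control=100, base_rate=0.3, seed=1)
        cohort, _ = generate_cohort(spec)
        cohort["self"] = cohort["PPM1D"]
        res = exposure_enrichment(cohort, "PPM1D", ["self"])
        assert res[0].corrected
        assert math.isfinite(res[0].odds_ratio) and res[0].odds_ratio > 1

    def test_zero_prevalence_flagged_and_outside_fdr_family(self):
        spec = CohortSpec(n_case=50, n_control=50, base_rate=0.3, seed=1)
        cohort, _ = generate_cohort(spec)
        cohort["never"] = 0
        res = exposure_enrichment(cohort, "PPM1D", ["never", "cisplatin"])
        flagged = next(r for r in res if r.factor == "never")
        assert not flagged.estimable and flagged.q is None
        assert next(r for r in res if r.factor == "cisplatin").q is not None

    def test_sampling_distribution_around_planted_or(self):
        # planted odds ratio 2.9 at a ~140-sample cohort: the point estimate
        # lands in [1.5, 5.5] in at least 80% of seeds
        hits = 0
        for s in range(100):
            spec = CohortSpec(
                n_case=139, n_control=1, base_rate=0.15,
                effect_log_or={("cisplatin", "PPM1D"): math.log(2.9)}, seed=s,
            )
            cohort, _ = generate_cohort(spec)
            res = exposure_enrichment(cohort, "PPM1D", ["cisplatin"])
            hits += 1.5 <= res[0].odds_ratio <= 5.5
        assert hits >= 80

    def test_results_sorted_by_q_then_p(self):
        spec = CohortSpec(
            n_case=300, n_control=300, base_rate=0.15,
            effect_log_or={("cisplatin", "PPM1D"): 1.2}, seed=6,
        )
        cohort, _ = generate_cohort(spec)
        res = exposure_enrichment(
            cohort, "PPM1D", ["vincristine", "cisplatin", "etoposide"]
        )
        keys = [(r.q, r.p_exact) for r in res if r.estimable]
        assert keys == sorted(keys)
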