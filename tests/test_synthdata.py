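"""Generator contracts: exact partition sizes, determinism, null behaviour,
spike-in construction, and copula correlation targets."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from mimiscan import synthdata
from mimiscan.catalog import assign_groups
from mimiscan.mimicry import (CE1_QUERY_SEQUENCE, EpitopeQuery,
                              compute_fold_changes, intersect_enriched,
                              run_mimicry_funnel)

QUERY = EpitopeQuery(CE1_QUERY_SEQUENCE, "CE1")


def small_cohort_spec(**kw):
    defaults = dict(n_healthy=40, n_cld=40, n_hcc=40,
                    n_peptides_per_group=(15, 25, 60), seed=11)
    defaults.update(kw)
    return synthdata.CohortSpec(**defaults)


class TestSerologyCohort:
    def test_partition_sizes_exact_at_published_catalog_size(self):
        spec = small_cohort_spec(n_peptides_per_group=(59, 281, 1671),
                                 n_healthy=5, n_cld=5, n_hcc=5)
        cohort = synthdata.generate_serology_cohort(spec)
        groups = assign_groups(cohort.catalog, cohort.annotations)
        counts = pd.Series([g.value for g in groups.values()]).value_counts()
        assert counts["CE1_VP1"] == 59
        assert counts["NON_CE1_VP1"] == 281
        assert counts["NON_VP1"] == 1671

    @pytest.mark.parametrize("sizes", [(3, 4, 5), (20, 1, 1), (1, 1, 50)])
    def test_partition_sizes_exact_various(self, sizes):
        cohort = synthdata.generate_serology_cohort(
            small_cohort_spec(n_peptides_per_group=sizes))
        counts = pd.Series(list(cohort.assignments.values())).value_counts()
        got = (counts.get("CE1_VP1", 0), counts.get("NON_CE1_VP1", 0),
               counts.get("NON_VP1", 0))
        assert got == sizes

    def test_determinism_bit_identical(self):
        spec = small_cohort_spec(seed=7)
        a = synthdata.generate_serology_cohort(spec)
        b = synthdata.generate_serology_cohort(spec)
        pd.testing.assert_frame_equal(a.ebs, b.ebs)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        assert a.catalog == b.catalog

    def test_seed_changes_output(self):
        a = synthdata.generate_serology_cohort(small_cohort_spec(seed=1))
        b = synthdata.generate_serology_cohort(small_cohort_spec(seed=2))
        assert not a.ebs.equals(b.ebs)

    def test_ebs_nonnegative_and_zero_inflated(self):
        cohort = synthdata.generate_serology_cohort(small_cohort_spec())
        vals = cohort.ebs.to_numpy()
        assert (vals >= 0).all()
        assert (vals == 0).mean() > 0.1  # substantial zero mass

    def test_null_spec_gives_no_group_difference(self):
        """shift=0, OR=1: healthy-vs-HCC CE1 mean difference is null."""
        nonsig = 0
        for seed in range(20):
            cohort = synthdata.generate_serology_cohort(
                small_cohort_spec(ebs_location_shift=0.0,
                                  diagnosis_or_per_ebs_unit=1.0, seed=seed))
            ce1 = [p for p, g in cohort.assignments.items() if g == "CE1_VP1"]
            x = cohort.ebs[ce1].mean(axis=1)
            dx = cohort.metadata["diagnosis"]
            p = ttest_ind(x[dx == "healthy"], x[dx == "HCC"]).pvalue
            nonsig += p >= 0.05
        assert nonsig >= 18  # >= 90% of replicates

    def test_location_shift_raises_healthy_ce1(self):
        cohort = synthdata.generate_serology_cohort(
            small_cohort_spec(ebs_location_shift=2.0, seed=3))
        ce1 = [p for p, g in cohort.assignments.items() if g == "CE1_VP1"]
        x = cohort.ebs[ce1].mean(axis=1)
        dx = cohort.metadata["diagnosis"]
        assert x[dx == "healthy"].mean() > x[dx == "HCC"].mean()

    def test_survival_only_for_hcc(self):
        cohort = synthdata.generate_serology_cohort(small_cohort_spec())
        meta = cohort.metadata
        assert meta.loc[meta["diagnosis"] != "HCC", "survival_time"].isna().all()
        assert meta.loc[meta["diagnosis"] == "HCC", "survival_time"].notna().all()

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="censor_rate"):
            synthdata.generate_serology_cohort(
                small_cohort_spec(censor_rate=1.5))
        with pytest.raises(ValueError, match="arb_hazard_ratio"):
            synthdata.generate_serology_cohort(
                small_cohort_spec(arb_hazard_ratio=-1.0))


class TestIpmsTables:
    def test_determinism(self):
        spec = synthdata.MimicrySpec(n_background_proteins=40, seed=5)
        a = synthdata.generate_ipms_tables(spec, QUERY)
        b = synthdata.generate_ipms_tables(spec, QUERY)
        for line in a.inputs.tables:
            pd.testing.assert_frame_equal(a.inputs.tables[line],
                                          b.inputs.tables[line])
        assert a.sequences == b.sequences
        assert a.surface_list == b.surface_list

    def test_spiked_mimic_recovered_rank_one(self):
        spec = synthdata.MimicrySpec(n_background_proteins=200,
                                     n_spiked_surface_mimics=1,
                                     enrichment_fold_spiked=500.0, seed=13)
        bundle = synthdata.generate_ipms_tables(spec, QUERY)
        res = run_mimicry_funnel(bundle.inputs, bundle.surface_list,
                                 bundle.sequences, QUERY)
        assert res.ranking.iloc[0]["candidate"] == bundle.mimic_ids[0]

    def test_fold_fifty_excluded_by_strict_cutoff(self):
        spec = synthdata.MimicrySpec(n_background_proteins=50,
                                     enrichment_fold_spiked=50.0, seed=17)
        bundle = synthdata.generate_ipms_tables(spec, QUERY)
        enriched = intersect_enriched(compute_fold_changes(bundle.inputs))
        assert bundle.mimic_ids[0] not in enriched

    def test_mimic_carries_planted_subsequence(self):
        spec = synthdata.MimicrySpec(n_background_proteins=10,
                                     mimic_identity_fraction=1.0, seed=19)
        bundle = synthdata.generate_ipms_tables(spec, QUERY)
        assert QUERY.sequence in bundle.sequences[bundle.mimic_ids[0]]
        assert bundle.mimic_ids[0] in bundle.surface_list

    def test_identity_fraction_validation(self):
        with pytest.raises(ValueError, match="mimic_identity_fraction"):
            synthdata.generate_ipms_tables(
                synthdata.MimicrySpec(mimic_identity_fraction=0.01, seed=1),
                QUERY)
        with pytest.raises(ValueError, match="mimic_identity_fraction"):
            synthdata.MimicrySpec(mimic_identity_fraction=0.0).validate()


class TestExpressionCohort:
    def test_determinism(self):
        spec = synthdata.ExpressionSpec(seed=23)
        a = synthdata.generate_expression_cohort(spec)
        b = synthdata.generate_expression_cohort(spec)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)

    def test_copula_hits_target_spearman(self):
        spec = synthdata.ExpressionSpec(n_tumors=1000, n_seropositive=500,
                                        adcc_asph_rho_pos=0.9,
                                        adcc_asph_rho_neg=0.0, seed=29,
                                        signature_noise_sd=0.0)
        bundle = synthdata.generate_expression_cohort(spec)
        # raw latent check, independent of the signature pipeline
        pos = bundle.metadata["seropositive"].to_numpy()
        ds = bundle.metadata["dataset"].to_numpy()
        # z-score within dataset to undo the affine distortion
        asph = np.empty(1000)
        sig = np.empty(1000)
        for d in np.unique(ds):
            cols = ds == d
            for src, dst in ((bundle.expression.loc["ASPH"], asph),
                             (bundle.expression.loc["GZMA"], sig)):
                v = src.to_numpy()[cols]
                dst[cols] = (v - v.mean()) / v.std(ddof=1)
        rho_pos = spearmanr(asph[pos], sig[pos]).statistic
        rho_neg = spearmanr(asph[~pos], sig[~pos]).statistic
        assert rho_pos == pytest.approx(0.9, abs=0.1)
        assert abs(rho_neg) < 0.15

    def test_nk_fractions_per_stratum(self):
        spec = synthdata.ExpressionSpec(n_tumors=600, n_seropositive=300,
                                        nk_high_fraction_pos=0.7,
                                        nk_high_fraction_neg=0.2, seed=31)
        bundle = synthdata.generate_expression_cohort(spec)
        high = bundle.metadata["nk_score"] > 0.01
        pos = bundle.metadata["seropositive"]
        assert high[pos].mean() == pytest.approx(0.7, abs=0.1)
        assert high[~pos].mean() == pytest.approx(0.2, abs=0.1)

    def test_seropositive_bound_validation(self):
        with pytest.raises(ValueError, match="n_seropositive"):
            synthdata.ExpressionSpec(n_tumors=10, n_seropositive=20).validate()
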