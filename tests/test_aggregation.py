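"""Burden assembly, cohort averaging, concordance and report derivation."""

import numpy as np
import pandas as pd
import pytest

from geneburden import (
    ConstraintMetrics,
    GeneAnnotation,
    GeneBurden,
    InheritanceMode,
    PopulationConfig,
    ReportedPrevalence,
    Tier,
    TierSet,
    average_cohorts,
    build_full_report,
    carrier_frequency,
    cohort_concordance,
    compute_gene_burden,
    constraint_comparison,
    crf_regression,
    disease_group_burden,
    genetic_prevalence,
    rank_top_genes,
    scale_to_population,
    screening_candidates,
    secondary_findings_report,
)

from conftest import make_variant


def ann(symbol, mode=InheritanceMode.AR, **kw):
    return GeneAnnotation(symbol=symbol, inheritance=mode, **kw)


def burden(gene, caf, mode=InheritanceMode.AR, anc="nfe", ts=TierSet.PLP, n=1):
    return GeneBurden(
        gene=gene, ancestry=anc, tier_set=ts, caf=caf,
        crf=carrier_frequency(caf), gp=genetic_prevalence(caf, mode), n_variants=n,
    )


class TestComputeGeneBurden:
    def test_chained_hand_example(self):
        genes = [ann("G1")]
        variants = [
            make_variant("1:1:A:T", "G1", ac={"nfe": 1}, an={"nfe": 100},
                         an_max={"nfe": 100}),
            make_variant("1:2:A:T", "G1", ac={"nfe": 2}, an={"nfe": 100},
                         an_max={"nfe": 100}),
        ]
        (b,) = compute_gene_burden(variants, genes, TierSet.P, "nfe")
        assert b.caf == pytest.approx(0.03)
        assert b.crf == pytest.approx(0.0582)
        assert b.gp == pytest.approx(9e-4)
        assert b.n_variants == 2

    def test_gene_without_variants_gets_zeros(self):
        (b,) = compute_gene_burden([], [ann("G1")], TierSet.P, "nfe")
        assert (b.caf, b.crf, b.gp) == (0.0, 0.0, 0.0)

    def test_caf_monotone_in_tier_set(self):
        genes = [ann("G1")]
        variants = [
            make_variant("1:1:A:T", "G1", tier=Tier.P),
            make_variant("1:2:A:T", "G1", tier=Tier.LP),
        ]
        caf = {
            ts: compute_gene_burden(variants, genes, ts, "nfe")[0].caf
            for ts in (TierSet.P, TierSet.PLP, TierSet.PLPVH)
        }
        assert caf[TierSet.P] <= caf[TierSet.PLP] <= caf[TierSet.PLPVH]

    def test_unknown_gene_warns_and_skips(self):
        with pytest.warns(RuntimeWarning, match="outside the"):
            out = compute_gene_burden(
                [make_variant("1:1:A:T", "NOPE")], [ann("G1")], TierSet.P, "nfe"
            )
        assert out[0].caf == 0.0


class TestAverageCohorts:
    def test_caf_averaged_crf_recomputed(self):
        genes = [ann("G1")]
        a = [burden("G1", 0.01)]
        b = [burden("G1", 0.03)]
        (avg,), log = average_cohorts(a, b, ["nfe"], genes)
        assert avg.caf == pytest.approx(0.02)
        assert avg.crf == pytest.approx(0.0392)
        assert log == []

    def test_gene_missing_from_one_cohort_zero_imputed(self):
        genes = [ann("G1"), ann("G2")]
        a = [burden("G1", 0.02), burden("G2", 0.04)]
        b = [burden("G1", 0.02)]
        avg, log = average_cohorts(a, b, ["nfe"], genes)
        by_gene = {x.gene: x for x in avg}
        assert by_gene["G2"].caf == pytest.approx(0.02)
        assert any("G2" in line for line in log)

    def test_identical_cohorts_identity(self):
        genes = [ann("G1")]
        a = [burden("G1", 0.05)]
        avg, _ = average_cohorts(a, a, ["nfe"], genes)
        assert avg[0].caf == pytest.approx(0.05)

    def test_unshared_ancestry_passes_through(self):
        genes = [ann("G1")]
        a = [burden("G1", 0.02, anc="tur")]
        b = [burden("G1", 0.04, anc="nfe")]
        avg, _ = average_cohorts(a, b, [], genes)
        by_anc = {x.ancestry: x.caf for x in avg}
        assert by_anc == {"tur": 0.02, "nfe": 0.04}

    def test_missing_shared_ancestry_is_error(self):
        genes = [ann("G1")]
        with pytest.raises(ValueError, match="missing from cohort"):
            average_cohorts([burden("G1", 0.01)], [burden("G1", 0.01, anc="afr")],
                            ["nfe"], genes)


class TestCohortConcordance:
    def _burdens(self, cafs, anc="nfe"):
        return [burden(f"G{i}", c, anc=anc) for i, c in enumerate(cafs)]

    def test_identical_vectors_r_one(self):
        a = self._burdens([0.01, 0.02, 0.03])
        res = cohort_concordance(a, a, TierSet.PLP)
        assert res.per_ancestry["nfe"] == pytest.approx(1.0)
        assert res.mean == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        a = self._burdens([0.01, 0.02, 0.03])
        b = self._burdens([0.02, 0.02, 0.02])
        res = cohort_concordance(a, b, TierSet.PLP)
        assert res.per_ancestry["nfe"] is None

    def test_anti_ordered_r_minus_one(self):
        a = self._burdens([0.001, 0.002, 0.003])
        b = self._burdens([0.003, 0.002, 0.001])
        res = cohort_concordance(a, b, TierSet.PLP)
        assert res.per_ancestry["nfe"] == pytest.approx(-1.0)

    def test_fewer_than_three_nonzero_undefined(self):
        a = self._burdens([0.01, 0.02, 0.0])
        b = self._burdens([0.01, 0.02, 0.03])
        assert cohort_concordance(a, b, TierSet.PLP).per_ancestry["nfe"] is None


class TestCrfRegression:
    def test_exact_match_r_one(self):
        reported = [ReportedPrevalence(gene=f"G{i}", rp=p)
                    for i, p in enumerate([1e-4, 4e-4, 1e-3, 4e-3])]
        calculated = {r.gene: r.rcrf for r in reported}
        res = crf_regression(reported, calculated)
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_constant_log_offset_slope_one(self):
        reported = [ReportedPrevalence(gene=f"G{i}", rp=p)
                    for i, p in enumerate([1e-4, 4e-4, 1e-3, 4e-3])]
        calculated = {r.gene: 2.0 * r.rcrf for r in reported}
        res = crf_regression(reported, calculated)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(np.log(2.0))

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(11)
        reported = [
            ReportedPrevalence(gene=f"G{i}", rp=float(10 ** rng.uniform(-6, -2)))
            for i in range(1000)
        ]
        calculated = {
            f"G{i}": float(10 ** rng.uniform(-4, -1)) for i in range(1000)
        }
        res = crf_regression(reported, calculated)
        assert abs(res.r) < 0.1

    def test_too_few_pairs_is_error(self):
        reported = [ReportedPrevalence(gene="G0", rp=1e-4)]
        with pytest.raises(ValueError, match="at least 3"):
            crf_regression(reported, {"G0": 0.01})


class TestDiseaseGroupBurden:
    def test_sum_within_group(self):
        genes = [
            ann("G1", disease_groups=frozenset({"eye"})),
            ann("G2", disease_groups=frozenset({"eye"})),
        ]
        burdens = [burden("G1", 0.1), burden("G2", np.sqrt(0.02))]
        with pytest.warns(RuntimeWarning):  # 12 empty groups
            df = disease_group_burden(burdens, genes, TierSet.PLP)
        eye = df[(df["group"] == "eye") & (df["ancestry"] == "nfe")]["GP"].iloc[0]
        assert eye == pytest.approx(0.01 + 0.02)

    def test_multi_group_gene_counts_in_every_group(self):
        genes = [ann("G1", disease_groups=frozenset({"eye", "ear"}))]
        burdens = [burden("G1", 0.1)]
        with pytest.warns(RuntimeWarning):
            df = disease_group_burden(burdens, genes, TierSet.PLP)
        sub = df[(df["ancestry"] == "nfe") & df["group"].isin(["eye", "ear"])]
        assert list(sub["GP"]) == [pytest.approx(0.01)] * 2

    def test_ad_ar_gene_contributes_both_phenotype_terms(self):
        genes = [ann("G1", InheritanceMode.AD_AR, disease_groups=frozenset({"skin"}))]
        burdens = [burden("G1", 0.1, InheritanceMode.AD_AR)]
        with pytest.warns(RuntimeWarning):
            df = disease_group_burden(burdens, genes, TierSet.PLP)
        skin = df[(df["group"] == "skin") & (df["ancestry"] == "nfe")]["GP"].iloc[0]
        assert skin == pytest.approx(0.18 + 0.01)


class TestRankTopGenes:
    def test_descending_with_truncation(self):
        burdens = [burden("A", 0.2, InheritanceMode.AD), burden("B", 0.1, InheritanceMode.AD),
                   burden("C", 0.3, InheritanceMode.AD)]
        df = rank_top_genes(burdens, metric="CrF", n=2)
        assert list(df["gene"]) == ["C", "A"]

    def test_ties_alphabetical(self):
        burdens = [burden("ZZZ", 0.2, InheritanceMode.AD), burden("AAA", 0.2, InheritanceMode.AD)]
        df = rank_top_genes(burdens, metric="CrF", n=2)
        assert list(df["gene"]) == ["AAA", "ZZZ"]

    def test_n_larger_than_genes(self):
        df = rank_top_genes([burden("A", 0.1)], metric="GP", n=100)
        assert len(df) == 1

    def test_nonpositive_n_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            rank_top_genes([burden("A", 0.1)], n=0)


class TestScreeningCandidates:
    def test_threshold_strict(self):
        def with_crf(gene, crf):
            return GeneBurden(gene=gene, ancestry="nfe", tier_set=TierSet.PLP,
                              caf=0.01, crf=crf, gp=1e-4, n_variants=1)

        burdens = [with_crf("ABOVE", 1 / 150), with_crf("EXACT", 1 / 200)]
        res = screening_candidates(burdens)
        assert res.per_ancestry["nfe"] == {"ABOVE"}  # exact threshold excluded

    def test_union_and_intersection(self):
        burdens = [
            burden("A", 0.1, anc="afr"), burden("A", 0.0001, anc="nfe"),
            burden("B", 0.1, anc="afr"), burden("B", 0.1, anc="nfe"),
        ]
        res = screening_candidates(burdens)
        assert res.union == {"A", "B"}
        assert res.intersection == {"B"}
        for anc_set in res.per_ancestry.values():
            assert res.intersection <= anc_set


class TestSecondaryFindings:
    def test_cumulative_over_toy_sf_set(self):
        genes = [
            ann("SF1", secondary_finding=True, sf_phenotype_group="cancer"),
            ann("SF2", secondary_finding=True, sf_phenotype_group="cardiovascular"),
            ann("OTHER"),
        ]
        variants = [
            make_variant("1:1:A:T", "SF1", ac={"nfe": 1}, an={"nfe": 199},
                         an_max={"nfe": 199}),
            make_variant("1:2:A:T", "SF2", ac={"nfe": 2}, an={"nfe": 198},
                         an_max={"nfe": 198}),
            make_variant("1:3:A:T", "OTHER", ac={"nfe": 50}, an={"nfe": 100},
                         an_max={"nfe": 100}),
        ]
        res = secondary_findings_report(variants, genes, TierSet.PLP, ["nfe"])
        cum = res.cumulative.iloc[0]
        caf1, caf2 = 1 / 199, 2 / 198
        expected = carrier_frequency(caf1) + carrier_frequency(caf2)
        assert cum["cumulative_crf"] == pytest.approx(expected)
        assert len(res.per_gene) == 2  # OTHER not a secondary-finding gene
        assert set(res.phenotype_groups["sf_phenotype_group"]) == {
            "cancer", "cardiovascular",
        }

    def test_restricted_gene_uses_only_listed_variants(self):
        genes = [
            ann("HFE", secondary_finding=True, sf_phenotype_group="miscellaneous",
                restricted_variant_ids=("6:1:G:A",)),
        ]
        variants = [
            make_variant("6:1:G:A", "HFE", ac={"nfe": 10}, an={"nfe": 1000}),
            make_variant("6:2:G:A", "HFE", ac={"nfe": 50}, an={"nfe": 1000}),
            make_variant("6:3:G:A", "HFE", ac={"nfe": 90}, an={"nfe": 1000}),
        ]
        res = secondary_findings_report(variants, genes, TierSet.PLP, ["nfe"])
        assert res.per_gene["CAF"].iloc[0] == pytest.approx(0.01)

    def test_unknown_restricted_id_is_error(self):
        genes = [ann("HFE", secondary_finding=True, restricted_variant_ids=("6:9:G:A",))]
        with pytest.raises(ValueError, match="6:9:G:A"):
            secondary_findings_report(
                [make_variant("6:1:G:A", "HFE")], genes, TierSet.PLP, ["nfe"]
            )

    def test_empty_sf_set_gives_zeros(self):
        res = secondary_findings_report(
            [make_variant("1:1:A:T", "G1")], [ann("G1")], TierSet.PLP, ["nfe"]
        )
        assert res.cumulative["cumulative_crf"].iloc[0] == 0.0
        assert len(res.per_gene) == 0


class TestScaleToPopulation:
    def test_ancestry_scope(self):
        cfg = PopulationConfig(cohort_individuals={"x": 1}, world_population={"x": 1000})
        assert scale_to_population(0.1, cfg, ancestry="x") == pytest.approx(100.0)
        assert scale_to_population(0.0, cfg, ancestry="x") == 0.0

    def test_global_is_weighted_sum_not_mean(self):
        cfg = PopulationConfig(
            cohort_individuals={"a": 1, "b": 1},
            world_population={"a": 100, "b": 300},
        )
        total = scale_to_population({"a": 0.1, "b": 0.3}, cfg)
        assert total == pytest.approx(10 + 90)
        assert total != pytest.approx(0.2 * 400)

    def test_conservation(self):
        cfg = PopulationConfig(
            cohort_individuals={"a": 1, "b": 1},
            world_population={"a": 123, "b": 456},
        )
        prev = {"a": 0.05, "b": 0.25}
        assert scale_to_population(prev, cfg) == pytest.approx(
            sum(scale_to_population(p, cfg, ancestry=a) for a, p in prev.items())
        )

    def test_unknown_ancestry_is_error(self):
        cfg = PopulationConfig(cohort_individuals={"x": 1}, world_population={"x": 10})
        with pytest.raises(ValueError, match="unknown ancestry"):
            scale_to_population(0.1, cfg, ancestry="y")


class TestConstraintComparison:
    def test_threshold_boundaries_strict(self):
        genes = [ann("G1", disease_groups=frozenset({"eye"}))]
        m_in = ConstraintMetrics(gene="G1", pli=0.9, loeuf=0.5, mis_z=3.10, syn_z=0.0)
        m_out = ConstraintMetrics(gene="G1", pli=0.9, loeuf=0.6, mis_z=3.09, syn_z=3.71)
        assert m_in.loeuf_constrained and m_in.mis_constrained
        assert not (m_out.loeuf_constrained or m_out.mis_constrained or m_out.syn_constrained)
        res = constraint_comparison([m_in], genes)
        assert bool(res.flags["loeuf_constrained"].iloc[0]) is True

    def test_planted_effect_direction_recovered(self):
        rng = np.random.default_rng(7)
        genes, metrics = [], []
        for i in range(60):
            multi = i % 2 == 0
            groups = frozenset({"eye", "ear"}) if multi else frozenset({"eye"})
            genes.append(ann(f"G{i:03d}", disease_groups=groups))
            loeuf = rng.uniform(0.1, 0.5) if multi else rng.uniform(0.7, 1.5)
            metrics.append(
                ConstraintMetrics(gene=f"G{i:03d}", pli=0.5, loeuf=float(loeuf),
                                  mis_z=0.0, syn_z=0.0)
            )
        res = constraint_comparison(metrics, genes)
        assert res.direction == "multi_more_constrained"
        assert res.p_value < 1e-6
        assert res.constrained_fraction_multi > res.constrained_fraction_single

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            constraint_comparison(
                [ConstraintMetrics(gene="X", pli=0, loeuf=1, mis_z=0, syn_z=0)],
                [ann("G1")],
            )


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # toy gene sets leave groups empty
class TestBuildFullReport:
    @pytest.fixture
    def inputs(self, toy_genes, two_anc_config):
        variants = [
            make_variant("7:1:A:T", "CFTR", Tier.P, ac={"afr": 2, "nfe": 8}),
            make_variant("7:2:A:T", "CFTR", Tier.LP, ac={"afr": 1, "nfe": 4}),
            make_variant("1:1:A:T", "F5", Tier.LP, ac={"afr": 30, "nfe": 28}),
            make_variant("6:26092913:G:A", "HFE", Tier.P, ac={"afr": 10, "nfe": 60}),
            make_variant("6:2:G:A", "HFE", Tier.LP, ac={"afr": 5, "nfe": 5}),
            make_variant("X:1:G:A", "G6PD", Tier.P, ac={"afr": 40, "nfe": 2},
                         an={"afr": 750, "nfe": 750}, an_max={"afr": 750, "nfe": 750}),
        ]
        return variants, toy_genes, two_anc_config

    def test_sections_populated(self, inputs):
        variants, genes, config = inputs
        rep = build_full_report(variants, genes, config)
        assert len(rep.gene_burden) == 4 * 2 * 3  # genes x ancestries x tier sets
        assert set(rep.cumulative["ancestry"]) == {"afr", "nfe", "mean"}
        assert len(rep.group_gp[rep.group_gp["ancestry"] != "mean"]) == 13 * 2 * 3
        assert not rep.secondary.per_gene.empty
        assert not rep.scaled_counts.empty

    def test_row_order_invariance(self, inputs):
        variants, genes, config = inputs
        rep1 = build_full_report(variants, genes, config)
        rep2 = build_full_report(list(reversed(variants)), list(reversed(genes)), config)
        pd.testing.assert_frame_equal(rep1.gene_burden, rep2.gene_burden)
        pd.testing.assert_frame_equal(rep1.cumulative, rep2.cumulative)
        pd.testing.assert_frame_equal(rep1.group_gp, rep2.group_gp)

    def test_tier_widening_never_decreases_cumulative_metrics(self, inputs):
        variants, genes, config = inputs
        rep = build_full_report(variants, genes, config)
        cum = rep.cumulative[rep.cumulative["ancestry"] == "mean"].set_index("tier_set")
        for col in ("cumulative_crf", "cumulative_gp"):
            vals = [cum.loc[ts, col] for ts in ("P", "P+LP", "P+LP+VUS-H")]
            assert vals == sorted(vals)

    def test_hfe_restriction_only_in_secondary_section(self, inputs):
        variants, genes, config = inputs
        rep = build_full_report(variants, genes, config)
        # main burden table uses all HFE P+LP variants; SF section only C282Y
        main = rep.gene_burden.query(
            "gene == 'HFE' and ancestry == 'nfe' and tier_set == 'P+LP'"
        )["CAF"].iloc[0]
        sf = rep.secondary.per_gene.query("gene == 'HFE' and ancestry == 'nfe'")[
            "CAF"
        ].iloc[0]
        assert main == pytest.approx(65 / 1000)
        assert sf == pytest.approx(60 / 1000)
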