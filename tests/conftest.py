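import pytest

from geneburden import (
    GeneAnnotation,
    InheritanceMode,
    PopulationConfig,
    Tier,
    VariantRecord,
)


def make_variant(
    vid: str,
    gene: str,
    tier: Tier = Tier.P,
    filter_status: str = "PASS",
    ac: dict | None = None,
    an: dict | None = None,
    an_max: dict | None = None,
) -> VariantRecord:
    """Variant with full coverage in two ancestries unless overridden."""
    ac = ac if ac is not None else {"afr": 1, "nfe": 2}
    an = an if an is not None else {a: 1000 for a in ac}
    an_max = an_max if an_max is not None else {a: 1000 for a in ac}
    return VariantRecord(
        variant_id=vid, gene=gene, tier=tier, filter_status=filter_status,
        ac=ac, an=an, an_max=an_max,
    )


@pytest.fixture
def two_anc_config() -> PopulationConfig:
    return PopulationConfig(
        cohort_individuals={"afr": 500, "nfe": 500},
        world_population={"afr": 1_400_000_000, "nfe": 940_000_000},
    )


@pytest.fixture
def toy_genes() -> list[GeneAnnotation]:
    return [
        GeneAnnotation(
            symbol="CFTR",
            inheritance=InheritanceMode.AR,
            disease_groups=frozenset(
                {"blood_immune", "congenital", "digestive", "endocrine_metabolic",
                 "respiratory"}
            ),
            sources=frozenset({"PanelApp", "OMIM"}),
        ),
        GeneAnnotation(
            symbol="F5",
            inheritance=InheritanceMode.AD_AR,
            disease_groups=frozenset({"blood_immune"}),
            sources=frozenset({"OMIM"}),
        ),
        GeneAnnotation(
            symbol="HFE",
            inheritance=InheritanceMode.AR,
            disease_groups=frozenset({"endocrine_metabolic"}),
            secondary_finding=True,
            sf_phenotype_group="miscellaneous",
            restricted_variant_ids=("6:26092913:G:A",),
        ),
        GeneAnnotation(
            symbol="G6PD",
            inheritance=InheritanceMode.XLR,
            disease_groups=frozenset({"blood_immune"}),
        ),
    ]
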