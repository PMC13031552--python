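"""Synthetic cohorts with known ground truth, and a genotype-level oracle.

The generator emulates what an exome-scale population summary release looks
like to this pipeline: a mixed-inheritance disease gene set, per-gene
variant lists with a seven-tier classification whose proportions default to
the observed exome-wide shares (P 0.5%, LP 2.4%, VUS-H 1.8%, VUS-M 3.0%,
VUS-L 68.1%, LB 23.6%, B 0.6%), rare allele frequencies (log-uniform) with
occasional common outliers, binomial AC sampling given AN, and planted QC
failures (non-PASS rows, low-coverage ancestry pairs).  Ground truth records
the exact per-gene CAF per ancestry and tier set implied by the true allele
frequencies of the rows that QC should retain, so the pipeline can be scored
against it; in noiseless mode the pipeline recovers truth exactly.

``simulate_genotypes`` is a brute-force check of the Hardy-Weinberg
formulas: individuals draw two haplotypes (one for males on chrX), each
haplotype carries each variant independently with its allele frequency, and
disease status counts haplotypes carrying at least one variant — compound
heterozygotes are trans by construction, matching the model behind
CrF = 2c(1-c) and HomF = c**2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_ANCESTRIES,
    DISEASE_GROUPS,
    GeneAnnotation,
    InheritanceMode,
    Tier,
    TierSet,
    VariantRecord,
)
from .curation import filter_variants_qc
from .aggregate import compute_gene_burden

__all__ = [
    "DEFAULT_WORLD_POPULATION",
    "default_population_config",
    "SyntheticSpec",
    "generate_gene_set",
    "generate_variant_table",
    "GenotypeSimulation",
    "simulate_genotypes",
    "RecoveryReport",
    "recovery_experiment",
]

_SF_GROUPS = ("cardiovascular", "cancer", "inborn errors of metabolism", "miscellaneous")

#: Rounded world population sizes (persons) per genetic-ancestry group;
#: the sum (~7.47 billion) serves as the reference population for
#: converting prevalences to absolute counts.
DEFAULT_WORLD_POPULATION: dict[str, int] = {
    "afr": 1_400_000_000,
    "amr_iam": 640_000_000,
    "asj": 10_000_000,
    "eas": 1_890_000_000,
    "fin": 5_500_000,
    "mid": 500_000_000,
    "nfe": 940_000_000,
    "sas": 2_000_000_000,
    "tur": 85_000_000,
}


def default_population_config(spec: "SyntheticSpec") -> "PopulationConfig":
    """Population config matching a synthetic spec's ancestries."""
    from .core import PopulationConfig

    world = {
        anc: DEFAULT_WORLD_POPULATION.get(anc, 500_000_000) for anc in spec.ancestries
    }
    return PopulationConfig(
        cohort_individuals={anc: spec.cohort_size for anc in spec.ancestries},
        world_population=world,
    )


def _default_inheritance_mix() -> dict[InheritanceMode, float]:
    # proportions follow the curated panel breakdown: AR-heavy, ~6% X-linked
    return {
        InheritanceMode.AR: 0.53,
        InheritanceMode.AD: 0.28,
        InheritanceMode.AD_AR: 0.13,
        InheritanceMode.XLR: 0.045,
        InheritanceMode.XLD: 0.015,
    }


def _default_tier_mix() -> dict[Tier, float]:
    return {
        Tier.P: 0.005,
        Tier.LP: 0.024,
        Tier.VUS_H: 0.018,
        Tier.VUS_M: 0.030,
        Tier.VUS_L: 0.681,
        Tier.LB: 0.236,
        Tier.B: 0.006,
    }


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort; the seed fully determines output."""

    n_genes: int = 50
    inheritance_mix: dict[InheritanceMode, float] = field(
        default_factory=_default_inheritance_mix
    )
    tier_mix: dict[Tier, float] = field(default_factory=_default_tier_mix)
    #: per-variant AF distribution: log-uniform over [af_min, af_max] with a
    #: ``common_fraction`` of outliers uniform up to ``common_af_max``
    af_min: float = 1e-6
    af_max: float = 1e-2
    common_fraction: float = 0.02
    common_af_max: float = 0.3
    ancestries: tuple[str, ...] = DEFAULT_ANCESTRIES
    cohort_size: int = 100_000  # individuals per ancestry
    mean_variants_per_gene: float = 30.0  # Poisson mean; desk-scale default
    #: disease-group multiplicity: P(1 group), P(2 groups), P(>2: uniform 3-9)
    group_multiplicity: tuple[float, float, float] = (0.40, 0.32, 0.28)
    low_coverage_fraction: float = 0.02  # ancestry pairs planted below QC
    nonpass_fraction: float = 0.02
    secondary_fraction: float = 0.05
    noiseless: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        for name, probs in (
            ("inheritance_mix", list(self.inheritance_mix.values())),
            ("tier_mix", list(self.tier_mix.values())),
            ("group_multiplicity", list(self.group_multiplicity)),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must be >=0 and sum to 1")
        if not 0.0 < self.af_min <= self.af_max <= 1.0:
            raise ValueError("require 0 < af_min <= af_max <= 1")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")

    @property
    def an_max_autosomal(self) -> int:
        return 2 * self.cohort_size

    @property
    def an_max_x(self) -> int:
        # 50:50 sex ratio: males contribute one chrX allele, females two
        return self.cohort_size // 2 + 2 * (self.cohort_size - self.cohort_size // 2)


def generate_gene_set(spec: SyntheticSpec) -> list[GeneAnnotation]:
    """Draw a mixed-inheritance disease gene set per the spec proportions."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    modes = list(spec.inheritance_mix)
    mode_p = np.array([spec.inheritance_mix[m] for m in modes])
    mult_p = np.array(spec.group_multiplicity)

    genes: list[GeneAnnotation] = []
    for i in range(spec.n_genes):
        symbol = f"GENE{i + 1:04d}"
        mode = modes[rng.choice(len(modes), p=mode_p)]
        mech = ["LoF", "GoF", "LoF_GoF"][rng.choice(3, p=[0.90, 0.05, 0.05])]
        src_draw = rng.random()
        if src_draw < 0.80:
            sources = frozenset({"PanelApp", "OMIM"})
        elif src_draw < 0.90:
            sources = frozenset({"PanelApp"})
        else:
            sources = frozenset({"OMIM"})
        bucket = rng.choice(3, p=mult_p)
        n_groups = 1 if bucket == 0 else 2 if bucket == 1 else int(rng.integers(3, 10))
        idx = rng.choice(len(DISEASE_GROUPS), size=n_groups, replace=False)
        groups = frozenset(DISEASE_GROUPS[j] for j in idx)
        is_sf = bool(rng.random() < spec.secondary_fraction)
        genes.append(
            GeneAnnotation(
                symbol=symbol,
                inheritance=mode,
                mechanism=mech,
                protein_coding=True,
                sources=sources,
                disease_groups=groups,
                secondary_finding=is_sf,
                sf_phenotype_group=_SF_GROUPS[int(rng.integers(len(_SF_GROUPS)))]
                if is_sf
                else None,
            )
        )
    return genes


def _draw_true_af(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    if rng.random() < spec.common_fraction:
        return float(rng.uniform(0.01, spec.common_af_max))
    log_af = rng.uniform(np.log(spec.af_min), np.log(spec.af_max))
    return float(np.exp(log_af))


def generate_variant_table(
    genes: Sequence[GeneAnnotation], spec: SyntheticSpec
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Generate per-gene variants plus the ground-truth CAF ledger.

    Returns (records, truth) where truth has one row per (gene, ancestry,
    tier_set) with the exact CAF implied by the true allele frequencies of
    the rows QC retains (PASS, adequately covered in that ancestry).  In
    noiseless mode AN = AN_max and AC = round(AF * AN), with truth defined
    on the emitted integers, so the pipeline is an exact identity on truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    bases = ("A", "C", "G", "T")
    tiers = list(spec.tier_mix)
    tier_p = np.array([spec.tier_mix[t] for t in tiers])

    records: list[VariantRecord] = []
    truth_af: dict[tuple[str, str, str], float] = {}  # (gene, anc, tier_set) -> caf
    for ts in TierSet:
        for g in genes:
            for anc in spec.ancestries:
                truth_af[(g.symbol, anc, ts.name)] = 0.0

    pos = 1000
    for g in genes:
        x_linked = g.inheritance in (InheritanceMode.XLR, InheritanceMode.XLD)
        chrom = "X" if x_linked else str(1 + (zlib.crc32(g.symbol.encode()) % 22))
        an_max = spec.an_max_x if x_linked else spec.an_max_autosomal
        n_var = int(rng.poisson(spec.mean_variants_per_gene))
        for _ in range(n_var):
            pos += int(rng.integers(10, 1000))
            ref, alt = bases[int(rng.integers(4))], bases[int(rng.integers(4))]
            if alt == ref:
                alt = bases[(bases.index(ref) + 1) % 4]
            tier = tiers[rng.choice(len(tiers), p=tier_p)]
            is_pass = spec.noiseless or rng.random() >= spec.nonpass_fraction
            base_af = _draw_true_af(rng, spec)
            ac: dict[str, int] = {}
            an: dict[str, int] = {}
            anm: dict[str, int] = {}
            for anc in spec.ancestries:
                # mild ancestry-specific AF jitter around the shared base
                true_af = float(
                    np.clip(base_af * rng.lognormal(0.0, 0.5), 0.0, 0.5)
                )
                low_cov = (not spec.noiseless) and rng.random() < spec.low_coverage_fraction
                if spec.noiseless:
                    an_i = an_max
                elif low_cov:
                    an_i = int(0.4 * an_max)
                else:
                    an_i = int(rng.binomial(an_max, 0.95))
                if spec.noiseless:
                    ac_i = int(round(true_af * an_i))
                    true_af = ac_i / an_i  # rationalize: truth is the emitted AF
                else:
                    ac_i = int(rng.binomial(an_i, true_af))
                ac[anc], an[anc], anm[anc] = ac_i, an_i, an_max
                if is_pass and not low_cov:
                    for ts in TierSet:
                        if tier in ts.members:
                            truth_af[(g.symbol, anc, ts.name)] += true_af
            records.append(
                VariantRecord(
                    variant_id=f"{chrom}:{pos}:{ref}:{alt}",
                    gene=g.symbol,
                    tier=tier,
                    filter_status="PASS" if is_pass else "VQSR_FAIL",
                    ac=ac,
                    an=an,
                    an_max=anm,
                )
            )

    truth = pd.DataFrame(
        [
            {"gene": gene, "ancestry": anc, "tier_set": ts, "true_caf": min(caf, 1.0)}
            for (gene, anc, ts), caf in sorted(truth_af.items())
        ],
        columns=["gene", "ancestry", "tier_set", "true_caf"],
    )
    return records, truth


@dataclass
class GenotypeSimulation:
    """Empirical genotype fractions from the haplotype-level simulator."""

    n_individuals: int
    genotypes: np.ndarray  # per-individual count of haplotypes carrying >=1 variant
    carrier_fraction: float  # exactly one carrier haplotype (diploid sense)
    biallelic_fraction: float  # both haplotypes carry (homozygote or trans comp-het)
    hemizygote_fraction: float  # males with a carrier haplotype (X-linked only)
    affected_xlr_fraction: float
    affected_xld_fraction: float


def simulate_genotypes(
    afs: Sequence[float],
    n_individuals: int,
    ploidy: str = "autosomal",
    sex_ratio: float = 0.5,
    seed: int = 0,
) -> GenotypeSimulation:
    """Draw genotypes for one gene under HWE and independent assortment.

    Each haplotype carries each variant independently with its AF; an
    individual's disease-relevant genotype is the number of its haplotypes
    carrying at least one variant (compound hets are trans).  For
    ploidy="x_linked", a ``sex_ratio`` fraction of individuals are male and
    draw a single haplotype.
    """
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be positive, got {n_individuals}")
    if ploidy not in {"autosomal", "x_linked"}:
        raise ValueError(f"unknown ploidy model {ploidy!r}")
    afs = np.asarray(afs, dtype=float)
    if afs.size and (afs.min() < 0.0 or afs.max() > 1.0):
        raise ValueError("allele frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)

    def hit(n: int) -> np.ndarray:
        carried = np.zeros(n, dtype=bool)
        for af in afs:
            carried |= rng.random(n) < af
        return carried

    if ploidy == "autosomal":
        counts = hit(n_individuals).astype(np.int8) + hit(n_individuals).astype(np.int8)
        n_male = 0
        male_hit = np.zeros(0, dtype=bool)
        female_counts = counts
    else:
        n_male = int(round(n_individuals * sex_ratio))
        male_hit = hit(n_male)
        n_female = n_individuals - n_male
        female_counts = hit(n_female).astype(np.int8) + hit(n_female).astype(np.int8)
        counts = np.concatenate([male_hit.astype(np.int8), female_counts])

    n = n_individuals
    if ploidy == "autosomal":
        carrier = float(np.mean(counts == 1))
        biallelic = float(np.mean(counts == 2))
        hemi = 0.0
        xlr = xld = 0.0
    else:
        carrier = float(np.mean(female_counts == 1) * (n - n_male) / n)
        biallelic = float(np.mean(female_counts == 2) * (n - n_male) / n)
        hemi = float(male_hit.sum() / n)
        xlr = float((male_hit.sum() + (female_counts == 2).sum()) / n)
        xld = float((male_hit.sum() + (female_counts >= 1).sum()) / n)
    return GenotypeSimulation(
        n_individuals=n,
        genotypes=counts,
        carrier_fraction=carrier,
        biallelic_fraction=biallelic,
        hemizygote_fraction=hemi,
        affected_xlr_fraction=xlr,
        affected_xld_fraction=xld,
    )


@dataclass
class RecoveryReport:
    """Pipeline-vs-ground-truth CAF recovery on a synthetic cohort."""

    per_gene: pd.DataFrame  # gene, ancestry, tier_set, true_caf, est_caf, abs_error
    median_abs_error: float
    max_abs_error: float
    fraction_within_tol: float
    tol: float


def recovery_experiment(spec: SyntheticSpec, tol: float = 1e-4) -> RecoveryReport:
    """Run the full pipeline on a synthetic cohort and score CAF recovery.

    Generates genes and variants, applies QC, computes per-gene burdens for
    every tier set and ancestry, and compares estimated CAF against the
    generator's ground truth.
    """
    genes = generate_gene_set(spec)
    variants, truth = generate_variant_table(genes, spec)
    filtered, _ = filter_variants_qc(variants)
    rows: list[dict[str, object]] = []
    for ts in TierSet:
        for anc in spec.ancestries:
            burdens = compute_gene_burden(filtered, genes, ts, anc)
            for b in burdens:
                rows.append(
                    {
                        "gene": b.gene,
                        "ancestry": anc,
                        "tier_set": ts.name,
                        "est_caf": b.caf,
                    }
                )
    est = pd.DataFrame(rows)
    merged = truth.merge(est, on=["gene", "ancestry", "tier_set"], how="left")
    merged["est_caf"] = merged["est_caf"].fillna(0.0)
    merged["abs_error"] = (merged["est_caf"] - merged["true_caf"]).abs()
    return RecoveryReport(
        per_gene=merged,
        median_abs_error=float(merged["abs_error"].median()),
        max_abs_error=float(merged["abs_error"].max()),
        fraction_within_tol=float((merged["abs_error"] < tol).mean()),
        tol=tol,
    )
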