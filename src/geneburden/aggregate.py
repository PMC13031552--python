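"""Per-gene burden assembly and report-level aggregation.

Assembles (gene, ancestry, tier set) burdens from QC-filtered variant
summaries, averages cohorts on the CAF scale, and derives the downstream
reports: cohort concordance, reported-vs-calculated carrier-frequency
regression, disease-group prevalence, top-gene rankings, carrier-screening
candidate sets, the actionable-gene (secondary findings) summary, absolute
population counts, and constraint contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    BurdenReport,
    ConstraintMetrics,
    DISEASE_GROUPS,
    GeneAnnotation,
    GeneBurden,
    PopulationConfig,
    ScreeningResult,
    SecondaryFindingsResult,
    TierSet,
    VariantRecord,
)
from .curation import select_tier_set
from .stats import (
    ReportedPrevalence,
    carrier_frequency,
    cumulative_allele_frequency,
    cumulative_crf,
    cumulative_gp,
    genetic_prevalence,
    noncarrier_likelihood,
    phenotype_entries,
)

__all__ = [
    "compute_gene_burden",
    "average_cohorts",
    "ConcordanceResult",
    "cohort_concordance",
    "RegressionResult",
    "crf_regression",
    "disease_group_burden",
    "rank_top_genes",
    "screening_candidates",
    "secondary_findings_report",
    "scale_to_population",
    "constraint_comparison",
    "report_from_burdens",
    "build_full_report",
    "build_cohort_report",
]

#: Default carrier-screening inclusion rule: CrF strictly above 1 in 200.
SCREENING_THRESHOLD = 1.0 / 200.0


def compute_gene_burden(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneAnnotation],
    tier_set: TierSet,
    ancestry: str,
) -> list[GeneBurden]:
    """Per-gene CAF/CrF/GP in one ancestry for one tier set.

    ``variants`` should already be QC-filtered and tier-selected; tier
    selection is re-applied defensively (idempotent).  Genes with no passing
    variant in the ancestry get CAF = CrF = GP = 0.  Variants pointing at
    genes outside the gene set are skipped with a warning.
    """
    by_symbol = {g.symbol: g for g in genes}
    afs_by_gene: dict[str, list[float]] = {g.symbol: [] for g in genes}
    n_by_gene: dict[str, int] = {g.symbol: 0 for g in genes}
    for v in variants:
        if v.tier not in tier_set:
            continue
        if v.gene not in by_symbol:
            warnings.warn(
                f"variant {v.variant_id} references gene {v.gene!r} outside the "
                "gene set; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        an = v.an.get(ancestry)
        if an is None or an == 0:
            continue
        afs_by_gene[v.gene].append(v.ac[ancestry] / an)
        n_by_gene[v.gene] += 1

    out: list[GeneBurden] = []
    for g in sorted(genes, key=lambda g: g.symbol):
        caf = cumulative_allele_frequency(afs_by_gene[g.symbol])
        out.append(
            GeneBurden(
                gene=g.symbol,
                ancestry=ancestry,
                tier_set=tier_set,
                caf=caf,
                crf=carrier_frequency(caf),
                gp=genetic_prevalence(caf, g.inheritance),
                n_variants=n_by_gene[g.symbol],
            )
        )
    return out


def average_cohorts(
    burden_a: Sequence[GeneBurden],
    burden_b: Sequence[GeneBurden],
    shared_ancestries: Sequence[str],
    genes: Sequence[GeneAnnotation],
) -> tuple[list[GeneBurden], list[str]]:
    """Average two cohorts' CAF estimates within each shared ancestry.

    CAF_avg = (CAF_a + CAF_b) / 2; CrF and GP are recomputed from the
    averaged CAF, never averaged themselves.  A gene observed in only one
    cohort is averaged against CAF = 0 and logged.  Burdens for unshared
    ancestries pass through unchanged.
    """
    mode = {g.symbol: g.inheritance for g in genes}
    shared = set(shared_ancestries)

    def index(burdens: Sequence[GeneBurden]) -> dict[tuple[str, str, TierSet], GeneBurden]:
        return {(b.gene, b.ancestry, b.tier_set): b for b in burdens}

    ia, ib = index(burden_a), index(burden_b)
    for anc in shared:
        if not any(b.ancestry == anc for b in burden_a):
            raise ValueError(f"shared ancestry {anc!r} missing from cohort A")
        if not any(b.ancestry == anc for b in burden_b):
            raise ValueError(f"shared ancestry {anc!r} missing from cohort B")

    log: list[str] = []
    out: list[GeneBurden] = []
    for key in sorted(set(ia) | set(ib), key=lambda k: (k[2].name, k[1], k[0])):
        gene, anc, tier_set = key
        a, b = ia.get(key), ib.get(key)
        if anc not in shared:
            out.append(a if a is not None else b)
            continue
        caf_a = a.caf if a is not None else 0.0
        caf_b = b.caf if b is not None else 0.0
        if a is None or b is None:
            which = "A" if a is None else "B"
            log.append(f"{gene}/{anc}/{tier_set.name}: absent from cohort {which}, CAF=0 imputed")
        caf = (caf_a + caf_b) / 2.0
        if gene not in mode:
            raise ValueError(f"gene {gene!r} not in gene set; cannot recompute GP")
        out.append(
            GeneBurden(
                gene=gene,
                ancestry=anc,
                tier_set=tier_set,
                caf=caf,
                crf=carrier_frequency(caf),
                gp=genetic_prevalence(caf, mode[gene]),
                n_variants=max(a.n_variants if a else 0, b.n_variants if b else 0),
            )
        )
    return out, log


@dataclass
class ConcordanceResult:
    """Per-ancestry Pearson r of per-gene CAF between two cohorts."""

    per_ancestry: dict[str, float | None]
    mean: float | None


def cohort_concordance(
    burden_a: Sequence[GeneBurden],
    burden_b: Sequence[GeneBurden],
    tier_set: TierSet,
    method: str = "pearson",
) -> ConcordanceResult:
    """Correlate per-gene CAF between cohorts within each shared ancestry.

    Only genes with nonzero CAF in both cohorts enter; an ancestry with
    fewer than 3 such genes, or a zero-variance vector, reports None.
    The mean is unweighted across the defined ancestries.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown method {method!r}")
    ia = {(b.gene, b.ancestry): b.caf for b in burden_a if b.tier_set is tier_set}
    ib = {(b.gene, b.ancestry): b.caf for b in burden_b if b.tier_set is tier_set}
    ancestries = sorted(
        {anc for _, anc in ia} & {anc for _, anc in ib}
    )
    per: dict[str, float | None] = {}
    for anc in ancestries:
        genes = sorted(
            {g for g, a in ia if a == anc} & {g for g, a in ib if a == anc}
        )
        xs = np.array([ia[(g, anc)] for g in genes])
        ys = np.array([ib[(g, anc)] for g in genes])
        mask = (xs > 0) & (ys > 0)
        xs, ys = xs[mask], ys[mask]
        if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            per[anc] = None
            continue
        if method == "spearman":
            per[anc] = float(sps.spearmanr(xs, ys).statistic)
        else:
            per[anc] = float(np.corrcoef(xs, ys)[0, 1])
    defined = [r for r in per.values() if r is not None]
    return ConcordanceResult(per_ancestry=per, mean=float(np.mean(defined)) if defined else None)


@dataclass
class RegressionResult:
    """Log-log OLS of calculated CrF on reported CrF."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float


def crf_regression(
    reported: Sequence[ReportedPrevalence], calculated: Mapping[str, float]
) -> RegressionResult:
    """Regress log(calculated CrF) on log(reported rCrF) over matched genes.

    Pairs require both values strictly positive (log-transform); fewer than
    3 pairs is an error.  R is the correlation of the log values; p is the
    two-sided test on the slope.
    """
    xs, ys = [], []
    for rec in reported:
        crf = calculated.get(rec.gene)
        if crf is None or crf <= 0.0 or rec.rcrf <= 0.0:
            continue
        xs.append(np.log(rec.rcrf))
        ys.append(np.log(crf))
    if len(xs) < 3:
        raise ValueError(f"need at least 3 matched pairs, got {len(xs)}")
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=len(xs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def disease_group_burden(
    burdens: Sequence[GeneBurden],
    genes: Sequence[GeneAnnotation],
    tier_set: TierSet,
) -> pd.DataFrame:
    """Cumulative GP per ICD-10 disease group and ancestry.

    Each member gene contributes one GP term per inheritance phenotype entry
    (an AD/AR gene adds its dominant and recessive terms); a multi-group
    gene contributes fully to every group it belongs to, so group totals are
    non-mutually exclusive.  Rows with ancestry="mean" carry the unweighted
    cross-ancestry mean.  Returns columns [group, ancestry, GP].
    """
    by_symbol = {g.symbol: g for g in genes}
    caf: dict[tuple[str, str], float] = {}
    ancestries: list[str] = []
    for b in burdens:
        if b.tier_set is not tier_set:
            continue
        caf[(b.gene, b.ancestry)] = b.caf
        if b.ancestry not in ancestries:
            ancestries.append(b.ancestry)
    ancestries.sort()

    rows: list[dict[str, object]] = []
    for group in DISEASE_GROUPS:
        members = [g for g in genes if group in g.disease_groups]
        if not members:
            warnings.warn(f"disease group {group!r} has no member genes", RuntimeWarning,
                          stacklevel=2)
        per_anc: list[float] = []
        for anc in ancestries:
            total = cumulative_gp(
                {g.symbol: caf.get((g.symbol, anc), 0.0) for g in members},
                {g.symbol: g.inheritance for g in members},
            )
            per_anc.append(total)
            rows.append({"group": group, "ancestry": anc, "GP": total})
        rows.append(
            {
                "group": group,
                "ancestry": "mean",
                "GP": float(np.mean(per_anc)) if per_anc else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["group", "ancestry", "GP"])


def rank_top_genes(
    burdens: Sequence[GeneBurden], metric: str = "CrF", n: int = 30
) -> pd.DataFrame:
    """Top-n genes per ancestry by CrF or GP, ties broken alphabetically."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if metric not in {"CrF", "GP"}:
        raise ValueError(f"unknown metric {metric!r} (use 'CrF' or 'GP')")
    key = (lambda b: b.crf) if metric == "CrF" else (lambda b: b.gp)
    rows: list[dict[str, object]] = []
    ancestries = sorted({b.ancestry for b in burdens})
    for anc in ancestries:
        ranked = sorted(
            (b for b in burdens if b.ancestry == anc),
            key=lambda b: (-key(b), b.gene),
        )[:n]
        for rank, b in enumerate(ranked, start=1):
            rows.append(
                {"ancestry": anc, "rank": rank, "gene": b.gene, metric: key(b)}
            )
    return pd.DataFrame(rows, columns=["ancestry", "rank", "gene", metric])


def screening_candidates(
    burdens: Sequence[GeneBurden], threshold: float = SCREENING_THRESHOLD
) -> ScreeningResult:
    """Carrier-screening candidates: CrF strictly above the threshold.

    A gene at exactly the threshold does not qualify.  Returns per-ancestry
    sets plus their union and intersection.
    """
    per: dict[str, set[str]] = {}
    for b in burdens:
        per.setdefault(b.ancestry, set())
        if b.crf > threshold:
            per[b.ancestry].add(b.gene)
    sets = list(per.values())
    union = set().union(*sets) if sets else set()
    intersection = set.intersection(*sets) if sets else set()
    return ScreeningResult(
        threshold=threshold, per_ancestry=per, union=union, intersection=intersection
    )


def _sf_result_from_burdens(
    burdens_by_anc: Mapping[str, Sequence[GeneBurden]],
    sf_genes: Sequence[GeneAnnotation],
    tier_set: TierSet,
) -> SecondaryFindingsResult:
    """Assemble the secondary-findings tables from per-ancestry SF burdens."""
    mode = {g.symbol: g.inheritance for g in sf_genes}
    sf_groups = sorted({g.sf_phenotype_group for g in sf_genes if g.sf_phenotype_group})
    per_gene_rows: list[dict[str, object]] = []
    cum_rows: list[dict[str, object]] = []
    group_rows: list[dict[str, object]] = []
    for anc, burdens in burdens_by_anc.items():
        for b in burdens:
            per_gene_rows.append(
                {
                    "gene": b.gene,
                    "ancestry": anc,
                    "tier_set": tier_set.label,
                    "n_variants": b.n_variants,
                    "CAF": b.caf,
                    "CrF": b.crf,
                    "GP": b.gp,
                }
            )
        cum_rows.append(
            {
                "ancestry": anc,
                "tier_set": tier_set.label,
                "cumulative_crf": cumulative_crf(burdens),
                "cumulative_gp": cumulative_gp({b.gene: b.caf for b in burdens}, mode),
            }
        )
        for grp in sf_groups:
            member_syms = {g.symbol for g in sf_genes if g.sf_phenotype_group == grp}
            caf = {b.gene: b.caf for b in burdens if b.gene in member_syms}
            group_rows.append(
                {
                    "sf_phenotype_group": grp,
                    "ancestry": anc,
                    "GP": cumulative_gp(caf, mode),
                }
            )
    return SecondaryFindingsResult(
        per_gene=pd.DataFrame(
            per_gene_rows,
            columns=["gene", "ancestry", "tier_set", "n_variants", "CAF", "CrF", "GP"],
        ),
        cumulative=pd.DataFrame(
            cum_rows, columns=["ancestry", "tier_set", "cumulative_crf", "cumulative_gp"]
        ),
        phenotype_groups=pd.DataFrame(
            group_rows, columns=["sf_phenotype_group", "ancestry", "GP"]
        ),
    )


def secondary_findings_report(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneAnnotation],
    tier_set: TierSet,
    ancestries: Sequence[str],
) -> SecondaryFindingsResult:
    """Burden over the actionable (secondary-finding) gene subset.

    Genes with a restricted variant list are recomputed from those variants
    only (e.g. HFE limited to C282Y); a restriction naming a variant id not
    present in the table is an error.  Reports per-gene burdens, cumulative
    CrF (each gene once) and cumulative GP (one term per inheritance
    phenotype entry) per ancestry, and totals per secondary-findings
    phenotype group.
    """
    sf_genes = sorted(
        (g for g in genes if g.secondary_finding), key=lambda g: g.symbol
    )
    all_ids = {v.variant_id for v in variants}
    for g in sf_genes:
        for vid in g.restricted_variant_ids or ():
            if vid not in all_ids:
                raise ValueError(
                    f"{g.symbol}: restricted variant id {vid!r} not in variant table"
                )
    selected = select_tier_set(variants, tier_set, sf_genes, apply_restrictions=True)
    burdens_by_anc = {
        anc: compute_gene_burden(selected, sf_genes, tier_set, anc) for anc in ancestries
    }
    return _sf_result_from_burdens(burdens_by_anc, sf_genes, tier_set)


def scale_to_population(
    prevalence: float | Mapping[str, float],
    config: PopulationConfig,
    ancestry: str | None = None,
) -> float:
    """Convert prevalence(s) to an absolute affected-individual count.

    Ancestry scope: a scalar prevalence times that ancestry's world
    population.  Global scope (``ancestry=None``): a per-ancestry prevalence
    mapping, scaled as the sum of per-ancestry counts — never a mean
    prevalence times the total population.
    """
    if ancestry is not None:
        if ancestry not in config.world_population:
            raise ValueError(f"unknown ancestry {ancestry!r}")
        if not isinstance(prevalence, (int, float)):
            raise TypeError("ancestry scope takes a scalar prevalence")
        if not 0.0 <= prevalence <= 1.0:
            raise ValueError(f"prevalence {prevalence} outside [0,1]")
        return prevalence * config.world_population[ancestry]
    if not isinstance(prevalence, Mapping):
        raise TypeError("global scope takes a per-ancestry prevalence mapping")
    total = 0.0
    for anc, p in prevalence.items():
        total += scale_to_population(p, config, ancestry=anc)
    return total


@dataclass
class ConstraintContrast:
    """Single- vs multi-disease-group contrast of gene constraint."""

    flags: pd.DataFrame
    n_single: int
    n_multi: int
    loeuf_median_single: float
    loeuf_median_multi: float
    direction: str  # "multi_more_constrained" / "single_more_constrained" / "none"
    p_value: float
    constrained_fraction_single: float
    constrained_fraction_multi: float


def constraint_comparison(
    metrics: Sequence[ConstraintMetrics], genes: Sequence[GeneAnnotation]
) -> ConstraintContrast:
    """Flag constrained genes and contrast single- vs multi-group genes.

    Thresholds: LOEUF < 0.6, missense Z > 3.09, synonymous Z > 3.71 (strict).
    The LOEUF distributions of single- and multi-group genes are compared
    with a two-sided Mann-Whitney rank-sum test; lower LOEUF means more
    constrained.
    """
    by_symbol = {g.symbol: g for g in genes}
    rows = []
    for m in metrics:
        g = by_symbol.get(m.gene)
        if g is None:
            continue
        rows.append(
            {
                "gene": m.gene,
                "pLI": m.pli,
                "LOEUF": m.loeuf,
                "mis_z": m.mis_z,
                "syn_z": m.syn_z,
                "loeuf_constrained": m.loeuf_constrained,
                "mis_constrained": m.mis_constrained,
                "syn_constrained": m.syn_constrained,
                "n_groups": len(g.disease_groups),
                "multi_group": len(g.disease_groups) > 1,
            }
        )
    if not rows:
        raise ValueError("no overlap between constraint metrics and gene set")
    flags = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)

    single = flags.loc[~flags["multi_group"], "LOEUF"].to_numpy()
    multi = flags.loc[flags["multi_group"], "LOEUF"].to_numpy()
    if len(single) == 0 or len(multi) == 0:
        p = float("nan")
        direction = "none"
    else:
        p = float(sps.mannwhitneyu(single, multi, alternative="two-sided").pvalue)
        med_s, med_m = float(np.median(single)), float(np.median(multi))
        if med_m < med_s:
            direction = "multi_more_constrained"
        elif med_s < med_m:
            direction = "single_more_constrained"
        else:
            direction = "none"

    def frac(mask: pd.Series) -> float:
        sub = flags.loc[mask]
        if len(sub) == 0:
            return float("nan")
        return float(
            (sub["loeuf_constrained"] | sub["mis_constrained"] | sub["syn_constrained"]).mean()
        )

    return ConstraintContrast(
        flags=flags,
        n_single=int((~flags["multi_group"]).sum()),
        n_multi=int(flags["multi_group"].sum()),
        loeuf_median_single=float(np.median(single)) if len(single) else float("nan"),
        loeuf_median_multi=float(np.median(multi)) if len(multi) else float("nan"),
        direction=direction,
        p_value=p,
        constrained_fraction_single=frac(~flags["multi_group"]),
        constrained_fraction_multi=frac(flags["multi_group"]),
    )


def report_from_burdens(
    burdens_by_ts: Mapping[TierSet, Sequence[GeneBurden]],
    genes: Sequence[GeneAnnotation],
    config: PopulationConfig,
    secondary: SecondaryFindingsResult,
    screening_tier_set: TierSet = TierSet.PLP,
    screening_threshold: float = SCREENING_THRESHOLD,
    top_n: int = 30,
) -> BurdenReport:
    """Derive every report section from precomputed per-gene burdens."""
    ancestries = list(config.ancestries)
    mode = {g.symbol: g.inheritance for g in genes}

    gene_rows: list[dict[str, object]] = []
    cum_rows: list[dict[str, object]] = []
    group_frames: list[pd.DataFrame] = []
    for ts, all_burdens in burdens_by_ts.items():
        per_anc_crf: list[float] = []
        per_anc_gp: list[float] = []
        per_anc_ncl: list[float] = []
        for anc in ancestries:
            burdens = [b for b in all_burdens if b.ancestry == anc]
            for b in burdens:
                gene_rows.append(
                    {
                        "tier_set": ts.label,
                        "gene": b.gene,
                        "ancestry": anc,
                        "n_variants": b.n_variants,
                        "CAF": b.caf,
                        "CrF": b.crf,
                        "GP": b.gp,
                    }
                )
            c_crf = cumulative_crf(burdens)
            c_gp = cumulative_gp({b.gene: b.caf for b in burdens}, mode)
            ncl = noncarrier_likelihood([b.crf for b in burdens])
            per_anc_crf.append(c_crf)
            per_anc_gp.append(c_gp)
            per_anc_ncl.append(ncl)
            cum_rows.append(
                {
                    "tier_set": ts.label,
                    "ancestry": anc,
                    "cumulative_crf": c_crf,
                    "cumulative_gp": c_gp,
                    "noncarrier_likelihood": ncl,
                }
            )
        cum_rows.append(
            {
                "tier_set": ts.label,
                "ancestry": "mean",
                "cumulative_crf": float(np.mean(per_anc_crf)),
                "cumulative_gp": float(np.mean(per_anc_gp)),
                "noncarrier_likelihood": float(np.mean(per_anc_ncl)),
            }
        )
        gdf = disease_group_burden(all_burdens, genes, ts)
        gdf.insert(0, "tier_set", ts.label)
        group_frames.append(gdf)

    if screening_tier_set not in burdens_by_ts:
        raise ValueError(
            f"screening tier set {screening_tier_set.label} not among computed burdens"
        )
    scr_burdens = list(burdens_by_ts[screening_tier_set])
    screening = screening_candidates(scr_burdens, threshold=screening_threshold)

    group_gp = pd.concat(group_frames, ignore_index=True)

    # absolute counts: disease-group GP and actionable-genotype GP per
    # ancestry, plus the weighted global sum (never mean x total population)
    scaled_rows: list[dict[str, object]] = []
    scr_label = screening_tier_set.label
    grp = group_gp[(group_gp["tier_set"] == scr_label) & (group_gp["ancestry"] != "mean")]
    for group in DISEASE_GROUPS:
        sub = grp[grp["group"] == group]
        per_anc = dict(zip(sub["ancestry"], sub["GP"]))
        for anc in ancestries:
            p = min(per_anc.get(anc, 0.0), 1.0)
            scaled_rows.append(
                {
                    "metric": f"group:{group}",
                    "ancestry": anc,
                    "prevalence": p,
                    "affected": scale_to_population(p, config, ancestry=anc),
                }
            )
        capped = {a: min(per_anc.get(a, 0.0), 1.0) for a in ancestries}
        scaled_rows.append(
            {
                "metric": f"group:{group}",
                "ancestry": "global",
                "prevalence": float(np.mean(list(capped.values()))),
                "affected": scale_to_population(capped, config),
            }
        )
    sf_gp = dict(
        zip(secondary.cumulative["ancestry"], secondary.cumulative["cumulative_gp"])
    )
    for anc in ancestries:
        p = min(sf_gp.get(anc, 0.0), 1.0)
        scaled_rows.append(
            {
                "metric": "secondary_findings_gp",
                "ancestry": anc,
                "prevalence": p,
                "affected": scale_to_population(p, config, ancestry=anc),
            }
        )
    capped_sf = {a: min(sf_gp.get(a, 0.0), 1.0) for a in ancestries}
    scaled_rows.append(
        {
            "metric": "secondary_findings_gp",
            "ancestry": "global",
            "prevalence": float(np.mean(list(capped_sf.values()))),
            "affected": scale_to_population(capped_sf, config),
        }
    )

    return BurdenReport(
        gene_burden=pd.DataFrame(
            gene_rows,
            columns=["tier_set", "gene", "ancestry", "n_variants", "CAF", "CrF", "GP"],
        ),
        cumulative=pd.DataFrame(
            cum_rows,
            columns=[
                "tier_set",
                "ancestry",
                "cumulative_crf",
                "cumulative_gp",
                "noncarrier_likelihood",
            ],
        ),
        group_gp=group_gp,
        top_crf=rank_top_genes(scr_burdens, metric="CrF", n=top_n),
        top_gp=rank_top_genes(scr_burdens, metric="GP", n=top_n),
        screening=screening,
        secondary=secondary,
        scaled_counts=pd.DataFrame(
            scaled_rows, columns=["metric", "ancestry", "prevalence", "affected"]
        ),
    )


def build_full_report(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneAnnotation],
    config: PopulationConfig,
    tier_sets: Sequence[TierSet] = (TierSet.P, TierSet.PLP, TierSet.PLPVH),
    screening_tier_set: TierSet = TierSet.PLP,
    screening_threshold: float = SCREENING_THRESHOLD,
    top_n: int = 30,
) -> BurdenReport:
    """Assemble the full burden report for one cohort; a pure function.

    ``variants`` must already be QC-filtered.  The report covers every tier
    set for the per-gene, cumulative and disease-group tables; screening,
    ranking and secondary-findings sections use ``screening_tier_set``
    (P+LP by default, the reporting standard for both).
    """
    ancestries = list(config.ancestries)
    burdens_by_ts: dict[TierSet, list[GeneBurden]] = {}
    for ts in tier_sets:
        selected = select_tier_set(variants, ts, genes)
        burdens_by_ts[ts] = [
            b for anc in ancestries for b in compute_gene_burden(selected, genes, ts, anc)
        ]
    secondary = secondary_findings_report(variants, genes, screening_tier_set, ancestries)
    return report_from_burdens(
        burdens_by_ts,
        genes,
        config,
        secondary,
        screening_tier_set=screening_tier_set,
        screening_threshold=screening_threshold,
        top_n=top_n,
    )


def _average_sf(
    a: SecondaryFindingsResult,
    b: SecondaryFindingsResult,
    genes: Sequence[GeneAnnotation],
    tier_set: TierSet,
    shared_ancestries: Sequence[str],
) -> SecondaryFindingsResult:
    """Average two cohorts' secondary-findings CAFs and rebuild the tables."""
    sf_genes = sorted((g for g in genes if g.secondary_finding), key=lambda g: g.symbol)
    mode = {g.symbol: g.inheritance for g in sf_genes}
    shared = set(shared_ancestries)

    def caf_map(res: SecondaryFindingsResult) -> dict[tuple[str, str], tuple[float, int]]:
        return {
            (r["gene"], r["ancestry"]): (float(r["CAF"]), int(r["n_variants"]))
            for r in res.per_gene.to_dict("records")
        }

    ca, cb = caf_map(a), caf_map(b)
    ancestries = sorted({anc for _, anc in ca} | {anc for _, anc in cb})
    burdens_by_anc: dict[str, list[GeneBurden]] = {}
    for anc in ancestries:
        burdens: list[GeneBurden] = []
        for g in sf_genes:
            va, na = ca.get((g.symbol, anc), (0.0, 0))
            vb, nb = cb.get((g.symbol, anc), (0.0, 0))
            caf = (va + vb) / 2.0 if anc in shared else (va or vb)
            burdens.append(
                GeneBurden(
                    gene=g.symbol,
                    ancestry=anc,
                    tier_set=tier_set,
                    caf=caf,
                    crf=carrier_frequency(caf),
                    gp=genetic_prevalence(caf, mode[g.symbol]),
                    n_variants=max(na, nb),
                )
            )
        burdens_by_anc[anc] = burdens
    return _sf_result_from_burdens(burdens_by_anc, sf_genes, tier_set)


def build_cohort_report(
    cohorts: Sequence[Sequence[VariantRecord]],
    genes: Sequence[GeneAnnotation],
    config: PopulationConfig,
    tier_sets: Sequence[TierSet] = (TierSet.P, TierSet.PLP, TierSet.PLPVH),
    screening_tier_set: TierSet = TierSet.PLP,
    screening_threshold: float = SCREENING_THRESHOLD,
    top_n: int = 30,
) -> BurdenReport:
    """Full report for one cohort, or two cohorts averaged on the CAF scale.

    With two cohorts, per-gene CAF estimates are averaged within every
    ancestry of ``config`` (CrF/GP recomputed from the averaged CAF) before
    report derivation — the estimator used when two summary releases cover
    the same ancestries.
    """
    if len(cohorts) == 1:
        return build_full_report(
            cohorts[0],
            genes,
            config,
            tier_sets=tier_sets,
            screening_tier_set=screening_tier_set,
            screening_threshold=screening_threshold,
            top_n=top_n,
        )
    if len(cohorts) != 2:
        raise ValueError("build_cohort_report supports one or two cohorts")
    ancestries = list(config.ancestries)
    burdens_by_ts: dict[TierSet, list[GeneBurden]] = {}
    for ts in tier_sets:
        per_cohort: list[list[GeneBurden]] = []
        for variants in cohorts:
            selected = select_tier_set(variants, ts, genes)
            per_cohort.append(
                [
                    b
                    for anc in ancestries
                    for b in compute_gene_burden(selected, genes, ts, anc)
                ]
            )
        averaged, _ = average_cohorts(per_cohort[0], per_cohort[1], ancestries, genes)
        burdens_by_ts[ts] = averaged
    sf_a = secondary_findings_report(cohorts[0], genes, screening_tier_set, ancestries)
    sf_b = secondary_findings_report(cohorts[1], genes, screening_tier_set, ancestries)
    secondary = _average_sf(sf_a, sf_b, genes, screening_tier_set, ancestries)
    return report_from_burdens(
        burdens_by_ts,
        genes,
        config,
        secondary,
        screening_tier_set=screening_tier_set,
        screening_threshold=screening_threshold,
        top_n=top_n,
    )
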