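"""Gene-set curation and variant QC.

Curation mirrors how diagnostic gene panels are assembled: non-protein-coding
genes are dropped (poorly covered by exome capture), genes with undefined or
mitochondrial inheritance are dropped, and OMIM-derived genes additionally
require an established disease mechanism and must not act through repeat
expansion alone (invisible to short-read exome summary statistics).  Every
exclusion lands in a ledger — retained + excluded always equals the input.

Variant QC keeps PASS variants and, per ancestry, only (AC, AN) pairs where
the called-allele fraction AN/AN_max exceeds ``min_call_fraction`` (default
0.5, strict).  A variant failing coverage in one ancestry still contributes
to the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneAnnotation, InheritanceMode, TierSet, VariantRecord

__all__ = [
    "ExclusionLedger",
    "MergeResult",
    "QCStats",
    "curate_genes",
    "merge_gene_sources",
    "filter_variants_qc",
    "select_tier_set",
]


@dataclass
class ExclusionLedger:
    """Gene -> reason log for curation exclusions; serializable as TSV."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene: str, reason: str) -> None:
        self.entries.append((gene, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "reason"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def curate_genes(
    raw: Sequence[GeneAnnotation], source: str
) -> tuple[list[GeneAnnotation], ExclusionLedger]:
    """Apply the per-source curation rules; nothing is lost silently.

    Common rules: drop non-protein-coding genes and genes whose inheritance
    is undefined/unascertained or mitochondrial.  source="OMIM" additionally
    drops repeat-expansion-only genes and genes without an established
    disease mechanism.
    """
    if source not in {"PanelApp", "OMIM"}:
        raise ValueError(f"unknown source {source!r} (use 'PanelApp' or 'OMIM')")
    retained: list[GeneAnnotation] = []
    ledger = ExclusionLedger()
    for g in raw:
        if not g.protein_coding:
            ledger.add(g.symbol, "non-protein-coding")
            continue
        if g.inheritance is None:
            raw_tok = g.inheritance_raw.strip().upper()
            if raw_tok in {"MT", "MITO", "MITOCHONDRIAL"}:
                ledger.add(g.symbol, "mitochondrial inheritance")
            else:
                ledger.add(g.symbol, "undefined/unascertained inheritance")
            continue
        if source == "OMIM":
            if g.repeat_expansion_only:
                ledger.add(g.symbol, "repeat-expansion-only")
                continue
            if not g.mechanism_established:
                ledger.add(g.symbol, "no established disease mechanism")
                continue
        retained.append(g)
    assert len(retained) + len(ledger) == len(raw)
    return retained, ledger


@dataclass
class MergeResult:
    """Union of two curated gene sources with provenance bookkeeping."""

    genes: list[GeneAnnotation]
    n_overlap: int
    n_unique_a: int
    n_unique_b: int
    conflicts: list[tuple[str, str]] = field(default_factory=list)  # gene, note


def _resolve_inheritance(
    a: InheritanceMode, b: InheritanceMode
) -> tuple[InheritanceMode, bool]:
    """More-inclusive-mode rule: AD/AR beats AD or AR.  Returns (mode, conflicted)."""
    if a is b:
        return a, False
    pair = {a, b}
    if pair == {InheritanceMode.AD, InheritanceMode.AR} or InheritanceMode.AD_AR in pair:
        return InheritanceMode.AD_AR, True
    # no inclusion rule (e.g. XLR vs XLD, autosomal vs X): keep the first
    # source's mode and flag for review
    return a, True


def merge_gene_sources(
    panelapp: Sequence[GeneAnnotation], omim: Sequence[GeneAnnotation]
) -> MergeResult:
    """Union two curated gene sets by symbol, merging provenance.

    Inheritance conflicts resolve to the more inclusive mode (AD/AR beats AD
    or AR) and are logged; mechanism conflicts keep the OMIM mechanism and
    are flagged for manual review.  Disease groups and flags are unioned.
    """
    by_symbol: dict[str, GeneAnnotation] = {}
    conflicts: list[tuple[str, str]] = []
    a_symbols = {g.symbol for g in panelapp}
    b_symbols = {g.symbol for g in omim}

    for g in panelapp:
        by_symbol[g.symbol] = g
    for g in omim:
        if g.symbol not in by_symbol:
            by_symbol[g.symbol] = g
            continue
        pa = by_symbol[g.symbol]
        inheritance, conflicted = _resolve_inheritance(pa.inheritance, g.inheritance)
        if conflicted:
            conflicts.append(
                (
                    g.symbol,
                    f"inheritance conflict: PanelApp={pa.inheritance.token} "
                    f"OMIM={g.inheritance.token} -> {inheritance.token}",
                )
            )
        mechanism = pa.mechanism
        if pa.mechanism != g.mechanism:
            mechanism = g.mechanism  # OMIM mechanism wins; flag for review
            conflicts.append(
                (
                    g.symbol,
                    f"mechanism conflict: PanelApp={pa.mechanism} OMIM={g.mechanism} "
                    f"-> {mechanism} (manual review)",
                )
            )
        by_symbol[g.symbol] = GeneAnnotation(
            symbol=g.symbol,
            inheritance=inheritance,
            mechanism=mechanism,
            protein_coding=pa.protein_coding and g.protein_coding,
            sources=pa.sources | g.sources,
            disease_groups=pa.disease_groups | g.disease_groups,
            repeat_expansion_only=pa.repeat_expansion_only or g.repeat_expansion_only,
            mechanism_established=pa.mechanism_established and g.mechanism_established,
            secondary_finding=pa.secondary_finding or g.secondary_finding,
            sf_phenotype_group=pa.sf_phenotype_group or g.sf_phenotype_group,
            restricted_variant_ids=pa.restricted_variant_ids or g.restricted_variant_ids,
        )

    genes = [by_symbol[s] for s in sorted(by_symbol)]
    return MergeResult(
        genes=genes,
        n_overlap=len(a_symbols & b_symbols),
        n_unique_a=len(a_symbols - b_symbols),
        n_unique_b=len(b_symbols - a_symbols),
        conflicts=conflicts,
    )


@dataclass
class QCStats:
    """Per-rule drop counts from variant QC."""

    n_input: int = 0
    n_non_pass: int = 0
    n_ancestry_pairs_dropped: int = 0
    n_fully_dropped_coverage: int = 0
    n_retained: int = 0


def filter_variants_qc(
    variants: Sequence[VariantRecord], min_call_fraction: float = 0.5
) -> tuple[list[VariantRecord], QCStats]:
    """Keep PASS variants with adequate per-ancestry call fraction.

    An (AC, AN) pair is usable in an ancestry only when AN / AN_max strictly
    exceeds ``min_call_fraction``; unusable pairs are removed from the record
    (the variant is treated as absent in that ancestry).  A variant with no
    usable ancestry left is dropped.  Idempotent.
    """
    stats = QCStats(n_input=len(variants))
    out: list[VariantRecord] = []
    for v in variants:
        if not v.is_pass():
            stats.n_non_pass += 1
            continue
        keep_anc: list[str] = []
        for anc in v.ancestries:
            an_max = v.an_max[anc]
            if an_max == 0:
                raise ValueError(
                    f"{v.variant_id}: AN_max=0 for declared ancestry {anc!r}"
                )
            if v.an[anc] / an_max > min_call_fraction:
                keep_anc.append(anc)
            else:
                stats.n_ancestry_pairs_dropped += 1
        if not keep_anc:
            stats.n_fully_dropped_coverage += 1
            continue
        if len(keep_anc) == len(v.ancestries):
            out.append(v)
        else:
            out.append(
                VariantRecord(
                    variant_id=v.variant_id,
                    gene=v.gene,
                    tier=v.tier,
                    filter_status=v.filter_status,
                    ac={a: v.ac[a] for a in keep_anc},
                    an={a: v.an[a] for a in keep_anc},
                    an_max={a: v.an_max[a] for a in keep_anc},
                )
            )
    stats.n_retained = len(out)
    return out, stats


def select_tier_set(
    variants: Iterable[VariantRecord],
    tier_set: TierSet,
    genes: Sequence[GeneAnnotation],
    apply_restrictions: bool = False,
) -> list[VariantRecord]:
    """Restrict to variants in ``tier_set`` whose gene is in the retained set.

    With ``apply_restrictions=True``, genes carrying a restricted variant
    list (the HFE C282Y-only secondary-findings rule) keep only the listed
    variant ids.
    """
    by_symbol = {g.symbol: g for g in genes}
    out: list[VariantRecord] = []
    for v in variants:
        if v.tier not in tier_set:
            continue
        ann = by_symbol.get(v.gene)
        if ann is None:
            continue
        if (
            apply_restrictions
            and ann.restricted_variant_ids is not None
            and v.variant_id not in ann.restricted_variant_ids
        ):
            continue
        out.append(v)
    return out
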