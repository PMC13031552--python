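"""Domain types, tabular I/O and reciprocal-frequency formatting.

The package works on cohort *summary statistics*: one row per variant with
per-ancestry alternate-allele counts (AC) and called-allele numbers (AN),
plus a gene annotation table carrying inheritance mode, disease mechanism
and disease-group memberships.  Coordinates are GRCh38, 1-based, with
left-normalized, bi-allelic (pre-split) alleles — the gnomAD convention.

The native exchange format is TSV with ancestry-suffixed columns
(``AC_afr``, ``AN_afr``, ``AN_max_afr`` ...); a VCF v4.2 dialect reader
(INFO keys ``AC_<anc>`` / ``AN_<anc>``) is provided for convenience.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_ANCESTRIES",
    "DISEASE_GROUPS",
    "Tier",
    "TierSet",
    "InheritanceMode",
    "VariantRecord",
    "GeneAnnotation",
    "ConstraintMetrics",
    "PopulationConfig",
    "GeneBurden",
    "BurdenReport",
    "format_one_in",
    "parse_one_in",
    "read_variant_table",
    "write_variant_table",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_population_config",
    "read_constraint_metrics",
    "write_burden_tables",
]

# ---------------------------------------------------------------------------
# registries

#: Genetic-ancestry codes used by the cohort summary files.  The registry is
#: extensible: readers accept any ancestry token declared in the header, but
#: these nine are the canonical set (African; Admixed/Indigenous American;
#: Ashkenazi Jewish; East Asian; Finnish; Middle Eastern; non-Finnish
#: European; South Asian; Turkish).
DEFAULT_ANCESTRIES: tuple[str, ...] = (
    "afr",
    "amr_iam",
    "asj",
    "eas",
    "fin",
    "mid",
    "nfe",
    "sas",
    "tur",
)

#: The 13 ICD-10-derived disease groups.  Gene membership is many-to-many,
#: so group-level prevalences are non-mutually exclusive.
DISEASE_GROUPS: tuple[str, ...] = (
    "congenital",
    "musculoskeletal_connective",
    "blood_immune",
    "nervous",
    "skin",
    "endocrine_metabolic",
    "circulatory",
    "eye",
    "ear",
    "genitourinary",
    "neoplasm",
    "digestive",
    "respiratory",
)


class Tier(enum.Enum):
    """Seven-level ACMG-based classification tier.

    Ordered from most to least confident pathogenicity call; the descriptive
    posterior odds bands are P >99%, LP 90%, VUS-H 67.5%, VUS-M 41%,
    VUS-L 14%, LB 10%, B <1%.
    """

    P = 7
    LP = 6
    VUS_H = 5
    VUS_M = 4
    VUS_L = 3
    LB = 2
    B = 1

    @property
    def token(self) -> str:
        return self.name.replace("_", "-")

    @classmethod
    def from_token(cls, token: str) -> "Tier":
        key = token.strip().upper().replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown classification tier {token!r}") from None

    def __lt__(self, other: "Tier") -> bool:
        if not isinstance(other, Tier):
            return NotImplemented
        return self.value < other.value

    def __le__(self, other: "Tier") -> bool:
        if not isinstance(other, Tier):
            return NotImplemented
        return self.value <= other.value


class TierSet(enum.Enum):
    """Nested variant sets used for burden: P ⊂ P+LP ⊂ P+LP+VUS-H."""

    P = (Tier.P,)
    PLP = (Tier.P, Tier.LP)
    PLPVH = (Tier.P, Tier.LP, Tier.VUS_H)

    @property
    def members(self) -> frozenset[Tier]:
        return frozenset(self.value)

    @property
    def label(self) -> str:
        return {"P": "P", "PLP": "P+LP", "PLPVH": "P+LP+VUS-H"}[self.name]

    @classmethod
    def from_token(cls, token: str) -> "TierSet":
        key = token.strip().upper().replace("+", "").replace("-", "").replace("_", "")
        aliases = {"P": "P", "PLP": "PLP", "PLPVH": "PLPVH", "PLPVUSH": "PLPVH"}
        if key not in aliases:
            raise ValueError(f"unknown tier set {token!r} (use P, PLP or PLPVH)")
        return cls[aliases[key]]

    def __contains__(self, tier: Tier) -> bool:
        return tier in self.members


class InheritanceMode(enum.Enum):
    """Mendelian inheritance mode of a gene-disease association.

    Pseudoautosomal dominant/recessive annotations are mapped to AD/AR at
    ingestion: pseudoautosomal genes behave autosomally for allele-frequency
    arithmetic.
    """

    AD = "AD"
    AR = "AR"
    AD_AR = "AD_AR"
    XLR = "XLR"
    XLD = "XLD"

    @classmethod
    def from_token(cls, token: str) -> "InheritanceMode":
        key = token.strip().upper().replace("/", "_").replace("-", "_")
        aliases = {
            "AD": "AD",
            "AR": "AR",
            "AD_AR": "AD_AR",
            "AR_AD": "AD_AR",
            "XLR": "XLR",
            "XLD": "XLD",
            # pseudoautosomal genes are treated autosomally
            "PAR_AD": "AD",
            "PAD": "AD",
            "PAR_AR": "AR",
            "PAR": "AR",
        }
        if key not in aliases:
            raise ValueError(f"unknown inheritance mode {token!r}")
        return cls[aliases[key]]

    @property
    def token(self) -> str:
        return "AD/AR" if self is InheritanceMode.AD_AR else self.value


# ---------------------------------------------------------------------------
# records


@dataclass
class VariantRecord:
    """One classified variant with per-ancestry AC/AN summary statistics.

    ``an_max`` is the maximum possible called alleles per ancestry
    (2 x cohort individuals for autosomes; supplied, not inferred, for chrX)
    and anchors the coverage QC rule AN/AN_max > min_call_fraction.
    """

    variant_id: str  # chrom:pos:ref:alt, GRCh38, 1-based, left-normalized
    gene: str
    tier: Tier
    filter_status: str
    ac: dict[str, int]
    an: dict[str, int]
    an_max: dict[str, int]

    def __post_init__(self) -> None:
        for anc, ac in self.ac.items():
            an = self.an.get(anc)
            if an is None:
                raise ValueError(f"{self.variant_id}: AC without AN for ancestry {anc!r}")
            an_max = self.an_max.get(anc)
            if an_max is None:
                raise ValueError(f"{self.variant_id}: missing AN_max for ancestry {anc!r}")
            if ac < 0 or an < 0:
                raise ValueError(f"{self.variant_id}: negative AC/AN for {anc!r}")
            if ac > an:
                raise ValueError(
                    f"{self.variant_id}: AC={ac} exceeds AN={an} for ancestry {anc!r}"
                )
            if an > an_max:
                raise ValueError(
                    f"{self.variant_id}: AN={an} exceeds AN_max={an_max} for ancestry {anc!r}"
                )

    @property
    def ancestries(self) -> tuple[str, ...]:
        return tuple(self.ac)

    def is_pass(self) -> bool:
        return self.filter_status == "PASS"


@dataclass
class GeneAnnotation:
    """Curated gene-level annotation.

    ``inheritance`` may be None on raw (pre-curation) rows, in which case
    ``inheritance_raw`` holds the original token (e.g. ``MT``, ``undefined``)
    so curation can log the exclusion reason.  ``restricted_variant_ids``
    limits burden computation to an explicit variant list (the HFE C282Y-only
    secondary-findings rule).
    """

    symbol: str
    inheritance: InheritanceMode | None
    mechanism: str = "LoF"  # LoF / GoF / LoF_GoF
    protein_coding: bool = True
    sources: frozenset[str] = frozenset()
    disease_groups: frozenset[str] = frozenset()
    repeat_expansion_only: bool = False
    mechanism_established: bool = True
    secondary_finding: bool = False
    sf_phenotype_group: str | None = None
    restricted_variant_ids: tuple[str, ...] | None = None
    inheritance_raw: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.disease_groups) - set(DISEASE_GROUPS)
        if unknown:
            raise ValueError(
                f"{self.symbol}: unknown disease group(s) {sorted(unknown)}; "
                f"valid names: {', '.join(DISEASE_GROUPS)}"
            )


@dataclass(frozen=True)
class ConstraintMetrics:
    """Gene-level constraint metrics with the standard threshold flags.

    Constrained means LOEUF < 0.6, missense Z > 3.09 or synonymous Z > 3.71
    (strict inequalities).
    """

    gene: str
    pli: float
    loeuf: float
    mis_z: float
    syn_z: float

    @property
    def loeuf_constrained(self) -> bool:
        return self.loeuf < 0.6

    @property
    def mis_constrained(self) -> bool:
        return self.mis_z > 3.09

    @property
    def syn_constrained(self) -> bool:
        return self.syn_z > 3.71


@dataclass(frozen=True)
class PopulationConfig:
    """Per-ancestry cohort sizes and world population sizes (persons)."""

    cohort_individuals: Mapping[str, int]
    world_population: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, table in (
            ("cohort_individuals", self.cohort_individuals),
            ("world_population", self.world_population),
        ):
            for anc, n in table.items():
                if n <= 0:
                    raise ValueError(f"{name}[{anc!r}] must be positive, got {n}")

    @property
    def reference_population(self) -> int:
        """Sum of the per-ancestry world populations."""
        return sum(self.world_population.values())

    @property
    def ancestries(self) -> tuple[str, ...]:
        return tuple(self.world_population)


@dataclass(frozen=True)
class GeneBurden:
    """Burden of one gene in one ancestry for one variant tier set."""

    gene: str
    ancestry: str
    tier_set: TierSet
    caf: float
    crf: float
    gp: float
    n_variants: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.caf <= 1.0:
            raise ValueError(f"{self.gene}/{self.ancestry}: CAF {self.caf} outside [0,1]")
        if self.caf == 0.0 and (self.crf != 0.0 or self.gp != 0.0):
            raise ValueError(f"{self.gene}/{self.ancestry}: CAF=0 requires CrF=GP=0")
        if self.crf > 0.5 + 1e-12:
            raise ValueError(f"{self.gene}/{self.ancestry}: CrF {self.crf} exceeds 0.5")


@dataclass
class ScreeningResult:
    """Per-ancestry carrier-screening candidate sets and their combinations."""

    threshold: float
    per_ancestry: dict[str, set[str]]
    union: set[str]
    intersection: set[str]


@dataclass
class SecondaryFindingsResult:
    """Actionable-gene (secondary findings) burden summary."""

    per_gene: pd.DataFrame  # gene, ancestry, CAF, CrF, GP, n_variants
    cumulative: pd.DataFrame  # ancestry, cumulative_crf, cumulative_gp
    phenotype_groups: pd.DataFrame  # sf_phenotype_group, ancestry, gp


@dataclass
class BurdenReport:
    """Full analysis output: per-gene burdens plus derived report tables.

    Disease-group prevalences are non-mutually exclusive — a gene contributes
    fully to every group it belongs to.
    """

    gene_burden: pd.DataFrame
    cumulative: pd.DataFrame
    group_gp: pd.DataFrame
    top_crf: pd.DataFrame
    top_gp: pd.DataFrame
    screening: ScreeningResult
    secondary: SecondaryFindingsResult
    scaled_counts: pd.DataFrame


# ---------------------------------------------------------------------------
# "1 in x" formatting


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits) if ndigits > 0 else Decimal(1)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_one_in(p: float, style: str = "gene") -> str:
    """Render a probability as a reciprocal ``"1 in x"`` display string.

    style="group": two decimals when x < 10 ("1 in 2.70"), integer otherwise.
    style="gene": integer below 1000; K/M-suffixed above, with one decimal
    while the scaled value is below 10 ("1 in 2.1K", "1 in 147M").

    Rounding is half-up at display precision; stored fractions are never
    rounded — formatting is presentation only.
    """
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    x = 1.0 / p
    if style == "group":
        if x < 10.0:
            return f"1 in {_round_half_up(x, 2):.2f}"
        return f"1 in {int(_round_half_up(x, 0))}"
    if style != "gene":
        raise ValueError(f"unknown style {style!r} (use 'group' or 'gene')")
    if x < 1000.0:
        return f"1 in {int(_round_half_up(x, 0))}"
    scale, suffix = (1e6, "M") if x >= 1e6 else (1e3, "K")
    v = x / scale
    if v < 10.0:
        v = _round_half_up(v, 1)
        body = f"{int(v)}" if v == int(v) else f"{v:.1f}"
    else:
        body = f"{int(_round_half_up(v, 0))}"
    return f"1 in {body}{suffix}"


def parse_one_in(s: str) -> float:
    """Invert :func:`format_one_in` to the probability at display precision."""
    text = s.strip()
    if not text.startswith("1 in "):
        raise ValueError(f"not a '1 in x' string: {s!r}")
    body = text[5:].strip()
    scale = 1.0
    if body.endswith(("K", "M")):
        scale = 1e3 if body.endswith("K") else 1e6
        body = body[:-1]
    x = float(body) * scale
    if x <= 0:
        raise ValueError(f"non-positive reciprocal in {s!r}")
    return 1.0 / x


# ---------------------------------------------------------------------------
# variant table I/O

_VARIANT_FIXED_COLS = ("variant_id", "gene", "tier", "filter")


def _split_ancestry_columns(columns: Sequence[str]) -> list[str]:
    """Extract ancestry codes from AC_/AN_/AN_max_ suffixed headers."""
    acs = {c[3:] for c in columns if c.startswith("AC_")}
    ans = {c[3:] for c in columns if c.startswith("AN_") and not c.startswith("AN_max_")}
    anmx = {c[7:] for c in columns if c.startswith("AN_max_")}
    if not acs:
        raise ValueError("variant table declares no AC_<ancestry> columns")
    if acs != ans or acs != anmx:
        raise ValueError(
            "ancestry-suffixed columns inconsistent: every ancestry needs "
            f"AC_, AN_ and AN_max_ columns (AC for {sorted(acs)}, AN for "
            f"{sorted(ans)}, AN_max for {sorted(anmx)})"
        )
    # preserve header order
    return [c[3:] for c in columns if c.startswith("AC_")]


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    an_max: Mapping[str, int] | None = None,
    an_max_x: Mapping[str, int] | None = None,
) -> list[VariantRecord]:
    """Read a cohort variant summary table.

    dialect="tsv" expects columns ``variant_id  gene  tier  filter`` plus
    ``AC_<anc>/AN_<anc>/AN_max_<anc>`` triplets.  dialect="vcf" reads a
    VCF v4.2 file with INFO keys ``GENE``, ``TIER`` and ``AC_<anc>/AN_<anc>``;
    since VCFs do not carry AN_max it must be supplied per ancestry
    (``an_max`` for autosomes, ``an_max_x`` for chrX records).
    """
    path = Path(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, an_max=an_max, an_max_x=an_max_x)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'vcf')")

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _VARIANT_FIXED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = set(_VARIANT_FIXED_COLS)
    extra = [
        c
        for c in df.columns
        if c not in known and not c.startswith(("AC_", "AN_"))
    ]
    if extra:
        raise ValueError(f"{path}: unrecognized column(s) {extra}")
    ancestries = _split_ancestry_columns(list(df.columns))

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        vid = row_d["variant_id"]
        try:
            if vid in seen:
                raise ValueError(f"duplicate variant_id {vid!r}")
            seen.add(vid)
            rec = VariantRecord(
                variant_id=vid,
                gene=row_d["gene"],
                tier=Tier.from_token(row_d["tier"]),
                filter_status=row_d["filter"],
                ac={a: int(row_d[f"AC_{a}"]) for a in ancestries},
                an={a: int(row_d[f"AN_{a}"]) for a in ancestries},
                an_max={a: int(row_d[f"AN_max_{a}"]) for a in ancestries},
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {idx}: {exc}") from exc
        records.append(rec)
    return records


def _read_variant_vcf(
    path: Path,
    an_max: Mapping[str, int] | None,
    an_max_x: Mapping[str, int] | None,
) -> list[VariantRecord]:
    import pysam

    if an_max is None:
        raise ValueError("VCF dialect requires an_max per ancestry (not stored in VCF)")
    an_max_x = an_max_x or an_max
    ancestries = list(an_max)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "pre-split into biallelic rows"
                )
            info = rec.info
            is_x = rec.chrom.lstrip("chr") == "X"
            amax = an_max_x if is_x else an_max
            ac: dict[str, int] = {}
            an: dict[str, int] = {}
            for anc in ancestries:
                if f"AC_{anc}" in info:
                    raw_ac = info[f"AC_{anc}"]
                    raw_an = info[f"AN_{anc}"]
                    ac[anc] = int(raw_ac[0] if isinstance(raw_ac, tuple) else raw_ac)
                    an[anc] = int(raw_an[0] if isinstance(raw_an, tuple) else raw_an)
            vid = f"{rec.chrom.lstrip('chr')}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            filter_status = "PASS" if (not rec.filter.keys() or "PASS" in rec.filter) else ";".join(rec.filter)
            records.append(
                VariantRecord(
                    variant_id=vid,
                    gene=str(info["GENE"]),
                    tier=Tier.from_token(str(info["TIER"])),
                    filter_status=filter_status,
                    ac=ac,
                    an=an,
                    an_max={a: amax[a] for a in ac},
                )
            )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write variant records in the canonical TSV dialect (re-readable)."""
    records = list(records)
    ancestries: list[str] = []
    for rec in records:
        for anc in rec.ancestries:
            if anc not in ancestries:
                ancestries.append(anc)
    cols = list(_VARIANT_FIXED_COLS)
    for a in ancestries:
        cols += [f"AC_{a}", f"AN_{a}", f"AN_max_{a}"]
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "variant_id": rec.variant_id,
            "gene": rec.gene,
            "tier": rec.tier.token,
            "filter": rec.filter_status,
        }
        for a in ancestries:
            row[f"AC_{a}"] = rec.ac.get(a, 0)
            row[f"AN_{a}"] = rec.an.get(a, 0)
            row[f"AN_max_{a}"] = rec.an_max.get(a, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation I/O

_GENE_COLS = ("symbol", "inheritance", "mechanism", "sources", "disease_groups")
_UNDEFINED_INHERITANCE = {"", "NA", "NONE", "UNDEFINED", "UNASCERTAINED"}
_MITO_INHERITANCE = {"MT", "MITO", "MITOCHONDRIAL"}


def _parse_inheritance(token: str) -> tuple[InheritanceMode | None, str]:
    raw = token.strip()
    key = raw.upper().replace("-", "_").replace("/", "_")
    if key in _UNDEFINED_INHERITANCE or key in _MITO_INHERITANCE:
        return None, raw
    return InheritanceMode.from_token(raw), raw


def _parse_listish(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text or text.upper() in {"NA", "NONE", "-"}:
        return []
    return [t.strip() for t in text.split(";") if t.strip()]


def _parse_flag(cell: object, default: bool = False) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return default
    text = str(cell).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n", ""}:
        return default if text == "" else False
    raise ValueError(f"unparseable boolean flag {cell!r}")


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV.

    Required columns: symbol, inheritance, mechanism, sources, disease_groups.
    Optional: protein_coding, repeat_expansion_only, mechanism_established,
    secondary_finding, sf_phenotype_group, restricted_variant_ids.  List cells
    are ';'-separated.  Duplicate symbols are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.to_dict("records"), start=2):
        try:
            symbol = str(row["symbol"]).strip()
            if symbol in seen:
                raise ValueError(f"duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            inheritance, raw = _parse_inheritance(str(row["inheritance"] or ""))
            restricted = _parse_listish(row.get("restricted_variant_ids"))
            out.append(
                GeneAnnotation(
                    symbol=symbol,
                    inheritance=inheritance,
                    inheritance_raw=raw,
                    mechanism=str(row.get("mechanism") or "LoF").strip(),
                    protein_coding=_parse_flag(row.get("protein_coding"), default=True),
                    sources=frozenset(_parse_listish(row.get("sources"))),
                    disease_groups=frozenset(_parse_listish(row.get("disease_groups"))),
                    repeat_expansion_only=_parse_flag(row.get("repeat_expansion_only")),
                    mechanism_established=_parse_flag(
                        row.get("mechanism_established"), default=True
                    ),
                    secondary_finding=_parse_flag(row.get("secondary_finding")),
                    sf_phenotype_group=(str(row["sf_phenotype_group"]).strip() or None)
                    if row.get("sf_phenotype_group")
                    and not (
                        isinstance(row["sf_phenotype_group"], float)
                        and math.isnan(row["sf_phenotype_group"])
                    )
                    else None,
                    restricted_variant_ids=tuple(restricted) if restricted else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {idx}: {exc}") from exc
    return out


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "symbol": g.symbol,
                "inheritance": g.inheritance.token if g.inheritance else g.inheritance_raw,
                "mechanism": g.mechanism,
                "sources": ";".join(sorted(g.sources)),
                "disease_groups": ";".join(sorted(g.disease_groups)),
                "protein_coding": int(g.protein_coding),
                "repeat_expansion_only": int(g.repeat_expansion_only),
                "mechanism_established": int(g.mechanism_established),
                "secondary_finding": int(g.secondary_finding),
                "sf_phenotype_group": g.sf_phenotype_group or "",
                "restricted_variant_ids": ";".join(g.restricted_variant_ids or ()),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_population_config(path: str | Path) -> PopulationConfig:
    """Read a population config TSV: ancestry, cohort_individuals, world_population."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("ancestry", "cohort_individuals", "world_population"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PopulationConfig(
        cohort_individuals=dict(zip(df["ancestry"], df["cohort_individuals"].astype(int))),
        world_population=dict(zip(df["ancestry"], df["world_population"].astype(int))),
    )


def read_constraint_metrics(path: str | Path) -> list[ConstraintMetrics]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ConstraintMetrics(
            gene=str(r["gene"]),
            pli=float(r["pLI"]),
            loeuf=float(r["LOEUF"]),
            mis_z=float(r["mis_z"]),
            syn_z=float(r["syn_z"]),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# report output


def _with_one_in(df: pd.DataFrame, columns: Mapping[str, str]) -> pd.DataFrame:
    """Add formatted reciprocal columns next to fraction columns."""
    out = df.copy()
    for col, style in columns.items():
        if col in out.columns:
            out[f"{col}_one_in"] = [
                format_one_in(v, style) if v and v > 0 else ""
                for v in out[col].astype(float)
            ]
    return out


def write_burden_tables(report: BurdenReport, outdir: str | Path) -> list[Path]:
    """Write every report section as TSV with deterministic column order.

    Fractions are written at full precision; formatted "1 in x" strings sit
    alongside for readability.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)

    emit(
        "gene_burden.tsv",
        _with_one_in(report.gene_burden, {"CrF": "gene", "GP": "gene"}),
    )
    emit("cumulative_burden.tsv", report.cumulative)
    emit("disease_group_gp.tsv", _with_one_in(report.group_gp, {"GP": "group", "GP_mean": "group"}))
    emit("top_genes_crf.tsv", _with_one_in(report.top_crf, {"CrF": "gene"}))
    emit("top_genes_gp.tsv", _with_one_in(report.top_gp, {"GP": "gene"}))

    scr_rows = []
    for anc in sorted(report.screening.per_ancestry):
        for gene in sorted(report.screening.per_ancestry[anc]):
            scr_rows.append(
                {
                    "ancestry": anc,
                    "gene": gene,
                    "in_intersection": int(gene in report.screening.intersection),
                }
            )
    emit(
        "screening_candidates.tsv",
        pd.DataFrame(scr_rows, columns=["ancestry", "gene", "in_intersection"]),
    )
    emit(
        "secondary_findings_genes.tsv",
        _with_one_in(report.secondary.per_gene, {"CrF": "gene", "GP": "gene"}),
    )
    emit("secondary_findings_cumulative.tsv", report.secondary.cumulative)
    emit(
        "secondary_findings_groups.tsv",
        _with_one_in(report.secondary.phenotype_groups, {"GP": "group"}),
    )
    emit("scaled_counts.tsv", report.scaled_counts)
    return written
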