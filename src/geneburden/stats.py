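"""Hardy-Weinberg burden statistics.

All quantities derive from a gene's cumulative allele frequency (CAF), the
sum of the allele frequencies of its qualifying variants under independent
assortment.  With c = CAF:

* carrier frequency          CrF  = 2 c (1 - c)
* homozygote + compound het  HomF = c**2
* genetic prevalence         GP   = CrF   for AD and AD/AR genes,
                                    HomF  for AR genes,
                                    c (c + 1) / 2                for XLR,
                                    (1 - c) c + c (c + 1) / 2    for XLD
* non-carrier likelihood     prod over genes of (1 - CrF_i)
* reported carrier freq.     rCrF = 2 sqrt(rP) (1 - sqrt(rP))

The X-linked forms average a hemizygous male contribution (prevalence c)
with the female diploid term under a 50:50 sex ratio; XLD adds the affected
female heterozygotes.  Pure functions, no I/O.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GeneBurden, InheritanceMode

__all__ = [
    "ReportedPrevalence",
    "allele_frequency",
    "cumulative_allele_frequency",
    "carrier_frequency",
    "invert_carrier_frequency",
    "homozygote_comphet_frequency",
    "compound_het_pair",
    "genetic_prevalence",
    "phenotype_entries",
    "noncarrier_likelihood",
    "reported_crf",
    "cumulative_crf",
    "cumulative_gp",
]


def allele_frequency(ac: int, an: int) -> float:
    """AF = AC / AN for one variant in one ancestry."""
    if an <= 0:
        raise ValueError("AN must be positive (variant unusable in this ancestry)")
    if not 0 <= ac <= an:
        raise ValueError(f"require 0 <= AC <= AN, got AC={ac}, AN={an}")
    return ac / an


def cumulative_allele_frequency(afs: Iterable[float]) -> float:
    """Sum of per-variant allele frequencies, capped at 1.0.

    The independence assumption can push raw sums above 1 for extreme
    inputs; the cap keeps CAF a probability and emits a warning.
    """
    total = 0.0
    for af in afs:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0,1]")
        total += af
    if total > 1.0:
        warnings.warn(
            f"raw CAF {total:.6g} exceeds 1; capped at 1.0 "
            "(independent-assortment assumption broken)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return total


def carrier_frequency(caf: float) -> float:
    """CrF = 2 CAF (1 - CAF): heterozygous-carrier proportion under HWE."""
    if not 0.0 <= caf <= 1.0:
        raise ValueError(f"CAF {caf} outside [0,1]")
    return 2.0 * caf * (1.0 - caf)


def invert_carrier_frequency(crf: float) -> float:
    """Minor root of 2 c (1 - c) = CrF: c = (1 - sqrt(1 - 2 CrF)) / 2.

    Reported carrier frequencies live in the minor-allele regime, so the
    minor root (c <= 0.5) is always taken.
    """
    if not 0.0 <= crf <= 0.5:
        raise ValueError(f"CrF {crf} outside [0, 0.5], the range of 2c(1-c)")
    return (1.0 - math.sqrt(1.0 - 2.0 * crf)) / 2.0


def homozygote_comphet_frequency(caf: float) -> float:
    """HomF = CAF**2: combined homozygote and compound-heterozygote frequency."""
    if not 0.0 <= caf <= 1.0:
        raise ValueError(f"CAF {caf} outside [0,1]")
    return caf * caf


def compound_het_pair(af_i: float, af_ii: float) -> float:
    """Frequency of the compound heterozygote for two distinct alleles.

    (AF_i + AF_ii)**2 - AF_i**2 - AF_ii**2 = 2 AF_i AF_ii.  Summed over all
    unordered distinct pairs plus the per-allele homozygote terms this
    reconstructs CAF**2 exactly.
    """
    for af in (af_i, af_ii):
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0,1]")
    return 2.0 * af_i * af_ii


def genetic_prevalence(caf: float, inheritance: InheritanceMode) -> float:
    """Dispatch GP by inheritance mode (see module docstring)."""
    if not 0.0 <= caf <= 1.0:
        raise ValueError(f"CAF {caf} outside [0,1]")
    if inheritance in (InheritanceMode.AD, InheritanceMode.AD_AR):
        return carrier_frequency(caf)
    if inheritance is InheritanceMode.AR:
        return homozygote_comphet_frequency(caf)
    if inheritance is InheritanceMode.XLR:
        return caf * (caf + 1.0) / 2.0
    if inheritance is InheritanceMode.XLD:
        return (1.0 - caf) * caf + caf * (caf + 1.0) / 2.0
    raise ValueError(f"unknown inheritance mode {inheritance!r}")


#: Phenotype inheritance entries per mode: an AD/AR gene has both a dominant
#: and a recessive phenotype and contributes one GP term for each in the
#: cumulative (and disease-group) counting rule.
_PHENOTYPE_ENTRIES: dict[InheritanceMode, tuple[InheritanceMode, ...]] = {
    InheritanceMode.AD: (InheritanceMode.AD,),
    InheritanceMode.AR: (InheritanceMode.AR,),
    InheritanceMode.AD_AR: (InheritanceMode.AD, InheritanceMode.AR),
    InheritanceMode.XLR: (InheritanceMode.XLR,),
    InheritanceMode.XLD: (InheritanceMode.XLD,),
}


def phenotype_entries(inheritance: InheritanceMode) -> tuple[InheritanceMode, ...]:
    """Inheritance phenotype entries a gene contributes to cumulative GP."""
    return _PHENOTYPE_ENTRIES[inheritance]


def noncarrier_likelihood(crfs: Iterable[float]) -> float:
    """Probability of carrying no qualifying variant: prod(1 - CrF_i)."""
    result = 1.0
    for crf in crfs:
        if not 0.0 <= crf <= 1.0:
            raise ValueError(f"CrF {crf} outside [0,1]")
        result *= 1.0 - crf
    return result


def reported_crf(rp: float) -> float:
    """Carrier frequency back-calculated from a reported disease prevalence.

    rCrF = 2 sqrt(rP) (1 - sqrt(rP)); for an AR disease with GP = c**2 this
    is the exact inverse of the CrF formula (sqrt recovers c).
    """
    if not 0.0 <= rp <= 1.0:
        raise ValueError(f"reported prevalence {rp} outside [0,1]")
    root = math.sqrt(rp)
    return 2.0 * root * (1.0 - root)


@dataclass(frozen=True)
class ReportedPrevalence:
    """Literature-reported prevalence of a gene's disease, with derived rCrF."""

    gene: str
    rp: float
    ancestry_scope: str = "global"
    rcrf: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rcrf", reported_crf(self.rp))


def cumulative_crf(burdens: Sequence[GeneBurden]) -> float:
    """Expected qualifying-variant count per individual: sum of per-gene CrF.

    Each gene is counted exactly once regardless of inheritance.  The sum of
    carrier probabilities is read as an expected count, not a probability,
    so it may exceed 1.
    """
    seen: set[str] = set()
    total = 0.0
    for b in burdens:
        if b.gene in seen:
            raise ValueError(f"duplicate gene {b.gene!r} in cumulative CrF input")
        seen.add(b.gene)
        total += b.crf
    return total


def cumulative_gp(
    cafs: Mapping[str, float],
    inheritance: Mapping[str, InheritanceMode],
    entries: Mapping[str, Sequence[InheritanceMode]] | None = None,
) -> float:
    """Expected disease-compatible genotype count per individual.

    Each gene is counted once per inheritance phenotype entry: an AD/AR gene
    contributes a dominant term 2c(1-c) plus a recessive term c**2; other
    modes contribute their single dispatch value.  ``entries`` overrides the
    default per-mode phenotype entries when explicit gene-phenotype pairs
    are available.
    """
    total = 0.0
    for gene, caf in cafs.items():
        mode = inheritance.get(gene)
        if mode is None:
            raise ValueError(f"no inheritance mode for gene {gene!r}")
        gene_entries = entries.get(gene) if entries is not None else None
        if gene_entries is None:
            gene_entries = phenotype_entries(mode)
        for entry in gene_entries:
            total += genetic_prevalence(caf, entry)
    return total
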