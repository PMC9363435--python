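"""Population burden of deletional α-thalassemia under Hardy–Weinberg.

From a cohort's genotype tallies, each individual contributes two haplotypes
to the allele pool.  Alleles are grouped into three functional classes:

* αα (normal) with frequency p_norm,
* α+ single-gene deletions (−α3.7, −α4.2) with frequency p_plus,
* α0 double-gene *cis* deletions (−−SEA, −−THAI, −−FIL) with frequency
  p_zero.

Under random mating (a Punnett square over these classes), the expected
phenotype frequencies are

    Hb Bart's hydrops   p_zero²
    Hb H disease        2·p_zero·p_plus
    α-thal trait        2·p_norm·p_zero + p_plus²
    silent carrier      2·p_norm·p_plus
    normal              p_norm²

which sum to (p_norm + p_plus + p_zero)² = 1 identically.  Multiplying by an
annual birth count projects the number of affected newborns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .regions import ALLELES, Genotype

__all__ = [
    "GenotypeCountTable",
    "AlleleFrequencies",
    "PhenotypeFrequencies",
    "PHENOTYPES",
    "allele_frequencies",
    "phenotype_from_genotype",
    "expected_phenotype_frequencies",
    "project_births",
    "read_genotype_counts",
    "genotype_prevalences",
    "VIETNAM_BIRTHS_2019",
]

PHENOTYPES = ("normal", "silent_carrier", "trait", "hbh", "barts")

#: Children born in the 12 months before 2019-04-01 (national census figure
#: used for the worked projection).
VIETNAM_BIRTHS_2019 = 1_394_401

_ALPHA_ZERO = {"SEA", "THAI", "FIL"}
_ALPHA_PLUS = {"3.7", "4.2"}

#: Phenotype by total functional α-gene count of the two haplotypes.
_PHENOTYPE_BY_GENES = {
    4: "normal",
    3: "silent_carrier",
    2: "trait",
    1: "hbh",
    0: "barts",
}


@dataclass(frozen=True)
class GenotypeCountTable:
    """Mapping of ``"hap1/hap2"`` genotype strings to individual counts."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for gt, n in self.counts.items():
            Genotype.from_string(gt)  # raises on unknown alleles
            if n < 0:
                raise ValueError(f"negative count for {gt}: {n}")
        if self.n_individuals == 0:
            raise ValueError("empty genotype table")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class AlleleFrequencies:
    per_allele: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.per_allele.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.per_allele.values()):
            raise ValueError("negative allele frequency")

    @property
    def p_zero(self) -> float:
        return sum(f for a, f in self.per_allele.items() if a in _ALPHA_ZERO)

    @property
    def p_plus(self) -> float:
        return sum(f for a, f in self.per_allele.items() if a in _ALPHA_PLUS)

    @property
    def p_norm(self) -> float:
        return self.per_allele.get("aa", 0.0)


@dataclass(frozen=True)
class PhenotypeFrequencies:
    normal: float
    silent_carrier: float
    trait: float
    hbh: float
    barts: float

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PHENOTYPES}

    def as_percent(self, decimals: int = 4) -> dict[str, float]:
        return {p: round(getattr(self, p) * 100, decimals) for p in PHENOTYPES}


def allele_frequencies(table: GenotypeCountTable) -> AlleleFrequencies:
    """Tally haplotypes (2 per individual) into per-allele frequencies."""
    tally: dict[str, int] = {}
    for gt_str, n in table.counts.items():
        gt = Genotype.from_string(gt_str)
        for hap in (gt.hap1, gt.hap2):
            tally[hap.name] = tally.get(hap.name, 0) + n
    two_n = table.n_haplotypes
    return AlleleFrequencies({a: c / two_n for a, c in sorted(tally.items())})


def phenotype_from_genotype(genotype: Genotype) -> str:
    """Phenotype class from the genotype's functional α-gene count."""
    return _PHENOTYPE_BY_GENES[genotype.n_functional_genes]


def expected_phenotype_frequencies(af: AlleleFrequencies) -> PhenotypeFrequencies:
    """Punnett-square phenotype frequencies under random mating."""
    p0, pp, pn = af.p_zero, af.p_plus, af.p_norm
    return PhenotypeFrequencies(
        normal=pn * pn,
        silent_carrier=2 * pn * pp,
        trait=2 * pn * p0 + pp * pp,
        hbh=2 * p0 * pp,
        barts=p0 * p0,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def project_births(pf: PhenotypeFrequencies, n_births: int) -> dict[str, int]:
    """Expected newborns per phenotype, plus the total needing follow-up.

    ``affected_or_carrier`` sums Hb H, trait and silent carrier — the births
    a screening programme would flag (Hb Bart's hydrops is separately
    counted as it is usually lethal in utero).
    """
    if n_births < 0:
        raise ValueError("n_births must be >= 0")
    out = {p: _round_half_up(getattr(pf, p) * n_births) for p in PHENOTYPES}
    out["affected_or_carrier"] = out["hbh"] + out["trait"] + out["silent_carrier"]
    return out


def genotype_prevalences(table: GenotypeCountTable) -> dict[str, float]:
    """Observed cohort prevalences (%): per genotype plus summary rows."""
    n = table.n_individuals
    out = {gt: 100 * c / n for gt, c in table.counts.items()}
    common = {"aa/aa", "aa/SEA", "3.7/aa", "aa/3.7", "4.2/aa", "aa/4.2"}
    carriers = sum(
        c for gt, c in table.counts.items() if Genotype.from_string(gt).label != "aa_aa"
    )
    rare = sum(
        c for gt, c in table.counts.items() if Genotype.from_string(gt).label == "Others"
    )
    out["any_deletion"] = 100 * carriers / n
    out["rare_genotypes"] = 100 * rare / n
    return out


def read_genotype_counts(path) -> GenotypeCountTable:
    """Read a two-column TSV (genotype, count) into a table."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "genotype" not in cols or "count" not in cols:
        raise ValueError(f"{path}: need 'genotype' and 'count' columns")
    df.columns = cols
    return GenotypeCountTable(
        {str(g): int(c) for g, c in zip(df["genotype"], df["count"])}
    )
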