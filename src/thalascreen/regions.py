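"""Model of the α-globin (HBA) locus: intervals, deletion alleles, genotypes, bins.

The α-globin cluster sits on the tip of chromosome 16 (16p13.3) and carries
two functional α genes per haplotype (HBA2, HBA1).  The common deletional
α-thalassemia alleles either remove one gene in *cis* (−α3.7, −α4.2; "α+"
alleles) or both (−−SEA, −−THAI, −−FIL; "α0" alleles).  Copy number over the
cluster is therefore a step function of position determined by the two
haplotypes an individual carries, and that step function — averaged over a
tiling of genomic bins — is the depth signature a coverage classifier learns.

Coordinates are 0-based half-open (BED convention) throughout.  The default
geometry below approximates the GRCh38 layout of the locus; exact deletion
breakpoints vary between carriers and assays, so the geometry is
configuration, not a constant: every function here takes explicit intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GenomicInterval",
    "DeletionAllele",
    "Genotype",
    "BinSet",
    "ALLELES",
    "DEFAULT_REGION",
    "CLASS_LABELS",
    "make_uniform_bins",
    "copy_fraction_track",
    "read_bins_bed",
    "write_bins_bed",
    "load_region_config",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class DeletionAllele:
    """One α-globin haplotype allele.

    ``deleted`` is the removed genomic interval (None for the intact αα
    haplotype) and ``n_functional_genes`` the number of working α genes the
    haplotype retains: 2 (normal), 1 (α+ single-gene deletions), or 0 (α0
    double-gene deletions).
    """

    name: str
    deleted: GenomicInterval | None
    n_functional_genes: int

    def __post_init__(self) -> None:
        if self.n_functional_genes not in (0, 1, 2):
            raise ValueError("n_functional_genes must be 0, 1 or 2")
        if (self.deleted is None) != (self.n_functional_genes == 2):
            raise ValueError(
                "normal allele must have no deletion; deletion alleles must "
                "remove at least one gene"
            )

    @property
    def is_normal(self) -> bool:
        return self.deleted is None


# Approximate GRCh38 chr16 geometry.  The 21 kb analysis region tiles the
# cluster; HBA2 ~172.9-173.7 kb, HBA1 ~176.7-177.5 kb.  SEA (~19.3 kb) spans
# both genes; THAI and FIL are larger α0 deletions fully containing SEA;
# −α3.7 and −α4.2 are the rightward/leftward single-gene deletions.  The
# region's left margin deliberately extends past the THAI breakpoint: TPM
# features are within-sample relative, so a deletion covering every bin is
# indistinguishable from normal — some bins must sit outside it.
DEFAULT_REGION = GenomicInterval("chr16", 160_000, 181_000)

_CHROM = DEFAULT_REGION.chrom

ALLELES: dict[str, DeletionAllele] = {
    "aa": DeletionAllele("aa", None, 2),
    "SEA": DeletionAllele("SEA", GenomicInterval(_CHROM, 165_400, 184_700), 0),
    "THAI": DeletionAllele("THAI", GenomicInterval(_CHROM, 162_000, 196_500), 0),
    "FIL": DeletionAllele("FIL", GenomicInterval(_CHROM, 156_000, 189_000), 0),
    "3.7": DeletionAllele("3.7", GenomicInterval(_CHROM, 173_700, 177_400), 1),
    "4.2": DeletionAllele("4.2", GenomicInterval(_CHROM, 168_700, 172_900), 1),
}

#: The five classifier target classes.
CLASS_LABELS = ("aa_aa", "aa_SEA", "aa_3.7", "aa_4.2", "Others")

# Genotypes (unordered allele pairs) that map onto a named class; everything
# else — compound heterozygotes, homozygous deletions, THAI/FIL carriers —
# is "Others".
_COMMON = {
    frozenset(["aa"]): "aa_aa",
    frozenset(["aa", "SEA"]): "aa_SEA",
    frozenset(["aa", "3.7"]): "aa_3.7",
    frozenset(["aa", "4.2"]): "aa_4.2",
}


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of haplotype alleles; (h1, h2) ≡ (h2, h1)."""

    hap1: DeletionAllele
    hap2: DeletionAllele

    @classmethod
    def from_names(cls, name1: str, name2: str) -> "Genotype":
        try:
            return cls(ALLELES[name1], ALLELES[name2])
        except KeyError as exc:
            raise ValueError(f"unknown allele name: {exc.args[0]!r}") from None

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse ``"aa/SEA"``-style genotype strings."""
        parts = text.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"genotype must be 'hap1/hap2', got {text!r}")
        return cls.from_names(parts[0], parts[1])

    @property
    def label(self) -> str:
        key = frozenset([self.hap1.name, self.hap2.name])
        return _COMMON.get(key, "Others")

    @property
    def n_functional_genes(self) -> int:
        return self.hap1.n_functional_genes + self.hap2.n_functional_genes

    def __str__(self) -> str:
        return f"{self.hap1.name}/{self.hap2.name}"

    def _key(self) -> tuple[str, str]:
        return tuple(sorted([self.hap1.name, self.hap2.name]))  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


class BinSet:
    """Ordered, non-overlapping bins tiling one chromosome.

    The bins are the classifier's feature space: the default layout is 66
    contiguous bins over the 21 kb cluster region.
    """

    def __init__(self, bins: Sequence[GenomicInterval]):
        bins = list(bins)
        if not bins:
            raise ValueError("no bins")
        chroms = {b.chrom for b in bins}
        if len(chroms) > 1:
            raise ValueError(f"bins span multiple chromosomes: {sorted(chroms)}")
        for i in range(1, len(bins)):
            if bins[i].start < bins[i - 1].start:
                raise ValueError(
                    f"bins not sorted at index {i}: {bins[i - 1]} then {bins[i]}"
                )
            if bins[i].start < bins[i - 1].end:
                raise ValueError(
                    f"bins overlap at index {i}: {bins[i - 1]} and {bins[i]}"
                )
        self.bins: tuple[GenomicInterval, ...] = tuple(bins)
        self.chrom: str = bins[0].chrom
        self.starts = np.array([b.start for b in bins], dtype=np.int64)
        self.ends = np.array([b.end for b in bins], dtype=np.int64)
        self.lengths = self.ends - self.starts

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.bins[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinSet):
            return NotImplemented
        return self.bins == other.bins

    @property
    def span(self) -> int:
        return int(self.ends[-1] - self.starts[0])


def make_uniform_bins(region: GenomicInterval, n_bins: int) -> BinSet:
    """Tile ``region`` with ``n_bins`` contiguous bins of near-equal width.

    Bin widths differ by at most 1 bp and the bins concatenate exactly to the
    region (tiling conservation).
    """
    if n_bins <= 0:
        raise ValueError(f"n_bins must be positive, got {n_bins}")
    if region.length < n_bins:
        raise ValueError(
            f"region of {region.length} bp is shorter than {n_bins} bins"
        )
    edges = region.start + np.round(
        np.linspace(0, region.length, n_bins + 1)
    ).astype(np.int64)
    return BinSet(
        [
            GenomicInterval(region.chrom, int(edges[i]), int(edges[i + 1]))
            for i in range(n_bins)
        ]
    )


def copy_fraction_track(genotype: Genotype, bins: BinSet) -> np.ndarray:
    """Per-bin fraction of the diploid copy number retained, in [0, 1].

    Each position contributes 1 per haplotype whose deletion does not cover
    it, 0 otherwise; the bin value is the length-weighted mean of the
    positionwise (retained copies)/2.  αα/αα gives all ones; a heterozygous
    α0 deletion gives 0.5 across bins fully inside its interval.
    """
    frac = np.zeros(len(bins))
    for hap in (genotype.hap1, genotype.hap2):
        if hap.deleted is None or hap.deleted.chrom != bins.chrom:
            frac += 0.5
            continue
        ov = np.minimum(bins.ends, hap.deleted.end) - np.maximum(
            bins.starts, hap.deleted.start
        )
        ov = np.clip(ov, 0, None)
        frac += 0.5 * (1.0 - ov / bins.lengths)
    return frac


def write_bins_bed(bins: BinSet, path) -> None:
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\n")


def read_bins_bed(path) -> BinSet:
    """Read a BED3 file of bins; validates sorting and non-overlap."""
    intervals: list[GenomicInterval] = []
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(f"line {lineno}: expected >=3 tab-separated fields")
                continue
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ValueError("invalid BED records: " + "; ".join(bad))
    if not intervals:
        raise ValueError("no bins")
    try:
        return BinSet(intervals)
    except ValueError as exc:
        raise ValueError(f"invalid bin layout in {path}: {exc}") from None


def load_region_config(path) -> dict:
    """Load a YAML locus-geometry config.

    Expected keys: ``region`` ({chrom, start, end}), optional ``n_bins``
    (default 66) and ``alleles`` (name → {start, end, n_functional_genes}).
    Returns {"region", "bins", "alleles"} with the default alleles used for
    any allele not overridden.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    reg = cfg["region"]
    region = GenomicInterval(reg["chrom"], int(reg["start"]), int(reg["end"]))
    n_bins = int(cfg.get("n_bins", 66))
    alleles = dict(ALLELES)
    for name, spec in (cfg.get("alleles") or {}).items():
        alleles[name] = DeletionAllele(
            name,
            GenomicInterval(region.chrom, int(spec["start"]), int(spec["end"])),
            int(spec["n_functional_genes"]),
        )
    return {
        "region": region,
        "bins": make_uniform_bins(region, n_bins),
        "alleles": alleles,
    }
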