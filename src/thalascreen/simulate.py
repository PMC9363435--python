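"""Synthetic cfDNA coverage generator for the α-globin locus.

The generative model per sample:

* expected depth per bin  μ_i = D · (L_i / ΣL) · c_i · b_i, where D is the
  expected fragment count over the region, L_i the bin length, c_i the
  genotype's per-bin copy fraction (1 for intact diploid, 0.5 under a
  heterozygous deletion, 0 under a homozygous one) and b_i a per-bin
  multiplicative bias drawn once per sample from LogNormal(−σ²/2, σ)
  (unit mean), standing in for capture-efficiency and mappability bias;
* raw counts  raw_i ~ NegativeBinomial(μ_i, k) with variance μ + μ²/k;
  k = ∞ recovers Poisson.

Defaults emulate the targeted-capture study conditions: a ~21 kb region at
~1852X mean coverage with ~166 bp fragments (≈ 234,000 fragments per
sample), bias σ = 0.1 and dispersion k = 20.  An optional fetal-fraction
admixture mixes in a fetal copy-number track that inherits one maternal
haplotype and one drawn from population allele frequencies; it exists to
test robustness of the maternal caller, not to call fetal genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .counts import CountProfile, Fragment, tpm_normalize
from .regions import (
    ALLELES,
    DEFAULT_REGION,
    BinSet,
    DeletionAllele,
    Genotype,
    copy_fraction_track,
    make_uniform_bins,
)

__all__ = [
    "SimulatorConfig",
    "CohortSpec",
    "STUDY_GENOTYPE_COUNTS",
    "coverage_to_fragments",
    "simulate_counts",
    "simulate_fragments",
    "simulate_cohort",
]

#: Genotype tallies of the screening cohort (N = 68,885) used as the default
#: class mix for simulated cohorts.
STUDY_GENOTYPE_COUNTS: dict[str, int] = {
    "aa/aa": 63_541,
    "aa/SEA": 2_801,
    "3.7/aa": 2_021,
    "4.2/aa": 452,
    "3.7/SEA": 49,
    "aa/THAI": 8,
    "4.2/SEA": 7,
    "3.7/4.2": 6,
}


def coverage_to_fragments(coverage_x: float, region_bp: int, fragment_bp: float) -> float:
    """Convert X-coverage over a region into an expected fragment count."""
    return coverage_x * region_bp / fragment_bp


_DEFAULT_BINS = make_uniform_bins(DEFAULT_REGION, 66)
#: 1852X over 21 kb with 166 bp fragments.
DEFAULT_MEAN_DEPTH = coverage_to_fragments(1852, DEFAULT_REGION.length, 166)


@dataclass
class SimulatorConfig:
    bins: BinSet = field(default_factory=lambda: _DEFAULT_BINS)
    alleles: Mapping[str, DeletionAllele] = field(default_factory=lambda: dict(ALLELES))
    mean_depth: float = DEFAULT_MEAN_DEPTH
    bias_sigma: float = 0.1
    dispersion: float = 20.0
    fragment_length_mean: float = 166.0
    fragment_length_sd: float = 40.0
    fetal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.bias_sigma < 0:
            raise ValueError("bias_sigma must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (use math.inf for Poisson)")
        if not 0 <= self.fetal_fraction <= 0.5:
            raise ValueError("fetal_fraction must lie in [0, 0.5]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _sample_bias(config: SimulatorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.bias_sigma == 0:
        return np.ones(len(config.bins))
    s = config.bias_sigma
    return rng.lognormal(mean=-s * s / 2, sigma=s, size=len(config.bins))


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not pos.any():
        return out
    if math.isinf(dispersion):
        out[pos] = rng.poisson(mu[pos])
    else:
        k = dispersion
        p = k / (k + mu[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def _expected_track(
    genotype: Genotype, config: SimulatorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin NB mean μ_i and the copy-fraction track used to build it."""
    cf = copy_fraction_track(genotype, config.bins)
    if config.fetal_fraction > 0:
        cf_fetal = copy_fraction_track(
            _draw_fetal_genotype(genotype, config, rng), config.bins
        )
        cf = (1 - config.fetal_fraction) * cf + config.fetal_fraction * cf_fetal
    bias = _sample_bias(config, rng)
    lengths = config.bins.lengths.astype(float)
    mu = config.mean_depth * (lengths / lengths.sum()) * cf * bias
    return mu, cf


_DEFAULT_PATERNAL_AF = None  # filled lazily from STUDY_GENOTYPE_COUNTS


def _paternal_allele_frequencies(config: SimulatorConfig) -> tuple[list[str], np.ndarray]:
    global _DEFAULT_PATERNAL_AF
    if _DEFAULT_PATERNAL_AF is None:
        tally: dict[str, int] = {}
        for gt, n in STUDY_GENOTYPE_COUNTS.items():
            for name in gt.split("/"):
                tally[name] = tally.get(name, 0) + n
        names = sorted(tally)
        freqs = np.array([tally[n] for n in names], dtype=float)
        _DEFAULT_PATERNAL_AF = (names, freqs / freqs.sum())
    return _DEFAULT_PATERNAL_AF


def _draw_fetal_genotype(
    maternal: Genotype, config: SimulatorConfig, rng: np.random.Generator
) -> Genotype:
    maternal_hap = maternal.hap1 if rng.random() < 0.5 else maternal.hap2
    names, freqs = _paternal_allele_frequencies(config)
    paternal_hap = config.alleles[names[rng.choice(len(names), p=freqs)]]
    return Genotype(maternal_hap, paternal_hap)


def simulate_counts(
    genotype: Genotype,
    config: SimulatorConfig,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> CountProfile:
    """Draw one sample's per-bin raw counts and TPM profile."""
    if rng is None:
        rng = config.rng()
    mu, _ = _expected_track(genotype, config, rng)
    raw = _draw_counts(mu, config.dispersion, rng)
    return CountProfile.from_raw(sample_id, raw, config.bins)


def simulate_fragments(
    genotype: Genotype,
    config: SimulatorConfig,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Draw a sample as individual fragments instead of bin counts.

    Per-bin fragment numbers come from the same negative-binomial model as
    :func:`simulate_counts`; midpoints are uniform within their bin and
    lengths Normal(mean, sd) truncated to [50, 500] bp, so piping the result
    through fragment counting is statistically consistent with the direct
    count route.
    """
    if rng is None:
        rng = config.rng()
    mu, _ = _expected_track(genotype, config, rng)
    per_bin = _draw_counts(mu, config.dispersion, rng)
    frags: list[Fragment] = []
    for i, n in enumerate(per_bin):
        if n == 0:
            continue
        mids = rng.uniform(config.bins.starts[i], config.bins.ends[i], size=n)
        lengths = np.clip(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n),
            50,
            500,
        )
        starts = np.maximum(0, np.round(mids - lengths / 2)).astype(np.int64)
        ends = np.round(mids + lengths / 2).astype(np.int64)
        ends = np.maximum(ends, starts + 1)
        frags.extend(
            Fragment(config.bins.chrom, int(s), int(e)) for s, e in zip(starts, ends)
        )
    return frags


@dataclass
class CohortSpec:
    """Class mix for a simulated cohort.

    Give either explicit per-genotype ``counts`` or population
    ``frequencies`` plus ``n_samples``.  Genotype keys are ``"hap1/hap2"``
    strings.
    """

    counts: Mapping[str, int] | None = None
    frequencies: Mapping[str, float] | None = None
    n_samples: int | None = None

    @classmethod
    def study_population(cls, n_samples: int) -> "CohortSpec":
        total = sum(STUDY_GENOTYPE_COUNTS.values())
        return cls(
            frequencies={g: n / total for g, n in STUDY_GENOTYPE_COUNTS.items()},
            n_samples=n_samples,
        )

    def resolve(self, rng: np.random.Generator) -> list[Genotype]:
        if self.counts is not None:
            genotypes = [
                Genotype.from_string(g)
                for g, n in self.counts.items()
                for _ in range(int(n))
            ]
        elif self.frequencies is not None:
            if self.n_samples is None:
                raise ValueError("n_samples required with frequencies")
            names = list(self.frequencies)
            freqs = np.array([self.frequencies[g] for g in names], dtype=float)
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"genotype frequencies sum to {freqs.sum():.6f}, not 1"
                )
            draws = rng.choice(len(names), size=self.n_samples, p=freqs)
            genotypes = [Genotype.from_string(names[i]) for i in draws]
        else:
            raise ValueError("CohortSpec needs counts or frequencies")
        return genotypes


def simulate_cohort(
    spec: CohortSpec, config: SimulatorConfig
) -> tuple[list[CountProfile], list[str], list[Genotype]]:
    """Simulate a cohort; returns (profiles, class labels, true genotypes)."""
    rng = config.rng()
    genotypes = spec.resolve(rng)
    profiles = [
        simulate_counts(g, config, sample_id=f"S{i:06d}", rng=rng)
        for i, g in enumerate(genotypes)
    ]
    labels = [g.label for g in genotypes]
    return profiles, labels, genotypes
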