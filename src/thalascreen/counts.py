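"""Fragment counting over bins and TPM normalization.

A cfDNA fragment is the outer span of a properly paired read pair.  Each
fragment that overlaps at least one bin increments exactly one bin — the bin
with the largest overlap, ties broken toward the leftmost — mirroring
unique-assignment feature counting.  Raw per-bin counts are then normalized
transcripts-per-million style: each bin's count is divided by its length in
kb to give a rate, and the rates are rescaled so they sum to 10^6.  The
normalization removes library-size differences between samples while keeping
the relative depth signature of a deletion intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import BinSet

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "CountProfile",
    "count_fragments",
    "tpm_normalize",
    "read_fragments_bed",
    "read_count_table",
    "write_count_table",
]

TPM_SCALE = 1e6


@dataclass(frozen=True)
class Fragment:
    """One sequenced cfDNA fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")


@dataclass
class CountProfile:
    """One sample's per-bin raw counts and TPM values."""

    sample_id: str
    raw: np.ndarray
    tpm: np.ndarray

    @property
    def total_fragments(self) -> int:
        return int(self.raw.sum())

    @classmethod
    def from_raw(cls, sample_id: str, raw, bins: BinSet) -> "CountProfile":
        raw = np.asarray(raw, dtype=np.int64)
        if raw.shape != (len(bins),):
            raise ValueError(
                f"raw vector has {raw.shape[0]} entries but BinSet has "
                f"{len(bins)} bins"
            )
        return cls(sample_id, raw, tpm_normalize(raw, bins.lengths))


def count_fragments(
    fragments: Iterable[Fragment], bins: BinSet
) -> np.ndarray:
    """Count fragments into bins with unique largest-overlap assignment.

    Fragments on other chromosomes are skipped (logged); fragments touching
    no bin are ignored.  The sum of counts never exceeds the number of
    fragments.
    """
    if len(bins) == 0:
        raise ValueError("empty BinSet")
    frags = list(fragments)
    skipped = sum(1 for f in frags if f.chrom != bins.chrom)
    if skipped:
        logger.info("skipped %d fragments on other chromosomes", skipped)
    starts = np.array(
        [f.start for f in frags if f.chrom == bins.chrom], dtype=np.int64
    )
    ends = np.array(
        [f.end for f in frags if f.chrom == bins.chrom], dtype=np.int64
    )
    counts = np.zeros(len(bins), dtype=np.int64)
    if starts.size == 0:
        return counts

    # Bins are sorted and non-overlapping: the bins a fragment can touch are
    # the contiguous index range [lo, hi).
    lo = np.searchsorted(bins.ends, starts, side="right")
    hi = np.searchsorted(bins.starts, ends, side="left")
    touching = hi > lo
    starts, ends, lo, hi = starts[touching], ends[touching], lo[touching], hi[touching]
    if starts.size == 0:
        return counts

    best_idx = lo.copy()
    best_ov = np.zeros(starts.size, dtype=np.int64)
    for offset in range(int((hi - lo).max())):
        idx = lo + offset
        active = idx < hi
        ov = np.zeros(starts.size, dtype=np.int64)
        ov[active] = np.minimum(ends[active], bins.ends[idx[active]]) - np.maximum(
            starts[active], bins.starts[idx[active]]
        )
        # strict > keeps the leftmost bin on ties
        better = ov > best_ov
        best_ov[better] = ov[better]
        best_idx[better] = idx[better]
    has_overlap = best_ov > 0
    np.add.at(counts, best_idx[has_overlap], 1)
    return counts


def tpm_normalize(raw, lengths) -> np.ndarray:
    """Normalize raw counts by bin length and library size to sum to 1e6.

    rate_i = raw_i * 1e3 / length_i; tpm_i = rate_i / sum(rate) * 1e6.
    """
    raw = np.asarray(raw, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if raw.shape != lengths.shape:
        raise ValueError("raw and lengths must have matching shapes")
    if np.any(lengths <= 0):
        raise ValueError("zero-length bin")
    total = raw.sum()
    if total <= 0:
        raise ValueError("no coverage: all-zero raw count vector")
    rate = raw * 1e3 / lengths
    return rate / rate.sum() * TPM_SCALE


def read_fragments_bed(path) -> list[Fragment]:
    """Read fragment spans from a BED3(+) file."""
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 fields"
                )
            frags.append(Fragment(fields[0], int(fields[1]), int(fields[2])))
    return frags


def write_count_table(
    profiles: Sequence[CountProfile], path, bins: BinSet, kind: str = "raw"
) -> None:
    """Write profiles as a TSV: sample_id column then one column per bin."""
    if kind not in ("raw", "tpm"):
        raise ValueError(f"kind must be 'raw' or 'tpm', got {kind!r}")
    columns = [f"bin_{i:03d}" for i in range(len(bins))]
    data = np.stack([getattr(p, kind) for p in profiles]) if profiles else np.empty((0, len(bins)))
    df = pd.DataFrame(data, columns=columns)
    df.insert(0, "sample_id", [p.sample_id for p in profiles])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g" if kind == "tpm" else None)


def read_count_table(path, bins: BinSet, kind: str = "raw") -> list[CountProfile]:
    """Read a count TSV back into profiles; validates shape and uniqueness."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    n_cols = df.shape[1] - 1
    if n_cols != len(bins):
        raise ValueError(
            f"{path}: table has {n_cols} bin columns but BinSet has "
            f"{len(bins)} bins"
        )
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated sample_id values: {dupes}")
    mat = df.drop(columns="sample_id").to_numpy()
    profiles = []
    for sid, row in zip(df["sample_id"], mat):
        if kind == "raw":
            profiles.append(CountProfile.from_raw(str(sid), row, bins))
        else:
            profiles.append(
                CountProfile(str(sid), np.zeros(len(bins), dtype=np.int64), row)
            )
    return profiles
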