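"""Alignment, 5'-end counting and the per-position occupancy table.

The 5' end of a NET-seq read marks the 3' end of the originating nascent
transcript, i.e. the polymerase position.  Occupancy is therefore the
per-position tally of read 5' ends: for a plus-strand alignment the 5' end
is the leftmost coordinate, for a minus-strand alignment the rightmost.
Counts from the two identical genomic copies of the unit are summed into a
single transcription-direction coordinate system, and normalised by the
plus-strand total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import ReadRecord
from .simulate import TemplateLocus, reverse_complement

#: Column order of the per-position occupancy table.
TRACK_COLUMNS = [
    "coordinate",
    "nucleotide",
    "region",
    "region_type",
    "strain",
    "replicate",
    "count_plus",
    "count_minus",
    "normalized",
]


@dataclass(frozen=True)
class AlignedInterval:
    """A BED-style aligned interval: 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def align_exact(
    reads: Sequence[ReadRecord], locus: TemplateLocus
) -> tuple[list[AlignedInterval], int]:
    """Exact-substring alignment of preprocessed inserts to the toy genome.

    Each insert is searched on the plus strand and, as its reverse
    complement, on the minus strand.  A read matching at several places
    (notably once per identical unit copy) contributes one interval per
    match; the copy-combination step later sums them.  Reads with no match
    are dropped and counted.

    Returns the intervals and the number of unmatched reads.
    """
    genome = locus.genome_sequence
    cache: dict[str, list[AlignedInterval]] = {}
    intervals: list[AlignedInterval] = []
    n_unmatched = 0
    for read in reads:
        seq = read.sequence
        hit = cache.get(seq)
        if hit is None:
            hit = [
                AlignedInterval(locus.chrom, p, p + len(seq), "+")
                for p in _find_all(genome, seq)
            ]
            rc = reverse_complement(seq) if set(seq) <= set("ACGT") else None
            if rc is not None:
                hit += [
                    AlignedInterval(locus.chrom, p, p + len(seq), "-")
                    for p in _find_all(genome, rc)
                ]
            cache[seq] = hit
        if hit:
            intervals.extend(hit)
        else:
            n_unmatched += 1
    return intervals, n_unmatched


def count_5prime_ends(
    intervals: Iterable[AlignedInterval], genome_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position read 5'-end counts, split by strand.

    Returns two integer vectors of length ``genome_length`` whose index
    ``i`` holds the count at 1-based genomic position ``i + 1``.  A
    plus-strand interval contributes at its start (position ``start + 1``),
    a minus-strand interval at its end (position ``end``) — the 5' end of
    the aligned read in both cases.
    """
    plus_idx: list[int] = []
    minus_idx: list[int] = []
    for iv in intervals:
        if iv.end > genome_length:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds for genome "
                f"length {genome_length}"
            )
        if iv.strand == "+":
            plus_idx.append(iv.start)
        else:
            minus_idx.append(iv.end - 1)
    plus = np.bincount(np.asarray(plus_idx, dtype=int), minlength=genome_length)
    minus = np.bincount(np.asarray(minus_idx, dtype=int), minlength=genome_length)
    return plus.astype(np.int64), minus.astype(np.int64)


def build_track(
    plus_counts: np.ndarray,
    minus_counts: np.ndarray,
    locus: TemplateLocus,
    strain: str,
    replicate: str | int,
) -> pd.DataFrame:
    """Assemble the per-position occupancy table in transcription coordinates.

    Counts at the genomic positions of the two unit copies are summed per
    coordinate.  Columns: coordinate (1-based, ascending in transcription
    direction), nucleotide (sense strand), region, region_type, strain,
    replicate, count_plus, count_minus, normalized (NaN until
    :func:`normalize_track`).
    """
    n = locus.unit_length
    if len(plus_counts) != len(locus.genome_sequence) or len(minus_counts) != len(
        locus.genome_sequence
    ):
        raise ValueError("count vectors must cover the whole genome")
    idx1 = locus.genomic_indices(0)
    idx2 = locus.genomic_indices(1)
    plus = np.asarray(plus_counts)
    minus = np.asarray(minus_counts)
    return pd.DataFrame(
        {
            "coordinate": np.arange(1, n + 1),
            "nucleotide": list(locus.unit_sequence),
            "region": locus.region_labels(),
            "region_type": locus.region_type_labels(),
            "strain": strain,
            "replicate": replicate,
            "count_plus": plus[idx1] + plus[idx2],
            "count_minus": minus[idx1] + minus[idx2],
            "normalized": np.nan,
        }
    )


def normalize_track(track: pd.DataFrame) -> pd.DataFrame:
    """Divide each plus-strand count by the plus-strand total.

    The normalised column sums to 1.  Minus-strand counts are retained for
    QC but are never normalised.  A track with zero plus-strand total has
    no defined occupancy distribution and is rejected.
    """
    total = track["count_plus"].sum()
    if total <= 0:
        raise ValueError("cannot normalize a track with zero plus-strand total")
    out = track.copy()
    out["normalized"] = track["count_plus"] / total
    return out


def track_from_reads(
    reads: Sequence[ReadRecord],
    locus: TemplateLocus,
    strain: str,
    replicate: str | int,
) -> pd.DataFrame:
    """Align preprocessed reads and build a normalised occupancy track."""
    intervals, _ = align_exact(reads, locus)
    plus, minus = count_5prime_ends(intervals, len(locus.genome_sequence))
    return normalize_track(build_track(plus, minus, locus, strain, replicate))
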