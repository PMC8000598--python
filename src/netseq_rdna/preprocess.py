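"""Read preprocessing for the NET-seq library format.

Libraries carry a fixed 5' structure ``AG + 8-nt UMI + TG`` followed by the
insert (the cDNA of the nascent-transcript 3' end) and, usually, the 3'
linker ``CTGTAGGCACCAT`` plus whatever the sequencer read past it.
Preprocessing is three steps, applied in order:

1. :func:`deduplicate` — collapse exact PCR duplicates.  Because the UMI is
   embedded in the read, identical full sequence implies identical UMI and
   identical fragment, so full-sequence collapse implements UMI-based
   deduplication.
2. :func:`filter_on_target` — keep reads matching the 5' library format,
   record the UMI and strip the 12-nt prefix.  Matching is anchored and
   exact (no mismatches, no indels).
3. :func:`trim_linker` — truncate at the first occurrence of the 3' linker;
   reads whose insert becomes empty are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

#: 3' linker ligated to the nascent-transcript 3' end before circularisation.
LINKER_3P = "CTGTAGGCACCAT"

#: Length of the fixed 5' library prefix (AG + 8-nt UMI + TG).
PREFIX_LENGTH = 12

#: Length of the embedded unique molecular identifier.
UMI_LENGTH = 8


@dataclass
class ReadRecord:
    """A sequencing read before/after preprocessing.

    The ``umi`` field is populated only once :func:`filter_on_target` has
    recognised the 5' library format and removed the prefix.
    """

    read_id: str
    sequence: str
    qualities: str | None = None
    umi: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.sequence)}"
            )


@dataclass
class PreprocessStats:
    """Bookkeeping for the three preprocessing steps.

    Invariant: ``n_on_target + n_discarded_format == n_after_dedup``.
    """

    n_input: int = 0
    n_after_dedup: int = 0
    n_on_target: int = 0
    n_discarded_format: int = 0
    n_linker_trimmed: int = 0
    n_empty_after_trim: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_on_target": self.n_on_target,
            "n_discarded_format": self.n_discarded_format,
            "n_linker_trimmed": self.n_linker_trimmed,
            "n_empty_after_trim": self.n_empty_after_trim,
        }


def deduplicate(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], PreprocessStats]:
    """Collapse exact duplicate reads, keeping the first occurrence.

    PCR duplicates are verbatim copies of the ligated molecule, UMI
    included, so two reads are duplicates iff their full sequences are
    identical.  Input order is otherwise preserved.
    """
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    for read in reads:
        if read.sequence not in seen:
            seen.add(read.sequence)
            kept.append(read)
    stats = PreprocessStats(n_input=len(reads), n_after_dedup=len(kept))
    return kept, stats


def is_on_target(sequence: str) -> bool:
    """True iff the read starts with the AG + NNNNNNNN + TG library prefix
    and retains at least one insert nucleotide after prefix removal."""
    return (
        len(sequence) > PREFIX_LENGTH
        and sequence[0:2] == "AG"
        and sequence[10:12] == "TG"
    )


def filter_on_target(
    reads: Sequence[ReadRecord],
) -> tuple[list[ReadRecord], PreprocessStats]:
    """Keep reads with the 5' library format; capture the UMI, drop the prefix.

    A read is on target iff it is at least 13 nt long, starts with ``AG``
    and has ``TG`` at positions 11-12 (1-based).  Positions 3-10 become the
    UMI and the first 12 nt are removed.  All other reads are discarded and
    counted.
    """
    kept: list[ReadRecord] = []
    n_discarded = 0
    for read in reads:
        seq = read.sequence
        if is_on_target(seq):
            kept.append(
                ReadRecord(
                    read.read_id,
                    seq[PREFIX_LENGTH:],
                    read.qualities[PREFIX_LENGTH:] if read.qualities else None,
                    seq[2 : 2 + UMI_LENGTH],
                )
            )
        else:
            n_discarded = n_discarded + 1
    stats = PreprocessStats(
        n_input=len(reads),
        n_after_dedup=len(reads),
        n_on_target=len(kept),
        n_discarded_format=n_discarded,
    )
    return kept, stats


def trim_linker(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], PreprocessStats]:
    """Truncate each read at the first occurrence of the 3' linker.

    Everything from the linker onward is removed.  Reads without the linker
    pass unchanged; reads whose insert becomes empty are discarded.
    """
    kept: list[ReadRecord] = []
    n_trimmed = 0
    n_empty = 0
    for read in reads:
        idx = read.sequence.find(LINKER_3P)
        if idx == -1:
            kept.append(read)
            continue
        n_trimmed += 1
        if idx == 0:
            n_empty += 1
            continue
        kept.append(
            ReadRecord(
                read.read_id,
                read.sequence[:idx],
                read.qualities[:idx] if read.qualities else None,
                read.umi,
            )
        )
    stats = PreprocessStats(
        n_input=len(reads),
        n_linker_trimmed=n_trimmed,
        n_empty_after_trim=n_empty,
    )
    return kept, stats


def preprocess_reads(
    reads: Sequence[ReadRecord],
) -> tuple[list[ReadRecord], PreprocessStats]:
    """Run deduplication, format filtering and linker trimming in order."""
    deduped, s1 = deduplicate(reads)
    on_target, s2 = filter_on_target(deduped)
    trimmed, s3 = trim_linker(on_target)
    return trimmed, PreprocessStats(
        n_input=s1.n_input,
        n_after_dedup=s1.n_after_dedup,
        n_on_target=s2.n_on_target,
        n_discarded_format=s2.n_discarded_format,
        n_linker_trimmed=s3.n_linker_trimmed,
        n_empty_after_trim=s3.n_empty_after_trim,
    )
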