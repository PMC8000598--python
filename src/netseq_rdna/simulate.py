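"""Synthetic rDNA locus and NET-seq library generator with known ground truth.

The generator emulates a yeast-like situation: a single polymerase-I
transcription unit (ETS1, 18S, ITS1, 5.8S, ITS2, 25S, ETS2 in transcription
order) present as two identical genomic copies, transcribed by polymerases
that may terminate prematurely (processivity) and dwell longer ahead of
G-rich template (sequence-dependent pausing).

Model
-----
The last incorporated nucleotide (LNT) of a captured nascent transcript is
drawn from a per-position distribution over transcription-direction
coordinates ``x`` (1-based)::

    w(x) ∝ (1 - delta)**x * exp(beta * g(x))

where ``delta`` is the per-nucleotide premature-termination probability (a
polymerase reaches position x only if it has survived x steps), ``g(x)`` is
the G fraction of the 10 template (sense-strand) positions downstream of x,
and ``beta`` couples dwell time to downstream G content.  Weights are
normalised to a probability distribution over eligible positions.  Positions
within one maximal fragment length of the unit's 5' edge are ineligible
(no partial fragments).

Geometry
--------
The transcription unit runs right-to-left on the genomic plus strand
(``gene_strand == '-'``): a nascent transcript ending at LNT ``x`` covers
unit coordinates ``x-L+1 .. x``, whose plus-strand projection is the genomic
interval ``[pos(x), pos(x)+L)`` with ``pos(x) = copy_start + unit_length - x``.
On-target inserts therefore align to the plus strand with leftmost
coordinate equal to the LNT position, so counting plus-strand 5' read ends
directly reads out polymerase positions.

Each on-target read is ``AG + UMI(8) + TG + insert`` with, usually, the 3'
linker and a short random tail appended.  PCR duplicates are verbatim
copies of earlier reads; off-target reads lack the 5' library format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import LINKER_3P, ReadRecord, is_on_target

#: The seven annotated regions of the 35S transcription unit, in
#: transcription order.
REGION_NAMES = ("ETS1", "18S", "ITS1", "5.8S", "ITS2", "25S", "ETS2")

#: Spacers are transcribed but removed during rRNA processing; genes are the
#: mature rRNA species.
REGION_TYPES = {
    "ETS1": "spacer",
    "18S": "gene",
    "ITS1": "spacer",
    "5.8S": "gene",
    "ITS2": "spacer",
    "25S": "gene",
    "ETS2": "spacer",
}

#: Default toy region lengths (sum = 900), scaled down from the ~6.9 kb unit.
DEFAULT_REGION_LENGTHS = (100, 180, 80, 60, 80, 340, 60)

#: Number of downstream template positions over which G content modulates
#: the pause weight.
PAUSE_G_WINDOW = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@dataclass
class TemplateLocus:
    """Toy genome with two identical, annotated copies of the 35S unit.

    ``genome_sequence`` is the plus strand.  ``copy_spans`` are 0-based
    half-open genomic intervals of the two copies; both have length
    ``unit_length`` (the sum of ``region_bounds``) and identical sequence.
    Transcription-direction coordinates are 1-based, starting at the ETS1
    end; for the default minus-strand geometry coordinate ``x`` of copy
    ``c`` lies at genomic position ``copy_start_c + unit_length - x``.
    """

    genome_sequence: str
    copy_spans: tuple[tuple[int, int], tuple[int, int]]
    region_bounds: tuple[int, ...]
    gene_strand: str = "-"
    chrom: str = "rDNA_toy"

    def __post_init__(self) -> None:
        if set(self.genome_sequence) - set("ACGT"):
            bad = sorted(set(self.genome_sequence) - set("ACGT"))
            raise ValueError(f"genome sequence contains non-ACGT characters: {bad}")
        if len(self.region_bounds) != len(REGION_NAMES):
            raise ValueError(
                f"expected {len(REGION_NAMES)} region lengths, got "
                f"{len(self.region_bounds)}"
            )
        for name, length in zip(REGION_NAMES, self.region_bounds):
            if length <= 0:
                raise ValueError(f"region {name} has non-positive length {length}")
        if self.gene_strand not in "+-":
            raise ValueError(f"gene_strand must be '+' or '-', got {self.gene_strand!r}")
        (s1, e1), (s2, e2) = self.copy_spans
        unit = self.unit_length
        for s, e in self.copy_spans:
            if not (0 <= s < e <= len(self.genome_sequence)):
                raise ValueError(f"copy span ({s}, {e}) out of genome bounds")
            if e - s != unit:
                raise ValueError(
                    f"copy span ({s}, {e}) length {e - s} != unit length {unit}"
                )
        if max(s1, s2) < min(e1, e2):
            raise ValueError("copy spans overlap")
        if self.genome_sequence[s1:e1] != self.genome_sequence[s2:e2]:
            raise ValueError("the two unit copies have different sequences")

    @property
    def unit_length(self) -> int:
        return int(sum(self.region_bounds))

    @property
    def unit_sequence(self) -> str:
        """Sense-strand (nascent-RNA-like) sequence of the unit, indexed by
        transcription-direction coordinate (position x at index x-1)."""
        s, e = self.copy_spans[0]
        copy = self.genome_sequence[s:e]
        return reverse_complement(copy) if self.gene_strand == "-" else copy

    def genomic_indices(self, copy: int) -> np.ndarray:
        """0-based genomic positions of unit coordinates 1..unit_length for
        one copy, in transcription order."""
        s, e = self.copy_spans[copy]
        coords = np.arange(1, self.unit_length + 1)
        if self.gene_strand == "-":
            return s + self.unit_length - coords
        return s + coords - 1

    def region_labels(self) -> np.ndarray:
        """Region name per unit coordinate, transcription order."""
        return np.repeat(np.array(REGION_NAMES, dtype=object), self.region_bounds)

    def region_type_labels(self) -> np.ndarray:
        labels = self.region_labels()
        return np.array([REGION_TYPES[r] for r in labels], dtype=object)


def generate_template(
    region_lengths: Sequence[int] = DEFAULT_REGION_LENGTHS,
    seed: int = 0,
    *,
    flank_length: int = 150,
    spacer_length: int = 120,
    chrom: str = "rDNA_toy",
) -> TemplateLocus:
    """Generate a random toy genome with two identical annotated 35S copies.

    The unit sequence, flanks and inter-copy spacer are drawn uniformly over
    ACGT; the two copies are byte-identical.  Deterministic for a fixed
    seed.  Region lengths must be positive; short regions are allowed but a
    unit shorter than twice the logo flank leaves no window-eligible
    positions downstream.
    """
    region_lengths = tuple(int(x) for x in region_lengths)
    if len(region_lengths) != len(REGION_NAMES):
        raise ValueError(
            f"expected {len(REGION_NAMES)} region lengths, got {len(region_lengths)}"
        )
    for name, length in zip(REGION_NAMES, region_lengths):
        if length <= 0:
            raise ValueError(f"region {name} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    unit_len = sum(region_lengths)
    unit_plus = _random_dna(rng, unit_len)
    flank5 = _random_dna(rng, flank_length)
    spacer = _random_dna(rng, spacer_length)
    flank3 = _random_dna(rng, flank_length)
    genome = flank5 + unit_plus + spacer + unit_plus + flank3
    start1 = flank_length
    start2 = flank_length + unit_len + spacer_length
    return TemplateLocus(
        genome_sequence=genome,
        copy_spans=((start1, start1 + unit_len), (start2, start2 + unit_len)),
        region_bounds=region_lengths,
        gene_strand="-",
        chrom=chrom,
    )


@dataclass(frozen=True)
class StrainParams:
    """Per-strain generative parameters.

    termination_prob
        Per-nucleotide premature-termination probability ``delta`` in [0, 1).
        A processivity defect is a larger ``delta``.
    pause_gc_weight
        Coefficient ``beta`` coupling the dwell weight at a position to the
        G fraction of the 10 downstream template positions.
    duplicate_rate
        Probability that an emitted read is a verbatim PCR copy of an
        earlier read rather than a fresh molecule.
    offtarget_frac
        Fraction of fresh reads lacking the 5' library format.
    fragment_length_range
        Inclusive (min, max) insert length in nucleotides.
    linker_prob
        Probability that the 3' linker (plus a short random tail) was read
        through at the 3' end of an on-target read.
    max_tail_length
        Maximal random tail length after the linker.
    """

    termination_prob: float = 0.0005
    pause_gc_weight: float = 0.0
    duplicate_rate: float = 0.1
    offtarget_frac: float = 0.05
    fragment_length_range: tuple[int, int] = (20, 40)
    linker_prob: float = 0.9
    max_tail_length: int = 6

    def __post_init__(self) -> None:
        if not 0.0 <= self.termination_prob < 1.0:
            raise ValueError(f"termination_prob must be in [0, 1): {self.termination_prob}")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError(f"duplicate_rate must be in [0, 1): {self.duplicate_rate}")
        if not 0.0 <= self.offtarget_frac <= 1.0:
            raise ValueError(f"offtarget_frac must be in [0, 1]: {self.offtarget_frac}")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid fragment_length_range {self.fragment_length_range}")
        if not 0.0 <= self.linker_prob <= 1.0:
            raise ValueError(f"linker_prob must be in [0, 1]: {self.linker_prob}")


#: Wild-type defaults: high processivity, no sequence-dependent pausing term.
WT_PARAMS = StrainParams(termination_prob=0.0005, pause_gc_weight=0.0)

#: spt4-deletion-like defaults: five-fold elevated premature termination and
#: pausing coupled to downstream G content.
SPT4D_PARAMS = StrainParams(termination_prob=0.0025, pause_gc_weight=2.0)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated library.

    ``probabilities[x-1]`` is the sampling probability of LNT position
    ``x`` (zero for ineligible positions); ``lnt_positions`` records the
    LNT of every freshly generated on-target read, in emission order.
    """

    probabilities: np.ndarray
    lnt_positions: np.ndarray
    seed: int
    n_offtarget: int = 0
    n_duplicates: int = 0


def downstream_g_fraction(locus: TemplateLocus, window: int = PAUSE_G_WINDOW) -> np.ndarray:
    """G fraction of the ``window`` sense-strand positions downstream of
    each unit coordinate (truncated at the unit's 3' end)."""
    is_g = np.frombuffer(locus.unit_sequence.encode(), dtype=np.uint8) == ord("G")
    csum = np.concatenate([[0], np.cumsum(is_g)])
    n = locus.unit_length
    coords = np.arange(1, n + 1)
    hi = np.minimum(coords + window, n)
    counts = csum[hi] - csum[coords]
    widths = np.maximum(hi - coords, 1)
    return counts / widths


def occupancy_probabilities(locus: TemplateLocus, params: StrainParams) -> np.ndarray:
    """Normalised per-position LNT sampling probabilities for one strain.

    Positions closer than the maximal fragment length to the unit's 5' edge
    are ineligible and receive probability zero.
    """
    n = locus.unit_length
    _, frag_max = params.fragment_length_range
    if frag_max > n:
        raise ValueError(
            f"fragment length range {params.fragment_length_range} exceeds "
            f"unit length {n}"
        )
    coords = np.arange(1, n + 1, dtype=float)
    log_w = coords * np.log1p(-params.termination_prob)
    if params.pause_gc_weight != 0.0:
        log_w = log_w + params.pause_gc_weight * downstream_g_fraction(locus)
    weights = np.exp(log_w - log_w.max())
    weights[: frag_max - 1] = 0.0  # coords < frag_max: fragment would overrun the 5' edge
    total = weights.sum()
    if total <= 0:
        raise ValueError("no eligible LNT positions")
    return weights / total


def simulate_reads(
    locus: TemplateLocus,
    params: StrainParams,
    n_reads: int,
    seed: int,
) -> tuple[list[ReadRecord], SimulationTruth]:
    """Emit ``n_reads`` library-format reads plus the sampling ground truth.

    Deterministic for a fixed seed.  Reads are a mixture of fresh on-target
    molecules (LNT sampled from :func:`occupancy_probabilities`), fresh
    off-target molecules (random sequence failing the 5' format), and PCR
    duplicates (verbatim copies of a uniformly chosen earlier read).
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    probs = occupancy_probabilities(locus, params)
    rng = np.random.default_rng(seed)
    frag_lo, frag_hi = params.fragment_length_range

    u_dup = rng.random(n_reads)
    u_off = rng.random(n_reads)
    u_link = rng.random(n_reads)
    positions = rng.choice(locus.unit_length, size=n_reads, p=probs) + 1
    lengths = rng.integers(frag_lo, frag_hi + 1, size=n_reads)
    dup_sources = rng.integers(0, np.maximum(np.arange(n_reads), 1))
    tail_lens = rng.integers(0, params.max_tail_length + 1, size=n_reads)
    # one pooled random-base string sliced for UMIs, tails and off-target reads
    pool_len = n_reads * (8 + params.max_tail_length + 12) + n_reads * frag_hi
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    pool = lut[rng.integers(0, 4, size=pool_len, dtype=np.uint8)].tobytes().decode()
    pool_at = 0

    genome = locus.genome_sequence
    copy_start = locus.copy_spans[0][0]
    unit_len = locus.unit_length
    dup_rate = params.duplicate_rate
    off_frac = params.offtarget_frac
    link_prob = params.linker_prob

    reads: list[ReadRecord] = []
    lnts: list[int] = []
    n_off = 0
    n_dup = 0
    for i in range(n_reads):
        if i > 0 and u_dup[i] < dup_rate:
            seq = reads[dup_sources[i]].sequence
            n_dup += 1
        elif u_off[i] < off_frac:
            length = 12 + int(lengths[i])
            seq = pool[pool_at : pool_at + length]
            pool_at += length
            if is_on_target(seq):
                # break the AG...TG pattern so the read fails the format filter
                seq = "TT" + seq[2:]
            n_off += 1
        else:
            x = int(positions[i])
            frag = int(lengths[i])
            left = copy_start + unit_len - x
            umi = pool[pool_at : pool_at + 8]
            pool_at += 8
            seq = "AG" + umi + "TG" + genome[left : left + frag]
            if u_link[i] < link_prob:
                tail = int(tail_lens[i])
                seq = seq + LINKER_3P + pool[pool_at : pool_at + tail]
                pool_at += tail
            lnts.append(x)
        reads.append(ReadRecord(f"read{i:07d}", seq, qualities=None))

    truth = SimulationTruth(
        probabilities=probs,
        lnt_positions=np.asarray(lnts, dtype=int),
        seed=seed,
        n_offtarget=n_off,
        n_duplicates=n_dup,
    )
    return reads, truth
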