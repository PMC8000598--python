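"""Pause-site calling, sequence windows and the permutation difference logo.

Pause sites are the top-quantile occupied positions of a strain's median
track.  Around each site a sense-strand window of 2*flank nucleotides is
extracted, spanning labels -flank..-1 (ending at the last incorporated
nucleotide, LNT, at label -1) and +1..+flank (downstream template).  Base
frequencies per column give a position matrix per strain; the difference
logo scores each column by the Jensen–Shannon divergence (base 2, so in
bits) between the two strains' base distributions, partitions that height
into signed per-base contributions (positive = overrepresented in the
mutant), and attaches a permutation p-value for the null hypothesis that
the two columns' bases come from the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import TemplateLocus

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PauseSiteSet:
    """Top-quantile occupied positions for one strain.

    All members have median normalised occupancy >= ``quantile_threshold``;
    ties at the threshold are all included, so the set may slightly exceed
    the nominal fraction of eligible positions.
    """

    coordinates: np.ndarray
    quantile_threshold: float
    strain: str = ""


@dataclass
class SequenceWindowSet:
    """Equal-length sense-strand windows around pause sites.

    Column labels run -flank..-1, +1..+flank (no label 0); the LNT is at
    label -1, i.e. 0-based column index ``flank - 1``.
    """

    windows: list[str]
    flank: int

    def __post_init__(self) -> None:
        width = 2 * self.flank
        for w in self.windows:
            if len(w) != width:
                raise ValueError(
                    f"window length {len(w)} != 2*flank = {width}: {w!r}"
                )

    @property
    def labels(self) -> np.ndarray:
        f = self.flank
        return np.concatenate([np.arange(-f, 0), np.arange(1, f + 1)])


@dataclass
class PositionMatrix:
    """Per-column base counts and probabilities over aligned windows.

    ``counts`` and ``probabilities`` are (4, width) arrays in ACGT order;
    count columns sum to ``n_sequences``, probability columns to 1.  No
    pseudocounts: probabilities are maximum-likelihood estimates.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    n_sequences: int

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class DiffLogoResult:
    """Column-wise difference statistics between two position matrices.

    ``heights`` are Jensen–Shannon divergences in bits; ``contributions``
    is a (4, width) signed partition of each height (positive toward the
    second, "mutant", matrix); ``p_values`` come from label permutations
    with a +1/(n+1) correction; ``significant`` flags p < alpha.
    """

    heights: np.ndarray
    contributions: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    labels: np.ndarray | None = None
    alpha: float = 0.05


def call_pause_sites(
    median_values,
    top_fraction: float = 0.025,
    flank: int = 30,
    strain: str = "",
) -> PauseSiteSet:
    """Positions in the top ``top_fraction`` of occupancy, window-eligible.

    Positions too close to the unit edges for a full +-flank window are
    excluded before the quantile is computed.  The threshold is the
    (1 - top_fraction) quantile of the eligible values; every position at
    or above it is returned (ties included).
    """
    values = np.asarray(median_values, dtype=float)
    n = values.size
    if not 0.0 < top_fraction < 1.0:
        raise ValueError(f"top_fraction must be in (0, 1): {top_fraction}")
    if n < 2 * flank:
        raise ValueError(f"track length {n} shorter than 2*flank = {2 * flank}")
    coords = np.arange(flank, n - flank + 1)  # 1-based, full window available
    eligible = values[coords - 1]
    threshold = float(np.quantile(eligible, 1.0 - top_fraction))
    sites = coords[eligible >= threshold]
    return PauseSiteSet(
        coordinates=sites, quantile_threshold=threshold, strain=strain
    )


def extract_windows(
    sites: PauseSiteSet,
    locus: TemplateLocus | str,
    flank: int = 30,
) -> SequenceWindowSet:
    """Sense-strand windows of labels -flank..+flank around each pause site.

    For an LNT at unit position ``p`` the window covers unit positions
    ``p - flank + 1 .. p + flank`` (the LNT at label -1).  ``locus`` may be
    a :class:`TemplateLocus` or a plain sense-strand sequence.  Windows are
    returned in ascending coordinate order.
    """
    sense = locus.unit_sequence if isinstance(locus, TemplateLocus) else str(locus)
    n = len(sense)
    windows = []
    for p in np.sort(np.asarray(sites.coordinates, dtype=int)):
        lo = p - flank  # 0-based start of label -flank
        hi = p + flank  # 0-based end (exclusive) of label +flank
        if lo < 0 or hi > n:
            raise ValueError(
                f"site {p} too close to the unit edge for flank {flank}"
            )
        windows.append(sense[lo:hi])
    return SequenceWindowSet(windows=windows, flank=flank)


def build_matrix(windows: SequenceWindowSet | Sequence[str]) -> PositionMatrix:
    """Per-column base counts and ML probabilities over aligned windows."""
    seqs = windows.windows if isinstance(windows, SequenceWindowSet) else list(windows)
    if not seqs:
        raise ValueError("need at least one window")
    width = len(seqs[0])
    counts = np.zeros((4, width), dtype=np.int64)
    for k, seq in enumerate(seqs):
        if len(seq) != width:
            raise ValueError(f"window {k} has length {len(seq)}, expected {width}")
        for j, base in enumerate(seq):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                raise ValueError(
                    f"window {k} ({seq!r}) contains non-ACGT character {base!r}"
                )
            counts[idx, j] += 1
    return PositionMatrix(
        counts=counts,
        probabilities=counts / len(seqs),
        n_sequences=len(seqs),
    )


def jensen_shannon_bits(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Jensen–Shannon divergence in bits between probability columns.

    Accepts vectors or (..., 4) stacks; 0*log(0) terms contribute zero.
    Symmetric, zero iff the distributions are equal, bounded by 1 bit.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p > 0, p * (np.log2(p) - np.log2(m)), 0.0)
        term_q = np.where(q > 0, q * (np.log2(q) - np.log2(m)), 0.0)
    return 0.5 * term_p.sum(axis=-1) + 0.5 * term_q.sum(axis=-1)


def _permutation_pvalues(
    counts_wt: np.ndarray,
    counts_mut: np.ndarray,
    observed: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Column-wise permutation p-values for the JSD statistic.

    Per column the base observations of both strains are pooled and strain
    labels reshuffled preserving group sizes — a random split of the pooled
    counts, drawn as a multivariate hypergeometric sample.  The smaller
    group is drawn, which makes the result invariant to argument order.
    The p-value is (1 + #{perm >= observed}) / (n_permutations + 1).
    """
    n_wt = int(counts_wt.sum(axis=0)[0])
    n_mut = int(counts_mut.sum(axis=0)[0])
    n_draw = min(n_wt, n_mut)
    width = counts_wt.shape[1]
    p_values = np.empty(width)
    for j in range(width):
        pooled = (counts_wt[:, j] + counts_mut[:, j]).astype(np.int64)
        draw = rng.multivariate_hypergeometric(
            pooled, n_draw, size=n_permutations
        ).astype(float)
        rest = pooled.astype(float) - draw
        jsd = jensen_shannon_bits(draw / n_draw, rest / (n_wt + n_mut - n_draw))
        n_ge = int(np.sum(jsd >= observed[j] - 1e-12))
        p_values[j] = (1 + n_ge) / (n_permutations + 1)
    return p_values


def diff_logo(
    matrix_wt: PositionMatrix,
    matrix_mut: PositionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    labels: np.ndarray | None = None,
) -> DiffLogoResult:
    """Column-wise difference statistic between WT and mutant matrices.

    Height = JSD in bits between the two probability columns.  Per-base
    contribution = height * (p_mut - p_wt) / sum|p_mut - p_wt|, so signed
    absolute contributions sum to the height and the sign points to the
    enriched strain (positive = mutant).  p-values come from
    :func:`_permutation_pvalues`; a column is significant if p < alpha.
    """
    if matrix_wt.width != matrix_mut.width:
        raise ValueError(
            f"matrix widths differ: {matrix_wt.width} vs {matrix_mut.width}"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if matrix_wt.n_sequences < 2 or matrix_mut.n_sequences < 2:
        raise ValueError("need at least 2 sequences per matrix")

    p_wt = matrix_wt.probabilities
    p_mut = matrix_mut.probabilities
    heights = jensen_shannon_bits(p_wt.T, p_mut.T)
    diff = p_mut - p_wt
    denom = np.abs(diff).sum(axis=0)
    safe = np.where(denom > 0, denom, 1.0)
    contributions = heights * diff / safe

    rng = np.random.default_rng(seed)
    p_values = _permutation_pvalues(
        matrix_wt.counts, matrix_mut.counts, heights, n_permutations, rng
    )
    return DiffLogoResult(
        heights=heights,
        contributions=contributions,
        p_values=p_values,
        significant=p_values < alpha,
        labels=None if labels is None else np.asarray(labels),
        alpha=alpha,
    )


def net_base_contribution(
    result: DiffLogoResult, base: str, label_lo: int, label_hi: int
) -> float:
    """Sum of one base's signed contributions over a label range.

    Positive values mean the base is overrepresented in the mutant over
    labels ``label_lo..label_hi`` (inclusive, no label 0 exists).
    """
    if result.labels is None:
        raise ValueError("result carries no column labels")
    mask = (result.labels >= label_lo) & (result.labels <= label_hi)
    return float(result.contributions[_BASE_INDEX[base], mask].sum())
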