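"""Replicate concordance and WT-vs-mutant occupancy comparison.

Concordance between replicates is Spearman rank correlation of normalised
occupancy.  The strain comparison works on the median-of-replicates track:
a per-position two-sample t-test on the replicate values classifies each
coordinate as increased / none / decreased occupancy in the mutant, moving
averages smooth the median profiles, and two-sample Kolmogorov–Smirnov
tests compare the occupancy value distributions genome-wide and per region.

The per-position test is a pooled-variance (Student) two-sample t-test on
normalised replicate values, two-sided, with no multiple-testing
correction — the per-position significance band is displayed raw.  With
three exchangeable replicates per strain the pooled test holds its nominal
level exactly under normality, whereas the Welch variant is structurally
conservative at n = 3 (true level ~0.035 at alpha = 0.05) because the
Satterthwaite degrees-of-freedom approximation degrades; see the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REGION_NAMES


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the comparison and pause-logo analyses.

    alpha
        Two-sided significance level for the per-position test, the K-S
        tests and the difference-logo permutation test.
    windows
        Moving-average window sizes in nucleotides.
    top_fraction
        Occupancy quantile defining pause sites (0.025 = top 2.5%).
    flank
        Half-width of the pause-site sequence window; the last incorporated
        nucleotide sits at label -1.
    n_permutations
        Label permutations per column of the difference logo.
    seed
        Seed for the permutation test.
    """

    alpha: float = 0.05
    windows: tuple[int, ...] = (200, 2000)
    top_fraction: float = 0.025
    flank: int = 30
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1): {self.alpha}")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError(f"top_fraction must be in (0, 1): {self.top_fraction}")
        if self.flank < 1:
            raise ValueError(f"flank must be >= 1: {self.flank}")
        if any(w < 1 for w in self.windows):
            raise ValueError(f"window sizes must be >= 1: {self.windows}")
        if self.n_permutations < 1:
            raise ValueError(f"n_permutations must be >= 1: {self.n_permutations}")


@dataclass
class ComparisonResult:
    """Per-position and per-region strain comparison.

    ``positions`` has columns coordinate, region, median_wt, median_mut,
    p_value, occupancy_class (increased / none / decreased, mutant relative
    to WT).  ``regions`` has columns region, ks_statistic, ks_p_value.
    ``genomewide_ks`` is the (statistic, p_value) pair for the full-unit
    median tracks.
    """

    positions: pd.DataFrame
    regions: pd.DataFrame
    genomewide_ks: tuple[float, float]
    alpha: float


def _normalized_matrix(tracks: Sequence[pd.DataFrame]) -> np.ndarray:
    """Stack the normalised columns of replicate tracks into (n_reps, L)."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 replicates per strain")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"replicate tracks differ in length: {sorted(lengths)}")
    mat = np.vstack([np.asarray(t["normalized"], dtype=float) for t in tracks])
    if np.isnan(mat).any():
        raise ValueError("tracks must be normalized before comparison")
    return mat


def spearman_concordance(values_a, values_b) -> float:
    """Spearman rank correlation between two occupancy vectors.

    Accepts raw vectors or track data frames (the ``normalized`` column is
    used).  Ties receive average ranks.  Constant input has no defined rank
    variance and is rejected.
    """
    a = np.asarray(
        values_a["normalized"] if isinstance(values_a, pd.DataFrame) else values_a,
        dtype=float,
    )
    b = np.asarray(
        values_b["normalized"] if isinstance(values_b, pd.DataFrame) else values_b,
        dtype=float,
    )
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 positions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float(stats.spearmanr(a, b).statistic)


def moving_average(values, window: int) -> np.ndarray:
    """Centred rolling mean; positions lacking a full window are omitted.

    Output length is ``len(values) - window + 1``; element ``i`` averages
    input positions ``i .. i + window - 1``.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1: {window}")
    if window > v.size:
        raise ValueError(f"window {window} exceeds vector length {v.size}")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    return (csum[window:] - csum[:-window]) / window


def ks_compare(values_wt, values_mut) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on two occupancy value sets.

    Returns the sup distance between the two empirical CDFs and the
    asymptotic two-sided p-value.
    """
    a = np.asarray(values_wt, dtype=float)
    b = np.asarray(values_mut, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def positionwise_comparison(
    wt_tracks: Sequence[pd.DataFrame],
    mut_tracks: Sequence[pd.DataFrame],
    config: AnalysisConfig = AnalysisConfig(),
) -> ComparisonResult:
    """Compare mutant and WT occupancy per position and per region.

    Per position: a two-sided pooled-variance t-test on the normalised
    replicate values; a position is classed increased (decreased) if p < alpha and
    the mutant median is above (below) the WT median, otherwise none.
    Positions where both strains are constant and equal give p = 1.
    Per region and genome-wide: K-S test between the two median tracks.
    """
    wt = _normalized_matrix(wt_tracks)
    mut = _normalized_matrix(mut_tracks)
    if wt.shape[1] != mut.shape[1]:
        raise ValueError(
            f"strain track lengths differ: {wt.shape[1]} vs {mut.shape[1]}"
        )
    med_wt = np.median(wt, axis=0)
    med_mut = np.median(mut, axis=0)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance positions trigger scipy's precision-loss warning;
        # their NaN p-values are mapped to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(mut, wt, axis=0, equal_var=True)
    p_values = np.asarray(t_res.pvalue, dtype=float)
    p_values[~np.isfinite(p_values)] = 1.0  # zero-variance ties: no evidence

    occ_class = np.full(wt.shape[1], "none", dtype=object)
    sig = p_values < config.alpha
    occ_class[sig & (med_mut > med_wt)] = "increased"
    occ_class[sig & (med_mut < med_wt)] = "decreased"

    regions = np.asarray(wt_tracks[0]["region"], dtype=object)
    positions = pd.DataFrame(
        {
            "coordinate": np.asarray(wt_tracks[0]["coordinate"]),
            "region": regions,
            "median_wt": med_wt,
            "median_mut": med_mut,
            "p_value": p_values,
            "occupancy_class": occ_class,
        }
    )

    rows = []
    for region in REGION_NAMES:
        mask = regions == region
        ks_stat, ks_p = ks_compare(med_wt[mask], med_mut[mask])
        rows.append({"region": region, "ks_statistic": ks_stat, "ks_p_value": ks_p})
    region_table = pd.DataFrame(rows)
    genomewide = ks_compare(med_wt, med_mut)

    return ComparisonResult(
        positions=positions,
        regions=region_table,
        genomewide_ks=genomewide,
        alpha=config.alpha,
    )


def median_track(tracks: Sequence[pd.DataFrame]) -> np.ndarray:
    """Median of the normalised values across replicate tracks."""
    return np.median(_normalized_matrix(tracks), axis=0)


def smoothed_profiles(
    tracks: Sequence[pd.DataFrame], windows: Sequence[int]
) -> dict[int, np.ndarray]:
    """Moving averages of the median track for each window size."""
    med = median_track(tracks)
    return {int(w): moving_average(med, int(w)) for w in windows}
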