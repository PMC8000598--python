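"""Pause-site calling, windows, matrices and the permutation difference logo."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netseq_rdna import (
    PauseSiteSet,
    build_matrix,
    call_pause_sites,
    diff_logo,
    downstream_g_fraction,
    extract_windows,
    jensen_shannon_bits,
    net_base_contribution,
    occupancy_probabilities,
)
from netseq_rdna.pauselogo import BASES


class TestCallPauseSites:
    def test_distinct_values_give_exact_top_fraction(self):
        rng = np.random.default_rng(2)
        flank = 30
        values = rng.permutation(6059).astype(float)  # 6000 eligible, all distinct
        sites = call_pause_sites(values, 0.025, flank)
        assert len(sites.coordinates) == 150
        eligible = values[flank - 1 : 6059 - flank]
        top = np.sort(eligible)[-150:]
        assert np.allclose(
            np.sort(values[sites.coordinates - 1]), top
        )

    def test_all_values_equal_returns_all_eligible(self):
        flank = 5
        values = np.full(100, 0.5)
        sites = call_pause_sites(values, 0.025, flank)
        assert len(sites.coordinates) == 100 - 2 * flank + 1

    def test_edge_positions_excluded_before_quantile(self):
        flank = 10
        values = np.zeros(100)
        values[:5] = 10.0  # huge but too close to the 5' edge
        values[50] = 1.0
        sites = call_pause_sites(values, 0.02, flank)
        assert 51 in sites.coordinates + 0  # coordinate 51 holds the 1.0
        assert all(c >= flank for c in sites.coordinates)

    def test_track_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            call_pause_sites(np.zeros(50), 0.025, 30)

    def test_planted_heavy_positions_all_called(self):
        """Twenty positions given 50x sampling weight are all recovered as
        pause sites from median-of-replicates multinomial counts."""
        rng = np.random.default_rng(11)
        n, flank = 900, 30
        weights = np.ones(n)
        planted = rng.choice(np.arange(flank, n - flank + 1), size=20, replace=False)
        weights[planted - 1] = 50.0
        probs = weights / weights.sum()
        reps = rng.multinomial(20000, probs, size=3) / 20000
        med = np.median(reps, axis=0)
        sites = call_pause_sites(med, 0.025, flank)
        assert set(planted) <= set(sites.coordinates)


class TestExtractWindows:
    def test_window_construction_lnt_at_minus_one(self):
        sites = PauseSiteSet(coordinates=np.array([3]), quantile_threshold=0.0)
        windows = extract_windows(sites, "AACGTT", flank=2)
        assert windows.windows == ["ACGT"]
        # LNT (unit position 3 = 'C') sits at label -1, 0-based index flank-1
        assert windows.windows[0][windows.flank - 1] == "C"
        assert list(windows.labels) == [-2, -1, 1, 2]

    def test_windows_in_ascending_coordinate_order(self):
        sites = PauseSiteSet(coordinates=np.array([5, 3]), quantile_threshold=0.0)
        windows = extract_windows(sites, "AACGTTAA", flank=2)
        assert windows.windows == ["ACGT", "GTTA"]

    def test_out_of_bounds_site_rejected(self):
        sites = PauseSiteSet(coordinates=np.array([1]), quantile_threshold=0.0)
        with pytest.raises(ValueError, match="too close"):
            extract_windows(sites, "AACGTT", flank=2)

    def test_g_weighted_sites_have_g_rich_downstream(self, locus_default, clean_params):
        """Windows around the highest-weight positions of a G-coupled
        occupancy model are downstream-G-enriched over the template mean."""
        import dataclasses

        params = dataclasses.replace(clean_params, pause_gc_weight=3.0)
        probs = occupancy_probabilities(locus_default, params)
        flank = 30
        eligible = np.arange(flank, locus_default.unit_length - flank + 1)
        order = np.argsort(probs[eligible - 1])[::-1]
        sites = PauseSiteSet(
            coordinates=eligible[order[:20]], quantile_threshold=0.0
        )
        windows = extract_windows(sites, locus_default, flank)
        downstream = [w[flank : flank + 10] for w in windows.windows]
        g_frac = np.mean([s.count("G") / len(s) for s in downstream])
        background = locus_default.unit_sequence.count("G") / locus_default.unit_length
        assert g_frac > background + 0.1


class TestBuildMatrix:
    def test_counting_example(self):
        m = build_matrix(["AC", "AG"])
        assert m.probabilities[BASES.index("A"), 0] == pytest.approx(1.0)
        assert m.probabilities[BASES.index("C"), 1] == pytest.approx(0.5)
        assert m.probabilities[BASES.index("G"), 1] == pytest.approx(0.5)
        assert m.n_sequences == 2

    def test_columns_sum_to_n_and_one(self):
        m = build_matrix(["ACGT", "AAAA", "CGTA"])
        assert (m.counts.sum(axis=0) == 3).all()
        assert m.probabilities.sum(axis=0) == pytest.approx(np.ones(4))

    def test_non_acgt_rejected_naming_window(self):
        with pytest.raises(ValueError, match="window 1"):
            build_matrix(["ACGT", "ACNT"])

    def test_sampled_matrix_recovers_distribution(self):
        rng = np.random.default_rng(3)
        p = np.array([0.5, 0.2, 0.2, 0.1])
        n = 400
        windows = ["".join(BASES[i] for i in rng.choice(4, size=3, p=p)) for _ in range(n)]
        m = build_matrix(windows)
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(m.probabilities - p[:, None]) < 5 * se[:, None] + 1e-9)


class TestJensenShannon:
    def test_disjoint_point_masses_one_bit(self):
        assert jensen_shannon_bits([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(1.0)

    def test_zero_iff_equal_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            d = jensen_shannon_bits(p, q)
            assert 0.0 <= d <= 1.0 + 1e-12
            assert jensen_shannon_bits(p, p) == pytest.approx(0.0, abs=1e-12)
            assert d == pytest.approx(jensen_shannon_bits(q, p))

    def test_matches_scipy(self):
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        assert jensen_shannon_bits(p, q) == pytest.approx(
            jensenshannon(p, q, base=2) ** 2
        )


class TestDiffLogo:
    def test_matrix_vs_itself_all_zero_nothing_significant(self):
        m = build_matrix(["ACGT", "AATT", "CCGG", "ACGG"])
        result = diff_logo(m, m, n_permutations=200, seed=0)
        assert np.allclose(result.heights, 0.0)
        assert not result.significant.any()
        assert np.allclose(result.contributions, 0.0)

    def test_point_mass_column_one_bit_and_significant(self):
        m_wt = build_matrix(["A"] * 50)
        m_mut = build_matrix(["C"] * 50)
        result = diff_logo(m_wt, m_mut, n_permutations=999, seed=1)
        assert result.heights[0] == pytest.approx(1.0)
        assert result.p_values[0] == pytest.approx(1 / 1000)
        assert result.significant[0]

    def test_permutation_p_matches_exact_enumeration_small_n(self):
        """At 3-vs-3 single-base observations the permutation p-value can be
        enumerated exactly over all C(6,3) label splits."""
        wt_obs = ["A", "A", "C"]
        mut_obs = ["C", "C", "A"]
        m_wt = build_matrix(wt_obs)
        m_mut = build_matrix(mut_obs)
        observed = jensen_shannon_bits(
            m_wt.probabilities[:, 0], m_mut.probabilities[:, 0]
        )
        pooled = wt_obs + mut_obs
        stats = []
        for combo in itertools.combinations(range(6), 3):
            grp = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(6) if i not in combo]
            stats.append(
                jensen_shannon_bits(
                    build_matrix(grp).probabilities[:, 0],
                    build_matrix(rest).probabilities[:, 0],
                )
            )
        exact = np.mean([s >= observed - 1e-12 for s in stats])
        result = diff_logo(m_wt, m_mut, n_permutations=4000, seed=2)
        # +1 correction keeps the sampled p within sampling error of exact
        assert result.p_values[0] == pytest.approx(exact, abs=0.03)

    def test_symmetry_heights_p_equal_contributions_flip(self):
        rng = np.random.default_rng(6)
        wt = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(30)]
        mut = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(40)]
        a = diff_logo(build_matrix(wt), build_matrix(mut), 500, seed=3)
        b = diff_logo(build_matrix(mut), build_matrix(wt), 500, seed=3)
        assert np.allclose(a.heights, b.heights)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.allclose(a.contributions, -b.contributions)

    def test_contribution_magnitudes_sum_to_height(self):
        rng = np.random.default_rng(7)
        wt = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(25)]
        mut = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(25)]
        result = diff_logo(build_matrix(wt), build_matrix(mut), 200, seed=4)
        assert np.abs(result.contributions).sum(axis=0) == pytest.approx(
            result.heights, abs=1e-12
        )

    def test_null_calibration_fraction_significant_near_alpha(self):
        """Two matrices sampled from the same distribution: the share of
        significant columns stays inside the 99% binomial band around alpha."""
        rng = np.random.default_rng(8)
        p = np.array([0.3, 0.3, 0.2, 0.2])
        n_cols, n_seq = 60, 150
        def sample():
            return [
                "".join(BASES[i] for i in rng.choice(4, size=n_cols, p=p))
                for _ in range(n_seq)
            ]
        result = diff_logo(
            build_matrix(sample()), build_matrix(sample()), 1000, seed=5
        )
        n_sig = int(result.significant.sum())
        from scipy import stats as ss

        lo, hi = ss.binom.ppf([0.005, 0.995], n_cols, 0.05)
        assert lo <= n_sig <= hi

    def test_width_mismatch_and_zero_permutations_rejected(self):
        m1 = build_matrix(["ACG", "AAA"])
        m2 = build_matrix(["AC", "AA"])
        with pytest.raises(ValueError, match="width"):
            diff_logo(m1, m2, 100, seed=0)
        with pytest.raises(ValueError, match="n_permutations"):
            diff_logo(m1, m1, 0, seed=0)

    def test_net_base_contribution_label_range(self):
        m_wt = build_matrix(["AA", "AA", "AC"])
        m_mut = build_matrix(["GG", "GG", "GA"])
        labels = np.array([-1, 1])
        result = diff_logo(m_wt, m_mut, 100, seed=9, labels=labels)
        net_g = net_base_contribution(result, "G", 1, 10)
        assert net_g > 0
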