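"""Shared intervals, sharing likelihood (enumeration oracles), age estimation."""

import itertools
import math

import numpy as np
import pytest

from aldorecur import haplotype as hap
from aldorecur import simulate as sim
from aldorecur.haplotype import (
    CarrierSharingObs,
    MarkerMap,
    PhasedHaplotype,
    SideObservation,
    discordance_bound_unphased,
    estimate_age,
    recomb_fraction,
    shared_interval_phased,
    sharing_log_likelihood,
)


def small_map(freqs_left, freqs_right, spacing=100_000, focal=1_000_000, mu_m=2e-8):
    nl, nr = len(freqs_left), len(freqs_right)
    positions = np.concatenate(
        [
            focal - spacing * np.arange(nl, 0, -1),
            focal + spacing * np.arange(1, nr + 1),
        ]
    )
    freqs = np.concatenate([freqs_left[::-1], freqs_right])
    return MarkerMap(
        ids=[f"m{i}" for i in range(nl + nr)],
        positions=positions,
        freqs=np.asarray(freqs, dtype=float),
        focal_bp=focal,
        mu_m=mu_m,
    )


class TestRecombFraction:
    def test_zero_distance(self):
        assert recomb_fraction(0, 2.9) == 0.0

    def test_one_megabase(self):
        """Haldane theta over 1 Mb at 2.9 cM/Mb: (1 - e^-0.058)/2."""
        assert recomb_fraction(1e6, 2.9) == pytest.approx(0.028175, abs=1e-5)

    def test_asymptote_and_monotonicity(self):
        assert recomb_fraction(1e9, 2.9) == pytest.approx(0.5, abs=1e-9)
        d = np.linspace(0, 5e6, 50)
        thetas = [recomb_fraction(x, 2.9) for x in d]
        assert np.all(np.diff(thetas) > 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            recomb_fraction(-1.0)


class TestSharedIntervalPhased:
    def test_identical_haplotypes_span_whole_region(self, toy_map):
        mmap, anc = toy_map
        haps = [PhasedHaplotype(f"c{i}", tuple(anc)) for i in range(3)]
        interval, _ = shared_interval_phased(haps, mmap)
        assert interval.censored_left and interval.censored_right
        assert interval.start == mmap.positions[0]
        assert interval.end == mmap.positions[-1]

    def test_constructed_discordance_positions(self):
        """Discordances planted at the 3rd marker out on each side."""
        mmap = small_map([0.5] * 5, [0.5] * 5)
        base = [0] * 10
        other = list(base)
        other[5 - 3] = 1  # 3rd marker left of focal (left side outward index 3)
        other[5 + 2] = 1  # 3rd marker right of focal
        haps = [
            PhasedHaplotype("a", tuple(base)),
            PhasedHaplotype("b", tuple(other)),
        ]
        interval, pairwise = shared_interval_phased(haps, mmap)
        assert interval.left_marker == "m2"
        assert interval.right_marker == "m7"
        assert interval.start == mmap.positions[2]
        assert interval.end == mmap.positions[7]
        assert interval.length == interval.end - interval.start
        assert pairwise[("a", "b")].length == interval.length

    def test_matches_bruteforce_all_pairs_scan(self):
        """Random haplotypes sharing a planted 12-marker core."""
        rng = np.random.default_rng(11)
        mmap = small_map([0.5] * 15, [0.5] * 15)
        core = set(range(15 - 6, 15 + 6))  # 6 markers each side
        haps = []
        for c in range(3):
            alleles = [
                0 if i in core else int(rng.integers(2)) for i in range(30)
            ]
            haps.append(PhasedHaplotype(f"c{c}", tuple(alleles)))
        interval, _ = shared_interval_phased(haps, mmap)

        # brute force: for every pair and every marker, record discordances
        arr = np.array([h.alleles for h in haps])
        discordant = [
            any(
                arr[i, k] != arr[j, k]
                for i in range(3)
                for j in range(i + 1, 3)
            )
            for k in range(30)
        ]
        left = [k for k in range(15) if discordant[k]]
        right = [k for k in range(15, 30) if discordant[k]]
        exp_start = mmap.positions[max(left)] if left else mmap.positions[0]
        exp_end = mmap.positions[min(right)] if right else mmap.positions[-1]
        assert interval.start == exp_start
        assert interval.end == exp_end

    def test_requires_two_carriers(self, toy_map):
        mmap, anc = toy_map
        with pytest.raises(ValueError):
            shared_interval_phased([PhasedHaplotype("a", tuple(anc))], mmap)


class TestUnphasedBound:
    def test_adjacent_hom_discordant_markers_minimal_bound(self):
        mmap = small_map([0.5] * 3, [0.5] * 3)
        g1 = np.zeros((6, 2), dtype=int)
        g2 = np.zeros((6, 2), dtype=int)
        g2[2] = [1, 1]  # innermost left marker
        g2[3] = [1, 1]  # innermost right marker
        bound = discordance_bound_unphased({"a": g1, "b": g2}, mmap)
        assert bound.left_marker == "m2" and bound.right_marker == "m3"
        assert not bound.censored

    def test_all_het_gives_unbounded_flagged(self):
        mmap = small_map([0.5] * 3, [0.5] * 3)
        g = np.tile([0, 1], (6, 1))
        bound = discordance_bound_unphased({"a": g, "b": g.copy()}, mmap)
        assert bound.censored_left and bound.censored_right
        assert bound.start == mmap.positions[0] and bound.end == mmap.positions[-1]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        mmap = small_map([0.5] * 8, [0.5] * 8)
        gts = {f"s{i}": rng.integers(0, 2, size=(16, 2)) for i in range(3)}
        bound = discordance_bound_unphased(gts, mmap)

        def excl(k):
            homs = {tuple(g[k]) for g in gts.values() if g[k][0] == g[k][1]}
            return len(homs) >= 2

        left = [k for k in range(8) if excl(k)]
        right = [k for k in range(8, 16) if excl(k)]
        assert bound.start == (mmap.positions[max(left)] if left else mmap.positions[0])
        assert bound.end == (
            mmap.positions[min(right)] if right else mmap.positions[-1]
        )

    @pytest.mark.parametrize("g_true,seed", [(20, 0), (100, 1), (500, 2)])
    def test_phased_interval_within_unphased_bound(self, g_true, seed):
        """The phased interval is always contained in the unphased bound."""
        mmap, anc = sim.default_marker_map(n_per_side=30, seed=5)
        haps, _ = sim.simulate_descendant_haplotypes(
            anc, mmap, g_true, n_carriers=3, seed=seed
        )
        gts = sim.haplotypes_to_genotypes(haps, mmap, seed=seed + 99)
        phased, _ = shared_interval_phased(haps, mmap)
        unphased = discordance_bound_unphased(gts, mmap)
        assert unphased.start <= phased.start
        assert unphased.end >= phased.end
        assert unphased.length >= phased.length


def likelihood_by_enumeration(j, thetas, freqs, g):
    """Independent oracle: P(first discordance at j | g) by enumerating every
    (breakpoint, chance-allele pattern) outcome, marker mutation off."""
    n = len(thetas)
    surv = [1.0] + [(1 - t) ** g for t in thetas]
    total = 0.0
    for k in range(1, n + 2):  # breakpoint before marker k; n+1 = no breakpoint
        p_break = surv[k - 1] - surv[k] if k <= n else surv[n]
        if p_break <= 0:
            continue
        free = list(range(k - 1, n))  # markers drawn from the population
        for pattern in itertools.product([0, 1], repeat=len(free)):
            # pattern[m] == 1 means the drawn allele matches the ancestral
            p_pat = math.prod(
                freqs[mk] if hit else (1 - freqs[mk])
                for mk, hit in zip(free, pattern)
            )
            alleles_match = [True] * (k - 1) + [bool(h) for h in pattern]
            first_mismatch = next(
                (i + 1 for i, ok in enumerate(alleles_match) if not ok), None
            )
            if first_mismatch == j:
                total += p_break * p_pat
    return total


class TestSharingLikelihood:
    def test_single_marker_closed_form(self):
        """One marker, vanishing chance-match: L = 1 - (1-theta)^g, increasing."""
        mmap = small_map([1e-12], [1e-12], mu_m=1e-15)
        theta = mmap.side_thetas("left")[0]
        obs = CarrierSharingObs([SideObservation("c", "left", 1)])
        for g in (5, 50, 500):
            ll = sharing_log_likelihood(obs, mmap, g)
            assert ll == pytest.approx(math.log(1 - (1 - theta) ** g), abs=1e-6)
        grid = np.arange(1, 200)
        lls = sharing_log_likelihood(obs, mmap, grid)
        assert np.all(np.diff(lls) > 0)

    def test_all_censored_closed_form(self):
        """All sides shared to the last marker, f ~ 0: L = prod (1-theta_M)^g."""
        mmap = small_map([1e-12] * 3, [1e-12] * 3, mu_m=1e-15)
        obs = CarrierSharingObs(
            [
                SideObservation("c", "left", None),
                SideObservation("c", "right", None),
            ]
        )
        tl = mmap.side_thetas("left")[-1]
        tr = mmap.side_thetas("right")[-1]
        for g in (2, 20, 200):
            expected = g * (math.log(1 - tl) + math.log(1 - tr))
            assert sharing_log_likelihood(obs, mmap, g) == pytest.approx(
                expected, abs=1e-6
            )
        grid = np.arange(1, 200)
        lls = sharing_log_likelihood(obs, mmap, grid)
        assert np.all(np.diff(lls) < 0)

    @pytest.mark.parametrize("g", [3, 30, 300])
    def test_matches_enumeration_oracle(self, g):
        """3 markers per side with uneven frequencies: every first-discordance
        probability equals exhaustive enumeration over breakpoints and
        chance-match patterns."""
        mmap = small_map([0.3, 0.6, 0.8], [0.7, 0.4, 0.9], mu_m=1e-15)
        for side in ("left", "right"):
            thetas = mmap.side_thetas(side)
            freqs = mmap.side_freqs(side)
            for j in (1, 2, 3):
                obs = CarrierSharingObs([SideObservation("c", side, j)])
                expected = likelihood_by_enumeration(j, thetas, freqs, g)
                got = math.exp(sharing_log_likelihood(obs, mmap, g))
                assert got == pytest.approx(expected, rel=1e-6), (side, j)

    @pytest.mark.parametrize("g", [1, 10, 100])
    def test_probability_conservation(self, g):
        """With marker mutation off, the first-discordance distribution
        (including censoring) sums to one."""
        mmap = small_map([0.3, 0.6, 0.8], [0.7, 0.4, 0.9], mu_m=1e-300)
        total = 0.0
        for j in (1, 2, 3, None):
            obs = CarrierSharingObs([SideObservation("c", "left", j)])
            total += math.exp(sharing_log_likelihood(obs, mmap, g))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            CarrierSharingObs([])


class TestEstimateAge:
    def test_all_censored_hits_lower_boundary(self, toy_map):
        mmap, _ = toy_map
        obs = CarrierSharingObs(
            [
                SideObservation("c", "left", None),
                SideObservation("c", "right", None),
            ]
        )
        est = estimate_age(obs, mmap, np.arange(1, 501))
        assert est.g_hat == 1
        assert est.at_boundary

    def test_immediate_discordance_hits_upper_boundary(self):
        mmap = small_map([1e-9], [1e-9])
        obs = CarrierSharingObs([SideObservation("c", "left", 1)])
        est = estimate_age(obs, mmap, np.arange(1, 301))
        assert est.g_hat == 300
        assert est.at_boundary

    def test_estimates_order_with_true_age(self):
        """Older mutations (shorter shared haplotypes) get larger estimates;
        the profile CI brackets the point estimate."""
        mmap, anc = sim.default_marker_map(seed=42)

        def median_ghat(g_true):
            ghats = []
            for rep in range(10):
                _, obs = sim.simulate_descendant_haplotypes(
                    anc, mmap, g_true, n_carriers=4, seed=7000 + rep
                )
                est = estimate_age(obs, mmap)
                assert est.ci_low <= est.g_hat <= est.ci_high
                ghats.append(est.g_hat)
            return np.median(ghats)

        assert median_ghat(20) < median_ghat(100) < median_ghat(500)

    def test_invariant_to_padding_with_uninformative_markers(self):
        """Appending outer markers with ancestral frequency 1 beyond the
        observed region leaves the likelihood surface unchanged."""
        mmap = small_map([0.4, 0.6], [0.5, 0.7])
        padded = small_map([0.4, 0.6, 1.0], [0.5, 0.7, 1.0])
        obs = CarrierSharingObs(
            [
                SideObservation("c", "left", 2),
                SideObservation("c", "right", None),
            ]
        )
        grid = np.arange(1, 400)
        # censored observation extends through the padded marker on the map
        ll_a = sharing_log_likelihood(obs, mmap, grid)
        ll_b = sharing_log_likelihood(obs, padded, grid)
        np.testing.assert_allclose(ll_a, ll_b, atol=1e-9)

    def test_marker_relabeling_equivariance(self, toy_map):
        mmap, _ = toy_map
        renamed = MarkerMap(
            ids=[f"rs{i}" for i in range(len(mmap))],
            positions=mmap.positions,
            freqs=mmap.freqs,
            focal_bp=mmap.focal_bp,
            rate_cM_per_Mb=mmap.rate_cM_per_Mb,
            mu_m=mmap.mu_m,
        )
        obs = CarrierSharingObs(
            [SideObservation("c", "left", 2), SideObservation("c", "right", 3)]
        )
        a = estimate_age(obs, mmap, np.arange(1, 2001))
        b = estimate_age(obs, renamed, np.arange(1, 2001))
        assert (a.g_hat, a.ci_low, a.ci_high) == (b.g_hat, b.ci_low, b.ci_high)


class TestMapValidation:
    def test_focal_inside(self):
        with pytest.raises(ValueError):
            MarkerMap(
                ids=["a", "b"],
                positions=np.array([100, 200]),
                freqs=np.array([0.5, 0.5]),
                focal_bp=300,
            )

    def test_increasing_positions(self):
        with pytest.raises(ValueError):
            MarkerMap(
                ids=["a", "b", "c"],
                positions=np.array([100, 90, 200]),
                freqs=np.array([0.5, 0.5, 0.5]),
                focal_bp=150,
            )


class TestIO:
    def test_plink_map_and_tsv_roundtrip(self, tmp_path):
        mappath = tmp_path / "chr16.map"
        mappath.write_text(
            "16 rs1 0.0 900000\n16 rs2 0.0 950000\n16 rs3 0.0 1050000\n16 rs4 0.0 1100000\n"
        )
        (tmp_path / "eur.tsv").write_text("id\tf\nrs1\t0.3\nrs2\t0.5\nrs3\t0.6\nrs4\t0.4\n")
        mmap = hap.read_plink_map(
            mappath, tmp_path / "eur.tsv", focal_bp=1_000_000
        )
        assert mmap.ids == ["rs1", "rs2", "rs3", "rs4"]
        assert list(mmap.side_indices("left")) == [1, 0]

        hapfile = tmp_path / "carriers.tsv"
        hapfile.write_text(
            "subject\tfocal_hap\trs1\trs2\trs3\trs4\n"
            "k1\t0\tA|G\tC|C\tT|T\tG|A\n"
            "k2\t1\tG|A\tC|C\tT|T\tA|A\n"
        )
        haps = hap.read_haplotypes_tsv(hapfile)
        assert haps[0].alleles == ("A", "C", "T", "G")
        assert haps[1].alleles == ("A", "C", "T", "A")
        interval, _ = shared_interval_phased(haps, mmap)
        assert interval.left_marker is None and interval.censored_left
        assert interval.right_marker == "rs4"
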