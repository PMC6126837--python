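import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucnet.io import AnchorAnnotation, NucleosomeCall
from nucnet.metrics import (
    OccupancyTrack,
    PhasingTemplate,
    binarize_profile,
    cluster_profiles,
    entropy,
    js_divergence,
    nfr_geometry,
    phasing_index,
)
from nucnet.pairs import index_to_anchors


def distributions(n):
    return (
        st.lists(st.floats(0.01, 10.0), min_size=n, max_size=n)
        .map(lambda w: np.array(w) / np.sum(w))
    )


class TestEntropyAndJSD:
    def test_closed_forms(self):
        assert entropy([0.5, 0.5]) == pytest.approx(1.0)
        assert entropy([1.0, 0.0]) == pytest.approx(0.0)
        assert entropy([0.75, 0.25]) == pytest.approx(0.8112781245, abs=1e-9)
        assert js_divergence([1, 0], [0.5, 0.5]) == pytest.approx(
            0.3112781245, abs=1e-9
        )

    def test_identity_and_disjoint_limits(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            entropy([0.5, 0.6])
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            js_divergence([1.0], [0.5, 0.5])

    @settings(derandomize=True, max_examples=50)
    @given(distributions(5), distributions(5))
    def test_symmetry_and_bounds(self, p, q):
        d = js_divergence(p, q)
        assert d == pytest.approx(js_divergence(q, p), abs=1e-12)
        assert -1e-12 <= d <= 1.0 + 1e-12

    def test_matches_scipy_jensenshannon(self):
        # independent cross-check: scipy returns the square root of the JSD
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert js_divergence(p, q) == pytest.approx(
                jensenshannon(p, q, base=2) ** 2, abs=1e-10
            )


class TestPhasingTemplate:
    def test_canonical_bin_frame(self):
        t = PhasingTemplate.canonical()
        assert len(t.bin_starts) == 40
        assert sum(t.values) == 23           # peak bins
        assert len(t.values) - sum(t.values) == 17  # valley bins
        assert 100 in t.bin_starts and 710 in t.bin_starts
        assert 170 not in t.bin_starts       # gap between peak 1 and valley 1
        assert all(b % 10 == 0 for b in t.bin_starts)


class TestPhasingIndex:
    def test_self_is_one_complement_is_zero(self):
        t = PhasingTemplate.canonical()
        assert phasing_index(t, np.array(t.values)).index == pytest.approx(1.0)
        comp = 1 - np.array(t.values)
        assert phasing_index(t, comp).index == pytest.approx(0.0, abs=1e-12)

    def test_partial_match_against_exact_arithmetic(self):
        import sympy

        t = PhasingTemplate.canonical()
        # profile: first three peak blocks occupied, nothing else
        profile = np.zeros(40, dtype=int)
        peak_bins = [i for i, v in enumerate(t.values) if v == 1]
        profile[peak_bins[:17]] = 1  # blocks of 6 + 6 + 5 bins
        got = phasing_index(t, profile).index

        # independent oracle in exact rational arithmetic
        p0 = [sympy.Rational(v, 23) for v in t.values]
        p1 = [sympy.Rational(int(x), 17) for x in profile]

        def H(ps):
            return -sum(
                p * sympy.log(p, 2) for p in ps if p != 0
            )

        jsd = H([(a + b) / 2 for a, b in zip(p0, p1)]) - (H(p0) + H(p1)) / 2
        expected = float(sympy.N(1 - jsd, 30))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_zero_profile_skipped(self):
        t = PhasingTemplate.canonical()
        assert phasing_index(t, np.zeros(40)) is None

    def test_index_bounded_and_maximal_only_at_identity(self):
        t = PhasingTemplate.canonical()
        rng = np.random.default_rng(0)
        for _ in range(20):
            profile = rng.integers(0, 2, size=40)
            if profile.sum() == 0:
                continue
            rec = phasing_index(t, profile)
            assert -1e-12 <= rec.index <= 1 + 1e-12
            normalized_equal = np.array_equal(
                profile / profile.sum(), np.array(t.values) / 23
            )
            assert (rec.index == pytest.approx(1.0)) == normalized_equal

    def test_literal_formula_variant(self):
        t = PhasingTemplate.canonical()
        rec = phasing_index(t, np.array(t.values), literal_formula=True)
        # 1 - H(P0) - H(P0) for self-comparison; not 1 under the literal reading
        assert rec.index == pytest.approx(1.0 - 2 * entropy(np.array(t.values) / 23))


class TestBinarizeProfile:
    def test_single_nucleosome_covers_first_peak_block(self):
        t = PhasingTemplate.canonical()
        a = AnchorAnnotation("g_TSS", "chr1", "TSS", 5000, "+")
        calls = [NucleosomeCall("chr1", 5095, 5250, 5170, 80, "MainPeak")]
        prof = binarize_profile(calls, a, t)
        by_start = dict(zip(t.bin_starts, prof))
        assert all(by_start[s] == 1 for s in range(100, 151, 10))
        # the footprint extends into the first valley region up to +250
        assert all(by_start[s] == 1 for s in range(210, 241, 10))
        assert all(by_start[s] == 0 for s in range(250, 261, 10))
        assert all(by_start[s] == 0 for s in range(290, 341, 10))

    def test_two_nucleosome_fixture_hand_enumerated(self):
        t = PhasingTemplate.canonical()
        a = AnchorAnnotation("g_TSS", "chr1", "TSS", 5000, "+")
        calls = [
            NucleosomeCall("chr1", 5095, 5250, 5170, 80, "MainPeak"),
            NucleosomeCall("chr1", 5280, 5430, 5355, 80, "MainPeak"),
        ]
        prof = binarize_profile(calls, a, t)
        by_start = dict(zip(t.bin_starts, prof))
        expected_ones = (
            list(range(100, 151, 10)) + list(range(210, 241, 10))
            + list(range(290, 341, 10)) + list(range(390, 421, 10))
        )
        assert [s for s, v in by_start.items() if v == 1] == expected_ones

    def test_no_calls_gives_all_zero(self):
        t = PhasingTemplate.canonical()
        a = AnchorAnnotation("g_TSS", "chr1", "TSS", 5000, "+")
        assert binarize_profile([], a, t).sum() == 0

    def test_minus_strand_flips_axis(self):
        t = PhasingTemplate.canonical()
        a = AnchorAnnotation("g_TSS", "chr1", "TSS", 5000, "-")
        # +1 nucleosome of a minus-strand gene lies genomically left of the TSS
        calls = [NucleosomeCall("chr1", 4750, 4905, 4830, 80, "MainPeak")]
        prof = binarize_profile(calls, a, t)
        by_start = dict(zip(t.bin_starts, prof))
        assert all(by_start[s] == 1 for s in range(100, 151, 10))
        assert all(by_start[s] == 0 for s in range(290, 341, 10))


def track(values_by_bin, chrom="chr1"):
    n = max(values_by_bin) + 1
    vals = np.zeros(n)
    for i, v in values_by_bin.items():
        vals[i] = v
    return OccupancyTrack(profiles={chrom: (0, vals)})


class TestNFRGeometry:
    anchor = AnchorAnnotation("g_TSS", "chr1", "TSS", 1000, "+")

    def indexed(self, up_summit=900, down_summit=1100):
        calls = [
            NucleosomeCall("chr1", up_summit - 73, up_summit + 74, up_summit,
                           80, "MainPeak"),
            NucleosomeCall("chr1", down_summit - 73, down_summit + 74,
                           down_summit, 80, "MainPeak"),
        ]
        return index_to_anchors(calls, [self.anchor], window=2000)

    def test_depth_formula_on_crafted_track(self):
        vals = {i: 6.0 for i in range(83, 90)}
        vals.update({i: 2.0 for i in range(90, 110)})
        vals.update({i: 10.0 for i in range(110, 117)})
        rec = nfr_geometry(self.anchor, self.indexed(), track(vals))
        assert rec.valid
        assert rec.length == 200
        assert rec.depth == pytest.approx(0.6)       # 1 - 2 / (0.5*(4+6))
        assert rec.size == pytest.approx(rec.length * rec.depth)

    def test_zero_nfr_signal_gives_depth_one(self):
        vals = {i: 4.0 for i in range(83, 90)}
        vals.update({i: 0.0 for i in range(90, 110)})
        vals.update({i: 4.0 for i in range(110, 117)})
        rec = nfr_geometry(self.anchor, self.indexed(), track(vals))
        assert rec.depth == pytest.approx(1.0)

    def test_flat_profile_gives_depth_zero(self):
        vals = {i: 5.0 for i in range(0, 130)}
        rec = nfr_geometry(self.anchor, self.indexed(), track(vals))
        assert rec.depth == pytest.approx(0.0)

    def test_wide_nfr_excluded(self):
        vals = {i: 5.0 for i in range(0, 140)}
        rec = nfr_geometry(
            self.anchor, self.indexed(up_summit=870, down_summit=1130),
            track(vals),
        )
        assert not rec.valid  # 260 bp summit-to-summit > 250

    def test_missing_flank_or_zero_signal_invalid(self):
        vals = {i: 5.0 for i in range(0, 130)}
        only_down = [nu for nu in self.indexed() if nu.slot == 1]
        assert not nfr_geometry(self.anchor, only_down, track(vals)).valid
        zero = track({i: 0.0 for i in range(0, 130)})
        assert not nfr_geometry(self.anchor, self.indexed(), zero).valid


class TestClusterProfiles:
    def archetypes(self, n_per=30, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 2 * math.pi, 50)
        a = np.cos(x) + 1.5
        b = np.cos(x + math.pi) + 1.5
        profiles = np.vstack(
            [a + rng.normal(0, noise, 50) for _ in range(n_per)]
            + [b + rng.normal(0, noise, 50) for _ in range(n_per)]
        )
        truth = np.array([0] * n_per + [1] * n_per)
        return profiles, truth

    def test_two_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        profiles, truth = self.archetypes()
        labels, k = cluster_profiles(profiles, range(2, 5), seed=7)
        assert k == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_profiles_degenerate(self):
        profiles = np.tile(np.linspace(1, 2, 30), (20, 1))
        labels, k = cluster_profiles(profiles, range(2, 4), seed=0)
        assert k == 1 and set(labels) == {0}

    def test_permutation_invariance_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score

        profiles, _ = self.archetypes(seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(profiles))
        l1, k1 = cluster_profiles(profiles, range(2, 5), seed=7)
        l2, k2 = cluster_profiles(profiles[perm], range(2, 5), seed=7)
        assert k1 == k2
        assert adjusted_rand_score(l1[perm], l2) == 1.0
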