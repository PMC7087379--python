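import itertools

import numpy as np
import pytest

from hicsv import (BreakpointRegion, PairScore, TranslocationCall,
                   call_translocations, detect_change_points,
                   generate_chimeric_reads, gini_index, max_interaction,
                   profile_1d_interchrom, quadrant_filter, rank_product,
                   refine_breakpoint, screen_pairs)
from hicsv.simulate import (SyntheticGenomeSpec, TranslocationSpec,
                            humanlike_chrom_sizes, random_translocations,
                            simulate_study)


def lorenz_gini_oracle(values):
    """Independent trapezoid Lorenz-area computation."""
    v = np.sort(np.asarray(values, dtype=float))
    total = v.sum()
    shares = np.concatenate([[0.0], np.cumsum(v) / total])
    x = np.linspace(0, 1, len(v) + 1)
    area = 0.0
    for i in range(len(v)):
        area += (x[i + 1] - x[i]) * (shares[i] + shares[i + 1]) / 2
    return 2 * (0.5 - area)


class TestGiniIndex:
    def test_uniform_block_is_zero(self):
        assert gini_index(np.full((4, 4), 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_known_small_vector(self):
        assert gini_index(np.array([[1.0, 1.0, 1.0, 9.0]])) == pytest.approx(0.5)

    def test_one_nonzero_among_ten(self):
        block = np.zeros((2, 5))
        block[0, 0] = 7.0
        block[1, :] = 1e-9  # keep rows/cols contacting so cells are retained
        block[:, 1:] += 1e-9
        got = gini_index(block)
        assert got == pytest.approx(lorenz_gini_oracle(block.ravel()), abs=1e-6)
        assert got == pytest.approx(0.9, abs=1e-3)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            vals = rng.random((1, n)) + 0.01
            assert gini_index(vals) == pytest.approx(
                lorenz_gini_oracle(vals.ravel()), abs=1e-12)

    def test_scale_invariance(self, rng):
        block = rng.random((6, 7)) + 0.1
        assert gini_index(3.7 * block) == pytest.approx(gini_index(block),
                                                        abs=1e-12)

    def test_non_contacting_rows_excluded(self):
        block = np.ones((3, 3))
        block[1, :] = 0.0  # row never contacts anything
        assert gini_index(block) == pytest.approx(0.0, abs=1e-12)

    def test_empty_block_undefined(self):
        assert np.isnan(gini_index(np.zeros((3, 3))))


class TestMaxInteraction:
    def test_single_cell(self):
        assert max_interaction(np.array([[7.3]])) == 7.3

    def test_all_equal(self):
        assert max_interaction(np.full((3, 3), 2.5)) == 2.5

    def test_matches_loop_maximum(self, rng):
        block = rng.random((8, 9))
        best = max(block[i, j] for i in range(8) for j in range(9))
        assert max_interaction(block) == best

    def test_masked_cells_ignored(self):
        block = np.array([[1.0, np.nan], [2.0, 3.0]])
        assert max_interaction(block) == 3.0


class TestRankProduct:
    def make(self, ginis, mifs):
        return [PairScore(f"chr{i}", f"chr{i+1}", g, m)
                for i, (g, m) in enumerate(zip(ginis, mifs))]

    def test_double_top_rank(self):
        ginis = np.linspace(0.9, 0.1, 10)
        mifs = np.linspace(100, 10, 10)
        scores = rank_product(self.make(ginis, mifs))
        assert scores[0].rp == pytest.approx(0.01)
        assert scores[0].is_candidate

    def test_rank_2_and_5(self):
        ginis = np.linspace(0.9, 0.1, 10)   # pair i has gini rank i+1
        mifs = [100, 80, 95, 90, 85, 60, 50, 40, 30, 20]  # pair 1: mif rank 5
        scores = rank_product(self.make(ginis, mifs))
        target = scores[1]
        assert (target.rank_gini, target.rank_mif) == (2, 5)
        assert target.rp == pytest.approx(0.10)
        assert not target.is_candidate

    def test_permutation_invariance(self, rng):
        ginis = rng.random(12)
        mifs = rng.random(12) * 50
        a = rank_product(self.make(ginis, mifs))
        perm = rng.permutation(12)
        b = rank_product(self.make(ginis[perm], mifs[perm]))
        got_a = {(s.gini, s.mif): s.rp for s in a}
        for s in b:
            assert s.rp == pytest.approx(got_a[(s.gini, s.mif)])

    def test_monotone_transform_invariance(self, rng):
        ginis = rng.random(12)
        mifs = rng.random(12) * 50
        a = rank_product(self.make(ginis, mifs))
        b = rank_product(self.make(np.exp(ginis), mifs ** 3))
        for x, y in zip(a, b):
            assert x.rp == y.rp

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            rank_product(self.make([0.5], [1.0]))


class TestProfiles:
    def test_small_block(self):
        rows, cols = profile_1d_interchrom(np.array([[1., 2, 3], [4, 5, 6]]))
        assert rows.tolist() == [6, 15]
        assert cols.tolist() == [5, 7, 9]

    def test_zero_block(self):
        rows, cols = profile_1d_interchrom(np.zeros((3, 4)))
        assert not rows.any() and not cols.any()

    def test_masked_cells_contribute_zero(self, rng):
        block = rng.random((5, 6))
        block[2, 3] = np.nan
        rows, _ = profile_1d_interchrom(block)
        expected = sum(v for j, v in enumerate(block[2]) if j != 3)
        assert rows[2] == pytest.approx(expected)


def exhaustive_change_points(x, max_breaks, min_seg, bic_penalty=3.0):
    """Enumerate every breakpoint placement; same BIC as the DP."""
    n = len(x)
    x = np.asarray(x, dtype=float)

    def rss_of(breaks):
        edges = [0, *breaks, n]
        return sum(((x[a:b] - x[a:b].mean()) ** 2).sum()
                   for a, b in zip(edges, edges[1:]))

    best = (n * np.log(rss_of([]) / n + 1e-12), [])
    for k in range(1, max_breaks + 1):
        for combo in itertools.combinations(range(1, n), k):
            edges = [0, *combo, n]
            if any(b - a < min_seg for a, b in zip(edges, edges[1:])):
                continue
            bic = (n * np.log(rss_of(list(combo)) / n + 1e-12)
                   + bic_penalty * k * np.log(n))
            if bic < best[0]:
                best = (bic, list(combo))
    return best[1]


class TestChangePoints:
    def test_constant_profile_has_none(self):
        assert detect_change_points(np.full(50, 3.0)) == []

    def test_single_step_found_within_one_bin(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        x += rng.normal(0, 0.5, 100)
        cps = detect_change_points(x)
        assert len(cps) == 1 and abs(cps[0] - 50) <= 1

    def test_short_profile_yields_nothing(self):
        assert detect_change_points(np.arange(8), min_seg=5) == []

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(12, 31))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.5:
                x[int(rng.integers(5, n - 5)):] += rng.normal(0, 4)
            got = detect_change_points(x, max_breaks=2, min_seg=5)
            want = exhaustive_change_points(x, max_breaks=2, min_seg=5)
            assert got == want


def quadrant_block(high_quadrants, n=80, q=5, hi=50.0, seed=42):
    """Noisy background (exponential, mean 1, so the 99th percentile sits
    well above the mean) with selected q x q quadrants elevated around the
    boundary (n//2, n//2)."""
    rng = np.random.default_rng(seed)
    b = rng.exponential(1.0, (n, n))
    r = c = n // 2
    spans = {0: (slice(r - q, r), slice(c - q, c)),
             1: (slice(r - q, r), slice(c, c + q)),
             2: (slice(r, r + q), slice(c - q, c)),
             3: (slice(r, r + q), slice(c, c + q))}
    for which in high_quadrants:
        b[spans[which]] = hi
    return b, r, c


class TestQuadrantFilter:
    def test_one_high_quadrant_is_unbalanced(self):
        b, r, c = quadrant_block([1])
        assert quadrant_filter(b, [r], [c]) == [(r, c, "unbalanced")]

    def test_two_diagonal_high_is_balanced(self):
        b, r, c = quadrant_block([1, 2])
        assert quadrant_filter(b, [r], [c]) == [(r, c, "balanced")]
        b, r, c = quadrant_block([0, 3])
        assert quadrant_filter(b, [r], [c]) == [(r, c, "balanced")]

    @pytest.mark.parametrize("quads", [[], [0, 1], [2, 3], [0, 2],
                                       [0, 1, 2], [0, 1, 2, 3]])
    def test_other_patterns_removed(self, quads):
        b, r, c = quadrant_block(quads)
        assert quadrant_filter(b, [r], [c]) == []

    def test_border_candidate_removed(self):
        b, r, c = quadrant_block([1])
        assert quadrant_filter(b, [0], [c]) == []

    def test_intermediate_quadrant_blocks_call(self):
        # one clearly high quadrant, another between the low and high bands
        b, r, c = quadrant_block([1])
        finite = b[np.isfinite(b)]
        thr = np.percentile(finite, 99)
        b[r:r + 5, c:c + 5] = 0.8 * thr  # not high, but not background either
        assert quadrant_filter(b, [r], [c]) == []


def region(chrom, start, width=100_000, axis="row"):
    return BreakpointRegion(chrom, start, start + width, axis)


class TestRefineBreakpoint:
    def spec(self):
        return TranslocationSpec("chr1", 12_345_678, "chr2", 9_000_001)

    def call(self):
        return TranslocationCall("chr1", "chr2",
                                 region("chr1", 12_300_000),
                                 region("chr2", 9_000_000, axis="column"),
                                 "unbalanced")

    def test_unanimous_chimeras_give_exact_breakpoint(self):
        chim = generate_chimeric_reads(self.spec(), 5, seed=1)
        call = refine_breakpoint(self.call(), chim)
        assert call.refined == (12_345_678, 9_000_001)
        assert call.n_support_chimeras == 5

    def test_no_support_reports_regions(self):
        call = refine_breakpoint(self.call(), [])
        assert call.refined is None
        assert call.regionA.start == 12_300_000

    def test_chimeras_outside_regions_ignored(self):
        far = TranslocationSpec("chr1", 50_000_000, "chr2", 70_000_000)
        chim = generate_chimeric_reads(far, 5, seed=2)
        call = refine_breakpoint(self.call(), chim)
        assert call.refined is None and call.n_support_chimeras == 0

    def test_modal_pair_wins(self):
        p = generate_chimeric_reads(self.spec(), 3, seed=3)
        q = generate_chimeric_reads(
            TranslocationSpec("chr1", 12_345_900, "chr2", 9_000_500), 1, seed=4)
        call = refine_breakpoint(self.call(), p + q)
        assert call.refined == (12_345_678, 9_000_001)
        assert call.n_support_chimeras == 4


def small_study(translocations, seed=5, n_chroms=5):
    sizes = humanlike_chrom_sizes(n_chroms)
    spec = SyntheticGenomeSpec(sizes, seed=seed)
    return simulate_study(spec, translocations), spec.make_bins()


class TestCallTranslocations:
    def test_unbalanced_event_recovered_with_region(self):
        t = TranslocationSpec("chr2", 40_000_000, "chr4", 30_000_000)
        (sample, bg, truths), bins = small_study([t])
        res = call_translocations(sample, bg)
        assert len(res.calls) >= 1
        best = res.calls[0]
        assert (best.chromA, best.chromB) == ("chr2", "chr4")
        assert t.posA in best.regionA and t.posB in best.regionB
        assert best.type == "unbalanced"

    def test_balanced_event_typed_balanced(self):
        t = TranslocationSpec("chr1", 50_000_000, "chr3", 35_000_000,
                              balanced=True)
        (sample, bg, truths), bins = small_study([t])
        res = call_translocations(sample, bg)
        assert any(c.type == "balanced"
                   and (c.chromA, c.chromB) == ("chr1", "chr3")
                   and t.posA in c.regionA and t.posB in c.regionB
                   for c in res.calls)

    def test_identity_input_yields_no_calls(self):
        sizes = humanlike_chrom_sizes(5)
        spec = SyntheticGenomeSpec(sizes, seed=6)
        (sample, bg, truths), bins = small_study([], seed=6)
        res = call_translocations(sample, bg)
        assert res.calls == []

    def test_refinement_wired_into_pipeline(self):
        t = TranslocationSpec("chr2", 40_000_000, "chr4", 30_000_000)
        (sample, bg, truths), bins = small_study([t])
        chim = generate_chimeric_reads(t, 4, seed=7)
        res = call_translocations(sample, bg, chim)
        best = res.calls[0]
        assert best.refined == (40_000_000, 30_000_000)
        assert best.n_support_chimeras == 4

    def test_translocated_pairs_outrank_background(self):
        """Planted pairs get strictly smaller rank products than every
        quiet pair in >= 95% of seeded runs."""
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            sizes = humanlike_chrom_sizes(5)
            spec = SyntheticGenomeSpec(sizes, seed=100 + seed)
            bins = spec.make_bins()
            tls = random_translocations(bins, 2, 100 + seed)
            sample, bg, truths = simulate_study(spec, tls)
            scores, _ = screen_pairs(sample, bg)
            planted = {(t.chromA, t.chromB) for t in truths}
            rp_t = [s.rp for s in scores if (s.chromA, s.chromB) in planted]
            rp_bg = [s.rp for s in scores if (s.chromA, s.chromB) not in planted]
            if max(rp_t) < min(rp_bg):
                wins += 1
        assert wins >= 0.95 * n_runs
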