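import numpy as np
import pytest

from ecodon import (
    DepthProfile,
    UncallableProfileError,
    call_copy_number,
    compare_bin_sizes,
    fit_copy_titer,
    parse_region,
    profile_from_base_depth,
    read_base_depth,
    read_depth_tsv,
    round_half_away,
    simulate_depth,
    write_depth_tsv,
)

REGION = (250_000, 255_000)


def make_profile(counts, bin_size=200, region=(2000, 3000), baseline="median"):
    counts = np.asarray(counts, dtype=float)
    starts = np.arange(len(counts)) * bin_size
    return DepthProfile(
        chrom="ref",
        bin_size=bin_size,
        starts=starts,
        ends=starts + bin_size,
        counts=counts,
        cassette_region=region,
        baseline_stat=baseline,
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(6.5, 7), (6.49, 6), (0.5, 1), (0.49, 0), (-6.5, -7), (2.0, 2)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestSimulateDepth:
    def test_neutral_copy_matches_baseline(self):
        profile = simulate_depth(500_000, REGION, 1, seed=0)
        inside, background = profile._masks()
        assert profile.counts[inside].mean() == pytest.approx(
            profile.counts[background].mean(), rel=0.05
        )

    def test_absent_cassette_gives_zero_depth(self):
        profile = simulate_depth(500_000, REGION, 0, dispersion=1.0, seed=0)
        inside, _ = profile._masks()
        assert np.all(profile.counts[inside] == 0)

    def test_region_mean_scales_with_copy_number(self):
        """Mean region depth over replicates approaches copies x bin depth."""
        means = []
        for s in range(200):
            profile = simulate_depth(500_000, REGION, 6, mean_bin_depth=40, seed=s)
            inside, _ = profile._masks()
            means.append(profile.counts[inside].mean())
        assert np.mean(means) == pytest.approx(240, rel=0.05)

    def test_seed_reproducibility(self):
        a = simulate_depth(500_000, REGION, 3, seed=42)
        b = simulate_depth(500_000, REGION, 3, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_overdispersed_counts_have_larger_variance(self):
        po = simulate_depth(500_000, REGION, 1, dispersion=1.0, seed=1)
        nb = simulate_depth(500_000, REGION, 1, dispersion=3.0, seed=1)
        assert nb.counts.var() > 1.5 * po.counts.var()

    def test_truncated_boundary_bin_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            profile = simulate_depth(1050, (0, 200), 1, bin_size=200, seed=0)
        assert profile.ends[-1] - profile.starts[-1] == 50

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_depth(1000, (900, 1200), 1)
        with pytest.raises(ValueError):
            simulate_depth(500_000, REGION, -1)
        with pytest.raises(ValueError):
            simulate_depth(500_000, REGION, 1, dispersion=0.5)


class TestCallCopyNumber:
    def test_ratio_arithmetic(self):
        counts = [40.0] * 50
        for i in range(10, 15):  # region 2000-3000 with bin 200
            counts[i] = 240.0
        call = call_copy_number(make_profile(counts))
        assert call.mean_region_depth == 240.0
        assert call.baseline == 40.0
        assert call.copy_estimate == pytest.approx(6.0)
        assert call.genotype == 6

    def test_equal_depth_is_single_copy(self):
        call = call_copy_number(make_profile([40.0] * 50))
        assert call.genotype == 1

    def test_ploidy_scales_estimate(self):
        counts = [40.0] * 50
        for i in range(10, 15):
            counts[i] = 80.0
        call = call_copy_number(make_profile(counts), ploidy=2.0)
        assert call.copy_estimate == pytest.approx(4.0)

    def test_zero_baseline_uncallable(self):
        profile = make_profile([0.0] * 50)
        with pytest.raises(UncallableProfileError):
            call_copy_number(profile)

    def test_too_few_background_bins_rejected(self):
        profile = make_profile([40.0] * 8, region=(0, 200))
        with pytest.raises(UncallableProfileError):
            call_copy_number(profile)

    def test_genotype_recovery_sampled_copies(self):
        """Short parameter-recovery check; the full panel runs in acceptance."""
        for copies in (2, 7):
            hits = 0
            for s in range(20):
                profile = simulate_depth(500_000, REGION, copies, seed=1000 * copies + s)
                hits += call_copy_number(profile).genotype == copies
            assert hits == 20

    def test_median_baseline_robust_to_outliers(self):
        rng = np.random.default_rng(0)
        profile = simulate_depth(500_000, REGION, 6, seed=5)
        clean = call_copy_number(profile)
        noisy_counts = profile.counts.copy()
        _, background = profile._masks()
        bg_idx = np.flatnonzero(background)
        outliers = rng.choice(bg_idx, size=len(bg_idx) // 100, replace=False)
        noisy_counts[outliers] *= 10
        noisy = make_profile(noisy_counts, region=REGION)
        assert call_copy_number(noisy).baseline == pytest.approx(clean.baseline, rel=0.02)

    def test_copy_ratio_linearity(self):
        """Doubling the simulated copy number doubles the mean depth ratio."""
        ratios = {}
        for copies in (3, 6):
            ratios[copies] = np.mean(
                [
                    call_copy_number(
                        simulate_depth(500_000, REGION, copies, seed=s + 7000 * copies)
                    ).depth_ratio
                    for s in range(100)
                ]
            )
        assert ratios[6] == pytest.approx(2 * ratios[3], rel=0.05)


class TestCompareBinSizes:
    def test_constant_depth_identical_estimates(self):
        depth = np.ones(500_000)
        comparison = compare_bin_sizes(depth, REGION, sizes=[100, 200, 1000])
        estimates = {c.copy_estimate for c in comparison.calls.values()}
        assert len(comparison.calls) == 3
        assert estimates == {1.0}
        assert comparison.max_estimate_difference == 0.0

    def test_similar_estimates_at_100_and_200(self):
        profile = simulate_depth(500_000, REGION, 10, mean_bin_depth=0.2, bin_size=1, seed=3)
        comparison = compare_bin_sizes(profile.counts, REGION, sizes=[100, 200])
        assert abs(
            comparison.calls[100].copy_estimate - comparison.calls[200].copy_estimate
        ) < 0.5

    def test_small_bins_rejected(self):
        with pytest.raises(ValueError):
            compare_bin_sizes(np.ones(10_000), (0, 100), sizes=[10])

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValueError):
            compare_bin_sizes(np.ones(10_000), (0, 100), sizes=[])


def pearson_least_squares_oracle(x, y):
    """Closed-form slope/intercept/r^2, independent of the fit routine."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    syy = ((y - ym) ** 2).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2


class TestFitCopyTiter:
    def test_exact_colinearity(self):
        fit = fit_copy_titer([(1, 100), (2, 200), (3, 300)])
        assert fit.slope == pytest.approx(100)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.integers(1, 11, size=15).astype(float)
            if np.ptp(x) == 0:
                continue
            y = 30 * x + rng.normal(0, 20, size=15)
            fit = fit_copy_titer(list(zip(x, y)))
            slope, intercept, r2 = pearson_least_squares_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_invariant_to_affine_titer_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.integers(1, 11, size=12).astype(float)
        y = 25 * x + rng.normal(0, 10, size=12)
        base = fit_copy_titer(list(zip(x, y)))
        scaled = fit_copy_titer(list(zip(x, 3.5 * y + 100)))
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_copy_titer([(1, 100), (2, 200)])
        with pytest.raises(ValueError):
            fit_copy_titer([(2, 100), (2, 200), (2, 300)])


class TestIO:
    def test_depth_tsv_round_trip(self, tmp_path):
        profile = simulate_depth(20_000, (4_000, 6_000), 4, seed=8)
        path = tmp_path / "depth.tsv"
        write_depth_tsv(profile, path)
        back = read_depth_tsv(path, (4_000, 6_000))
        assert np.array_equal(back.counts, profile.counts)
        assert np.array_equal(back.starts, profile.starts)
        assert back.bin_size == profile.bin_size

    def test_base_depth_reader_fills_gaps(self, tmp_path):
        path = tmp_path / "base.txt"
        path.write_text("chr1\t1\t5\nchr1\t3\t7\nchr1\t6\t2\n")
        chrom, depth = read_base_depth(path)
        assert chrom == "chr1"
        assert depth.tolist() == [5.0, 0.0, 7.0, 0.0, 0.0, 2.0]

    def test_parse_region(self):
        assert parse_region("scaffold_1:250000-255000") == ("scaffold_1", 250_000, 255_000)
        with pytest.raises(ValueError):
            parse_region("chr1:500-100")
        with pytest.raises(ValueError):
            parse_region("no-coords")

    def test_profile_from_base_depth_sums_bins(self):
        depth = np.arange(400, dtype=float)
        profile = profile_from_base_depth(depth, 100, (0, 100))
        assert profile.counts.tolist() == [
            sum(range(0, 100)), sum(range(100, 200)),
            sum(range(200, 300)), sum(range(300, 400)),
        ]
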