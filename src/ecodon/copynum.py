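"""Read-depth copy-number genotyping of an integrated expression cassette.

Random integration delivers a transgene cassette in variable copy number.
With the cassette sequence appended to the reference genome, every copy in
the strain maps onto the single cassette region, so the region's read depth
relative to the genome-wide baseline estimates the copy number directly: in
a haploid host a depth ratio of k means k copies.  This module bins depth,
forms the ratio against a robust (median) baseline, rounds to an integer
genotype, and fits the downstream copy-number-vs-titer regression.  A depth
simulator provides Poisson or overdispersed (negative-binomial) synthetic
profiles for validation.

All intervals are 0-based half-open, including "chrom:start-end" strings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

Region = Tuple[int, int]


def parse_region(spec: str) -> Tuple[str, int, int]:
    """Parse "chrom:start-end" (0-based half-open) into (chrom, start, end)."""
    try:
        chrom, span = spec.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ValueError(f"malformed region spec {spec!r}; expected chrom:start-end") from None
    if not (0 <= start < end):
        raise ValueError(f"invalid region bounds in {spec!r}")
    return chrom, start, end


@dataclass
class DepthProfile:
    """Binned read depth over a reference augmented with a cassette region."""

    chrom: str
    bin_size: int
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    cassette_region: Region
    baseline_stat: str = "median"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if not (len(self.starts) == len(self.ends) == len(self.counts)):
            raise ValueError("starts, ends and counts must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("bins must have positive width")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("bins must tile the reference without overlap")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")
        if self.baseline_stat not in ("median", "mean"):
            raise ValueError("baseline_stat must be 'median' or 'mean'")

    def __len__(self) -> int:
        return len(self.counts)

    def _masks(self) -> Tuple[np.ndarray, np.ndarray]:
        """(cassette mask, baseline mask): cassette bins are fully inside the
        region; bins partially overlapping it belong to neither group, and
        truncated boundary bins are kept out of the baseline."""
        rs, re_ = self.cassette_region
        inside = (self.starts >= rs) & (self.ends <= re_)
        overlapping = (self.starts < re_) & (self.ends > rs)
        full_width = (self.ends - self.starts) == self.bin_size
        return inside, ~overlapping & full_width


@dataclass(frozen=True)
class RegionCall:
    """Copy-number call for the cassette region of one depth profile."""

    chrom: str
    region: Region
    bin_size: int
    n_region_bins: int
    mean_region_depth: float
    baseline: float
    depth_ratio: float
    copy_estimate: float
    genotype: int
    dispersion_sd: float
    ploidy: float = 1.0

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "region": f"{self.chrom}:{self.region[0]}-{self.region[1]}",
            "bin_size": self.bin_size,
            "n_region_bins": self.n_region_bins,
            "mean_region_depth": self.mean_region_depth,
            "baseline": self.baseline,
            "depth_ratio": self.depth_ratio,
            "copy_estimate": self.copy_estimate,
            "genotype": self.genotype,
            "dispersion_sd": self.dispersion_sd,
            "ploidy": self.ploidy,
        }


def round_half_away(x: float) -> int:
    """Round half away from zero (6.5 -> 7, -6.5 -> -7)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simulate_depth(
    reference_length: int,
    cassette_region: Region,
    copy_number: float,
    mean_bin_depth: float = 40.0,
    dispersion: float = 1.0,
    bin_size: int = 200,
    seed: Optional[int] = None,
    chrom: str = "ref",
    baseline_stat: str = "median",
) -> DepthProfile:
    """Simulate binned read depth with the cassette at ``copy_number`` copies.

    Non-cassette bins have mean ``mean_bin_depth``; bins inside the cassette
    have mean scaled by ``copy_number`` (partial-overlap bins are scaled by
    their overlap fraction).  ``dispersion`` is the variance-to-mean ratio:
    1 gives Poisson counts, > 1 negative-binomial.  A trailing bin shorter
    than ``bin_size`` is kept, truncated, with a warning.
    """
    rs, re_ = cassette_region
    if not (0 <= rs < re_ <= reference_length):
        raise ValueError("cassette_region must lie inside the reference")
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    if mean_bin_depth <= 0:
        raise ValueError("mean_bin_depth must be positive")
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1 (variance-to-mean ratio)")
    starts = np.arange(0, reference_length, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, reference_length)
    if reference_length % bin_size:
        warnings.warn(
            f"reference length {reference_length} is not a multiple of bin size "
            f"{bin_size}; final bin truncated to {int(ends[-1] - starts[-1])} bp",
            stacklevel=2,
        )
    overlap = np.clip(np.minimum(ends, re_) - np.maximum(starts, rs), 0, None)
    per_base = mean_bin_depth / bin_size
    mu = per_base * ((ends - starts - overlap) + overlap * copy_number)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(mu))
    pos = mu > 0
    if dispersion == 1:
        counts[pos] = rng.poisson(mu[pos])
    else:
        n = mu[pos] / (dispersion - 1)
        p = 1.0 / dispersion
        counts[pos] = rng.negative_binomial(n, p)
    return DepthProfile(
        chrom=chrom,
        bin_size=bin_size,
        starts=starts,
        ends=ends,
        counts=counts,
        cassette_region=cassette_region,
        baseline_stat=baseline_stat,
    )


class UncallableProfileError(ValueError):
    """Raised when a depth profile cannot support a copy-number call."""


def call_copy_number(profile: DepthProfile, ploidy: float = 1.0) -> RegionCall:
    """Genotype the cassette region from its depth ratio to the baseline.

    The baseline is the median (or mean) count over full-width bins outside
    the cassette; the genotype is the copy estimate (ratio x ploidy)
    rounded half away from zero.
    """
    inside, background = profile._masks()
    n_in = int(inside.sum())
    n_bg = int(background.sum())
    if n_in < 1:
        raise UncallableProfileError("no bins fully inside the cassette region")
    if n_bg < 10:
        raise UncallableProfileError(
            f"only {n_bg} non-cassette bins; at least 10 required for a baseline"
        )
    bg = profile.counts[background]
    baseline = float(np.median(bg) if profile.baseline_stat == "median" else np.mean(bg))
    if baseline <= 0:
        raise UncallableProfileError("baseline depth is zero; profile not callable")
    region_counts = profile.counts[inside]
    mean_region = float(region_counts.mean())
    ratio = mean_region / baseline
    estimate = ratio * ploidy
    sd = float(region_counts.std(ddof=1)) if n_in > 1 else 0.0
    return RegionCall(
        chrom=profile.chrom,
        region=profile.cassette_region,
        bin_size=profile.bin_size,
        n_region_bins=n_in,
        mean_region_depth=mean_region,
        baseline=baseline,
        depth_ratio=ratio,
        copy_estimate=estimate,
        genotype=round_half_away(estimate),
        dispersion_sd=sd,
        ploidy=ploidy,
    )


def profile_from_base_depth(
    base_depth: np.ndarray,
    bin_size: int,
    cassette_region: Region,
    chrom: str = "ref",
    baseline_stat: str = "median",
) -> DepthProfile:
    """Aggregate a per-base depth array into ``bin_size`` bins."""
    base_depth = np.asarray(base_depth, dtype=np.float64)
    length = len(base_depth)
    if length == 0:
        raise ValueError("empty per-base depth")
    starts = np.arange(0, length, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, length)
    counts = np.add.reduceat(base_depth, starts)
    if length % bin_size:
        warnings.warn(
            f"depth length {length} is not a multiple of bin size {bin_size}; "
            "final bin truncated",
            stacklevel=2,
        )
    return DepthProfile(
        chrom=chrom,
        bin_size=bin_size,
        starts=starts,
        ends=ends,
        counts=counts,
        cassette_region=cassette_region,
        baseline_stat=baseline_stat,
    )


DEFAULT_BIN_SIZES = (100, 200, 1000)


@dataclass(frozen=True)
class BinSizeComparison:
    """Copy-number calls at several bin sizes on one underlying depth signal."""

    calls: Dict[int, RegionCall]
    max_estimate_difference: float

    def to_dict(self) -> dict:
        return {
            "calls": {str(size): call.to_dict() for size, call in self.calls.items()},
            "max_estimate_difference": self.max_estimate_difference,
        }


def compare_bin_sizes(
    base_depth: np.ndarray,
    cassette_region: Region,
    sizes: Sequence[int] = DEFAULT_BIN_SIZES,
    chrom: str = "ref",
    baseline_stat: str = "median",
    ploidy: float = 1.0,
) -> BinSizeComparison:
    """Call the cassette copy number at each bin size on the same depth.

    Per-bin expected depth scales with bin size but the depth *ratio* does
    not, so estimates should agree up to sampling variance.
    """
    if not sizes:
        raise ValueError("sizes must be nonempty")
    for size in sizes:
        if size < 50:
            raise ValueError(f"bin size {size} too small; minimum is 50 bp")
    calls: Dict[int, RegionCall] = {}
    for size in sizes:
        profile = profile_from_base_depth(
            base_depth, size, cassette_region, chrom=chrom, baseline_stat=baseline_stat
        )
        calls[size] = call_copy_number(profile, ploidy=ploidy)
    estimates = [c.copy_estimate for c in calls.values()]
    max_diff = max(estimates) - min(estimates)
    return BinSizeComparison(calls=calls, max_estimate_difference=max_diff)


# -- copy-number vs titer regression -------------------------------------


@dataclass(frozen=True)
class TiterRegression:
    """Least-squares fit of product titer against cassette copy number."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


def fit_copy_titer(points: Iterable[Tuple[float, float]]) -> TiterRegression:
    """Fit titer ~ copy number by least squares.

    ``r_squared`` is the squared Pearson correlation and ``p_value`` the
    two-sided t-test of the slope with n - 2 degrees of freedom.
    """
    pts = [(float(c), float(t)) for c, t in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 strains, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all copy numbers equal; slope undefined")
    fit = stats.linregress(x, y)
    return TiterRegression(
        n=len(pts),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
    )


# -- plain-text I/O -------------------------------------------------------


def write_depth_tsv(profile: DepthProfile, path: Union[str, Path]) -> None:
    """Write bins as BED-like TSV: chrom, start, end, count."""
    with Path(path).open("w") as fh:
        for s, e, c in zip(profile.starts, profile.ends, profile.counts):
            fh.write(f"{profile.chrom}\t{s}\t{e}\t{c:g}\n")


def read_depth_tsv(
    path: Union[str, Path],
    cassette_region: Region,
    baseline_stat: str = "median",
) -> DepthProfile:
    """Read a BED-like depth TSV (chrom, start, end, count; no header)."""
    chroms: List[str] = []
    starts: List[int] = []
    ends: List[int] = []
    counts: List[float] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"line {line_no}: expected 4 tab-separated columns")
        chroms.append(fields[0])
        starts.append(int(fields[1]))
        ends.append(int(fields[2]))
        counts.append(float(fields[3]))
    if not counts:
        raise ValueError(f"no depth bins found in {path}")
    if len(set(chroms)) != 1:
        raise ValueError("depth profile must cover a single contig")
    widths = {e - s for s, e in zip(starts[:-1], ends[:-1])} or {ends[0] - starts[0]}
    bin_size = max(widths)
    return DepthProfile(
        chrom=chroms[0],
        bin_size=bin_size,
        starts=np.array(starts),
        ends=np.array(ends),
        counts=np.array(counts),
        cassette_region=cassette_region,
        baseline_stat=baseline_stat,
    )


def read_base_depth(path: Union[str, Path]) -> Tuple[str, np.ndarray]:
    """Read samtools-depth-style text (chrom, 1-based position, depth).

    Positions absent from the file get depth 0; returns (chrom, per-base
    depth array covering 1..max position).
    """
    chrom: Optional[str] = None
    positions: List[int] = []
    depths: List[float] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {line_no}: expected 3 whitespace-separated columns")
        if chrom is None:
            chrom = fields[0]
        elif fields[0] != chrom:
            raise ValueError("per-base depth must cover a single contig")
        positions.append(int(fields[1]))
        depths.append(float(fields[2]))
    if chrom is None:
        raise ValueError(f"no depth records found in {path}")
    out = np.zeros(max(positions), dtype=np.float64)
    out[np.array(positions) - 1] = depths
    return chrom, out
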