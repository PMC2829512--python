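"""Copy-number detection from binned, normalized read-depth ratios.

Per-base depth from each strain is averaged over fixed-width bins across
the mappable nuclear genome and normalized by that strain's total nuclear
bases; the per-bin log2 ratio (evolved/parent) is then median-centered so
the unamplified baseline sits at 0 even on small genomes, where a large
amplification contributes a non-negligible share of the total read mass.
Circular binary segmentation (CBS) partitions each chromosome into
regions of equal copy ratio: the algorithm recursively finds the circular
arc maximizing the two-sample |t| statistic between arc and complement
and splits while the arc is significant under a permutation null.
Adjacent segments whose means differ by less than a multiple of the
residual SD are merged, and segments spanning less than a minimum width
are absorbed into their more similar neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .mapping import DepthTrack, MappabilityMask, is_nuclear


@dataclass
class CbsParams:
    """Tuning knobs for segmentation.

    alpha: change-point significance level for the permutation test.
    n_permutations: permutations per test (early-stopped once futile).
    smooth_sd_multiplier: adjacent segments closer than this many residual
        SDs are merged.
    min_segment_span: segments narrower than this many bp are absorbed.
    seed: RNG seed for the permutation null.
    """

    alpha: float = 0.01
    n_permutations: int = 1000
    smooth_sd_multiplier: float = 3.0
    min_segment_span: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_segment_span < 1:
            raise ValueError("min_segment_span must be >= 1")


@dataclass
class BinSeries:
    """Binned, cross-strain-normalized log2 depth ratios for one chromosome.

    ``bin_index`` holds the 0-based bin numbers; bin b covers reference
    positions [b*width+1, (b+1)*width] (1-based inclusive; the final bin may
    be truncated at the chromosome end).  ``log2_ratio`` is defined only on
    usable bins.
    """

    chrom: str
    width: int
    chrom_length: int
    bin_index: np.ndarray  # all bins, 0..n_bins-1
    mean_evolved: np.ndarray
    mean_parent: np.ndarray
    log2_ratio: np.ndarray  # NaN on unusable bins
    usable: np.ndarray  # bool

    @property
    def n_bins(self) -> int:
        return self.bin_index.size

    def bin_start(self, b: int) -> int:
        return b * self.width + 1

    def bin_end(self, b: int) -> int:
        return min((b + 1) * self.width, self.chrom_length)


@dataclass
class Segment:
    """A constant-copy-number interval (1-based inclusive, bin-aligned)."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    uncertainty_bp: int

    @property
    def copy_ratio(self) -> float:
        return float(2.0 ** self.mean_log2)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def copy_ratio(segment: Segment) -> tuple[float, int, float]:
    """Copy-ratio estimate 2^(mean log2), its nearest integer, and the
    distance to that integer."""
    ratio = segment.copy_ratio
    nearest = max(0, int(round(ratio)))
    return ratio, nearest, abs(ratio - nearest)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def _bin_sums(values: np.ndarray, width: int, n_bins: int) -> np.ndarray:
    padded = np.zeros(n_bins * width, dtype=float)
    padded[: values.size] = values
    return padded.reshape(n_bins, width).sum(axis=1)


def bin_depth(
    depth_evolved: DepthTrack,
    depth_parent: DepthTrack,
    mask: MappabilityMask,
    width: int = 25,
    median_center: bool = True,
) -> dict[str, BinSeries]:
    """Average per-base depth over fixed bins of mappable positions,
    normalize by each strain's total nuclear bases, and form per-bin log2
    ratios (evolved/parent).

    Bins with no mappable positions or zero parent coverage are flagged
    unusable; the final partial bin must contain at least width/2 mappable
    positions.  Non-nuclear chromosomes are excluded.  With
    ``median_center`` the genome-wide median usable-bin log2 ratio is
    subtracted, putting the unchanged baseline at 0.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if set(depth_evolved.depth) != set(depth_parent.depth):
        raise ValueError("depth tracks cover different chromosome sets")
    total_e = depth_evolved.total_nuclear_bases
    total_p = depth_parent.total_nuclear_bases
    if total_e <= 0 or total_p <= 0:
        raise ValueError("empty depth track")

    out: dict[str, BinSeries] = {}
    for chrom in depth_evolved.depth:
        if not is_nuclear(chrom, depth_evolved.non_nuclear):
            continue
        de = depth_evolved.depth[chrom].astype(float)
        dp = depth_parent.depth[chrom].astype(float)
        m = mask[chrom].astype(float)
        if de.size != dp.size or de.size != m.size:
            raise ValueError(f"track/mask length mismatch on {chrom}")
        L = de.size
        n_bins = -(-L // width)
        n_mappable = _bin_sums(m, width, n_bins)
        sum_e = _bin_sums(de * m, width, n_bins)
        sum_p = _bin_sums(dp * m, width, n_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_e = sum_e / n_mappable
            mean_p = sum_p / n_mappable
        usable = (n_mappable > 0) & (sum_p > 0)
        # final partial bin: keep only with >= half-width mappable positions
        if L % width:
            if n_mappable[-1] < width / 2:
                usable[-1] = False
        ratio = np.full(n_bins, np.nan)
        ok = usable
        ratio[ok] = np.log2((mean_e[ok] / total_e) / (mean_p[ok] / total_p))
        out[chrom] = BinSeries(
            chrom=chrom,
            width=width,
            chrom_length=L,
            bin_index=np.arange(n_bins),
            mean_evolved=mean_e,
            mean_parent=mean_p,
            log2_ratio=ratio,
            usable=usable,
        )
    if median_center and out:
        all_ratios = np.concatenate([b.log2_ratio[b.usable] for b in out.values()])
        if all_ratios.size:
            center = float(np.median(all_ratios))
            for b in out.values():
                b.log2_ratio = b.log2_ratio - center
    return out


# ---------------------------------------------------------------------------
# Maximal-t arc search
# ---------------------------------------------------------------------------


@njit(cache=False, fastmath=True)
def _max_t_kernel(x: np.ndarray) -> tuple[int, int, float]:  # pragma: no cover
    # Maximize t^2 = diff^2 * (n-2) / (ss * (1/k + 1/m)) over all arcs
    # (i, i+k); the (n-2) factor is constant and dropped, and t^2 is kept as
    # a numerator/denominator pair so the inner loop is division-free.
    n = x.size
    S = np.empty(n + 1)
    Q = np.empty(n + 1)
    S[0] = 0.0
    Q[0] = 0.0
    for i in range(n):
        S[i + 1] = S[i] + x[i]
        Q[i + 1] = Q[i] + x[i] * x[i]
    tot_s = S[n]
    tot_q = Q[n]
    best_num = 0.0
    best_den = 1.0
    bi = 0
    bj = 0
    found = False
    found_inf = False
    # scale-relative degeneracy thresholds (float cancellation leaves
    # ~1e-13-relative residues even on exactly constant series)
    eps_ss = 1e-10 * tot_q
    eps_num = 1e-10 * (tot_q / n)
    for k in range(1, n):
        m = n - k
        inv_k = 1.0 / k
        inv_m = 1.0 / m
        cf = inv_k + inv_m
        for i in range(n - k + 1):
            s1 = S[i + k] - S[i]
            s2 = tot_s - s1
            ss = tot_q - s1 * s1 * inv_k - s2 * s2 * inv_m
            diff = s1 * inv_k - s2 * inv_m
            num = diff * diff
            den = ss * cf
            if ss <= eps_ss:
                # zero pooled variance: a perfect split (infinite t) unless
                # the means are equal too (constant series -> no candidate)
                if num > eps_num and not found_inf:
                    found_inf = True
                    found = True
                    bi = i
                    bj = i + k
                continue
            if found_inf:
                continue
            lhs = num * best_den
            rhs = best_num * den
            if lhs > rhs or (
                lhs == rhs and found and (i < bi or (i == bi and i + k < bj))
            ):
                best_num = num
                best_den = den
                bi = i
                bj = i + k
                found = True
    if not found or (not found_inf and best_num <= 0.0):
        return 0, 0, 0.0
    # signed t of the winning arc, with the dropped constants restored
    denom_df = n - 2 if n > 2 else 1
    k = bj - bi
    m = n - k
    s1 = S[bj] - S[bi]
    m1 = s1 / k
    m2 = (tot_s - s1) / m
    ss = tot_q - s1 * m1 - (tot_s - s1) * m2
    var = ss / denom_df * (1.0 / k + 1.0 / m)
    if ss <= eps_ss or var <= 1e-300:
        # perfect split: report an infinite t with the sign of the contrast
        t = math.inf if m1 > m2 else -math.inf
        return bi, bj, t
    t = (m1 - m2) / math.sqrt(var)
    return bi, bj, t


def max_t_split(series: Sequence[float]) -> tuple[int, int, float]:
    """Over all circular arcs of the series, return ``(i, j, t)`` for the arc
    ``series[i:j]`` (0-based half-open) maximizing |t| of arc mean versus
    complement mean with pooled variance.

    Because |t| is identical for an arc and its complement, scanning the
    contiguous arcs covers every circular arc.  Ties break to the smallest
    (i, j); a zero-variance series returns t = 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("series must have at least 4 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    i, j, t = _max_t_kernel(x)
    return int(i), int(j), float(t)


def _is_significant(
    x: np.ndarray, t_obs: float, params: CbsParams, rng: np.random.Generator
) -> bool:
    """Permutation test for the observed max |t|, early-stopped once the
    exceedance count makes significance impossible."""
    if abs(t_obs) == 0.0:
        return False
    allowed = int(math.floor(params.alpha * params.n_permutations))
    exceed = 0
    for _ in range(params.n_permutations):
        xp = rng.permutation(x)
        _, _, tp = _max_t_kernel(xp)
        if abs(tp) >= abs(t_obs):
            exceed += 1
            if exceed > allowed:
                return False
    return True


def cbs_segment(bins: BinSeries, params: CbsParams | None = None) -> list[Segment]:
    """Recursive circular binary segmentation of one chromosome's usable bins.

    Splits while the maximal-t arc is significant at ``params.alpha`` under a
    seeded permutation null; on termination adjacent segments tile the usable
    bins.  Deterministic for a fixed seed.
    """
    params = params or CbsParams()
    usable_idx = bins.bin_index[bins.usable]
    values = bins.log2_ratio[bins.usable]
    if usable_idx.size < 4:
        if usable_idx.size == 0:
            return []
        return [_make_segment(bins, usable_idx, values, 0, usable_idx.size)]
    rng = np.random.default_rng(params.seed)

    final: list[tuple[int, int]] = []
    stack = [(0, usable_idx.size)]
    while stack:
        lo, hi = stack.pop(0)
        n = hi - lo
        if n < 4:
            final.append((lo, hi))
            continue
        x = values[lo:hi]
        i, j, t = _max_t_kernel(x)
        if not _is_significant(x, t, params, rng):
            final.append((lo, hi))
            continue
        cuts = sorted({lo, lo + i, lo + j, hi})
        pieces = [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]
        if len(pieces) == 1:
            final.append((lo, hi))
        else:
            stack = pieces + stack
    final.sort()
    return [_make_segment(bins, usable_idx, values, lo, hi) for lo, hi in final]


def _make_segment(
    bins: BinSeries, usable_idx: np.ndarray, values: np.ndarray, lo: int, hi: int
) -> Segment:
    return Segment(
        chrom=bins.chrom,
        start=bins.bin_start(int(usable_idx[lo])),
        end=bins.bin_end(int(usable_idx[hi - 1])),
        n_bins=hi - lo,
        mean_log2=float(values[lo:hi].mean()),
        uncertainty_bp=bins.width,
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def _segment_bin_slices(segments: list[Segment], bins: BinSeries) -> list[np.ndarray]:
    usable_idx = bins.bin_index[bins.usable]
    starts = (usable_idx * bins.width + 1).astype(int)
    slices = []
    for seg in segments:
        sel = (starts >= seg.start) & (starts <= seg.end)
        slices.append(np.where(sel)[0])
    return slices


def _residual_sd(segments: list[Segment], bins: BinSeries) -> float:
    values = bins.log2_ratio[bins.usable]
    resid = []
    for seg, sl in zip(segments, _segment_bin_slices(segments, bins)):
        resid.append(values[sl] - seg.mean_log2)
    r = np.concatenate(resid) if resid else np.empty(0)
    return float(r.std()) if r.size > 1 else 0.0


def _merge(segments: list[Segment], bins: BinSeries, a: int) -> list[Segment]:
    values = bins.log2_ratio[bins.usable]
    slices = _segment_bin_slices(segments, bins)
    s1, s2 = segments[a], segments[a + 1]
    sl = np.concatenate([slices[a], slices[a + 1]])
    merged = Segment(
        chrom=s1.chrom,
        start=s1.start,
        end=s2.end,
        n_bins=s1.n_bins + s2.n_bins,
        mean_log2=float(values[sl].mean()),
        uncertainty_bp=s1.uncertainty_bp,
    )
    return segments[:a] + [merged] + segments[a + 2 :]


def smooth_segments(
    segments: list[Segment], bins: BinSeries, params: CbsParams | None = None
) -> list[Segment]:
    """Merge adjacent segments whose means differ by < multiplier x residual
    SD (recomputed until stable), then absorb segments spanning less than the
    minimum width into the more similar neighbor.  The output still tiles the
    usable bins."""
    params = params or CbsParams()
    segs = sorted(segments, key=lambda s: s.start)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        sd = _residual_sd(segs, bins)
        threshold = params.smooth_sd_multiplier * sd
        diffs = [abs(segs[a + 1].mean_log2 - segs[a].mean_log2) for a in range(len(segs) - 1)]
        a = int(np.argmin(diffs))
        if diffs[a] < threshold:
            segs = _merge(segs, bins, a)
            changed = True
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for a, seg in enumerate(segs):
            if seg.span < params.min_segment_span:
                if a == 0:
                    segs = _merge(segs, bins, 0)
                elif a == len(segs) - 1:
                    segs = _merge(segs, bins, a - 1)
                else:
                    d_prev = abs(seg.mean_log2 - segs[a - 1].mean_log2)
                    d_next = abs(seg.mean_log2 - segs[a + 1].mean_log2)
                    segs = _merge(segs, bins, a - 1 if d_prev <= d_next else a)
                changed = True
                break
    return segs


def segment_genome(
    bins_by_chrom: dict[str, BinSeries], params: CbsParams | None = None
) -> dict[str, list[Segment]]:
    """CBS plus smoothing for every (nuclear) chromosome."""
    params = params or CbsParams()
    out = {}
    for chrom, bins in bins_by_chrom.items():
        raw = cbs_segment(bins, params)
        out[chrom] = smooth_segments(raw, bins, params) if raw else []
    return out


def plot_segments(
    bins_by_chrom: dict[str, BinSeries],
    segments_by_chrom: dict[str, list[Segment]],
    path: str,
) -> None:
    """Simple per-chromosome scatter of bin log2 ratios with segment means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(bins_by_chrom)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.5 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        b = bins_by_chrom[chrom]
        pos = b.bin_index[b.usable] * b.width + b.width / 2
        ax.plot(pos, b.log2_ratio[b.usable], ".", ms=1, color="gray", alpha=0.5)
        for seg in segments_by_chrom.get(chrom, []):
            ax.plot([seg.start, seg.end], [seg.mean_log2] * 2, "r-", lw=2)
        ax.set_ylabel("log2 ratio")
        ax.set_title(chrom)
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
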