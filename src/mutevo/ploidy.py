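"""Two-step ploidy estimation from per-gene depth and allelic frequencies.

Step one treats the sample as diploid: the median read depth over all coding
regions defines the 2N level and each gene's median depth is converted to a
relative gene copy number (2 x gene/overall ratio).  Chromosomes, in
gene-ordinal space, are then partitioned by circular binary segmentation of
the log2 depth ratios.  Step two assigns each segment an absolute integer
copy number by matching the modes of its smoothed heterozygous-AF density to
the expected peak grid {k/N}: a diploid segment peaks at 50%, a triploid one
at 33% and 66%, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "Segment",
    "PloidyError",
    "relative_gcn",
    "cbs_segment",
    "cbs_max_t",
    "af_density",
    "density_modes",
    "peak_mismatch",
    "absolute_cn",
    "estimate_ploidy",
    "PloidyResult",
]


class PloidyError(ValueError):
    pass


@dataclass
class DepthProfile:
    """Ordered per-gene median depths, one row per gene ordinal."""

    table: pd.DataFrame  # columns: chrom, ordinal, gene, median_depth

    REQUIRED = ("chrom", "ordinal", "gene", "median_depth")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise PloidyError(f"depth profile missing columns {sorted(missing)}")
        if (self.table["median_depth"] < 0).any():
            raise PloidyError("negative median depth")
        self.table = self.table.sort_values(["chrom", "ordinal"]).reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom"):
            ords = sub["ordinal"].to_numpy()
            if len(set(ords)) != len(ords):
                raise PloidyError(f"duplicate ordinals on {chrom}")

    @property
    def overall_median(self) -> float:
        return float(self.table["median_depth"].median())

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class Segment:
    """A contiguous run of gene ordinals with one copy-number state."""

    chrom: str
    start: int  # 1-based ordinal, closed
    end: int
    mean_log2: float
    relative_gcn: float
    absolute_cn: Optional[int] = None
    n_afs: int = 0
    fit_score: float = float("nan")
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PloidyError(f"segment start {self.start} > end {self.end}")

    @property
    def n_ordinals(self) -> int:
        return self.end - self.start + 1


def relative_gcn(profile: DepthProfile) -> pd.DataFrame:
    """Per-gene relative copy number: 2 x (gene median / overall median)."""
    overall = profile.overall_median
    if overall <= 0:
        raise PloidyError("overall median depth is zero; cannot normalize")
    out = profile.table.copy()
    out["relative_gcn"] = 2.0 * out["median_depth"] / overall
    return out


def cbs_max_t(x: np.ndarray, min_seg: int) -> tuple[float, int, int]:
    """Max |t| over all circular arcs of ``x`` and the best arc [i, j).

    The statistic compares the in-arc mean against the out-of-arc mean with a
    pooled-variance two-sample t; arcs and complements shorter than
    ``min_seg`` are not considered.  Vectorized over arc starts per length.
    """
    n = len(x)
    total = x.sum()
    sq_total = (x * x).sum()
    # circular prefix sums over a doubled array
    xx = np.concatenate([x, x])
    csum = np.concatenate([[0.0], np.cumsum(xx)])
    csq = np.concatenate([[0.0], np.cumsum(xx * xx)])
    best_t, best_i, best_j = 0.0, 0, n
    for k in range(min_seg, n - min_seg + 1):
        starts = np.arange(n)
        s_in = csum[starts + k] - csum[starts]
        q_in = csq[starts + k] - csq[starts]
        n_in, n_out = k, n - k
        s_out = total - s_in
        q_out = sq_total - q_in
        mean_in = s_in / n_in
        mean_out = s_out / n_out
        ss = (q_in - n_in * mean_in**2) + (q_out - n_out * mean_out**2)
        dof = max(n - 2, 1)
        pooled = np.sqrt(np.maximum(ss / dof, 0.0) * (1.0 / n_in + 1.0 / n_out))
        diff = np.abs(mean_in - mean_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(diff == 0, 0.0, np.where(pooled > 0, diff / pooled, np.inf))
        idx = int(np.argmax(t))
        if t[idx] > best_t:
            best_t, best_i, best_j = float(t[idx]), idx, idx + k
    return best_t, best_i, best_j


def _segment_recursive(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_seg: int,
    breakpoints: set[int],
) -> None:
    n = len(x)
    if n < 2 * min_seg:
        return
    t_obs, i, j = cbs_max_t(x, min_seg)
    if t_obs <= 0:
        return
    exceed = 0
    for _ in range(n_perm):
        t_perm, _, _ = cbs_max_t(rng.permutation(x), min_seg)
        if t_perm >= t_obs:
            exceed += 1
    # add-one permutation p-value: never exactly 0, so alpha -> 0 is conservative
    p = (exceed + 1) / (n_perm + 1)
    if p > alpha:
        return
    # arc [i, j) may wrap; record the cut positions inside (0, n)
    cuts = sorted({i % n, j % n} - {0})
    if not cuts:
        return
    for c in cuts:
        breakpoints.add(offset + c)
    bounds = [0] + cuts + [n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        _segment_recursive(
            x[lo:hi], offset + lo, alpha, n_perm, rng, min_seg, breakpoints
        )


def cbs_segment(
    values: Sequence[float],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_seg: int = 3,
) -> list[int]:
    """Circular binary segmentation of one chromosome's ordered log2 ratios.

    Returns sorted interior breakpoints b (0 < b < n): the segment boundaries
    in 0-based half-open coordinates.  A candidate split is accepted when its
    max-|t| arc statistic beats ``alpha`` under a permutation null with
    ``n_perm`` shuffles (fixed ``seed``); recursion continues on both sides.
    ``alpha -> 0`` therefore yields a single segment for any input.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        return []
    rng = np.random.default_rng(seed)
    breakpoints: set[int] = set()
    _segment_recursive(x, 0, alpha, n_perm, rng, min_seg, breakpoints)
    return sorted(breakpoints)


def af_density(
    afs: Sequence[float],
    bandwidth: float = 0.03,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed density of allelic frequencies on [0, 1]."""
    afs = np.asarray(afs, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 1001)
    if len(afs) == 0:
        return grid, np.zeros_like(grid)
    if len(afs) <= 2000:
        z = (grid[:, None] - afs[None, :]) / bandwidth
        dens = np.exp(-0.5 * z * z).sum(axis=1)
    else:
        # binned KDE: histogram at 1e-3 resolution convolved with the kernel
        edges = np.arange(-0.0005, 1.0015, 0.001)
        hist, _ = np.histogram(np.clip(afs, 0.0, 1.0), bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        half = np.arange(0, 5 * bandwidth + 0.001, 0.001)
        kernel = np.exp(-0.5 * (np.concatenate([-half[:0:-1], half]) / bandwidth) ** 2)
        smooth = np.convolve(hist, kernel, mode="same")
        dens = np.interp(grid, centers, smooth)
    return grid, dens / (len(afs) * bandwidth * np.sqrt(2 * np.pi))


def density_modes(
    grid: np.ndarray,
    dens: np.ndarray,
    rel_height: float = 0.25,
) -> list[float]:
    """Local maxima of a density curve, keeping peaks >= rel_height x max."""
    if dens.max() <= 0:
        return []
    modes = []
    for i in range(1, len(dens) - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]:
            if dens[i] >= rel_height * dens.max():
                modes.append(float(grid[i]))
    if not modes:  # flat maximum edge case
        modes = [float(grid[int(np.argmax(dens))])]
    return modes


def peak_mismatch(modes: Sequence[float], n: int) -> float:
    """Symmetric mean distance between observed AF modes and the {k/N} grid."""
    expected = np.array([k / n for k in range(1, n)])
    modes = np.asarray(modes, dtype=float)
    if len(modes) == 0:
        return float("inf")
    d_mode = np.abs(modes[:, None] - expected[None, :]).min(axis=1).mean()
    d_exp = np.abs(expected[:, None] - modes[None, :]).min(axis=1).mean()
    return float(0.5 * (d_mode + d_exp))


def absolute_cn(
    rel_gcn: float,
    afs: Sequence[float],
    max_cn: int = 8,
    bandwidth: float = 0.03,
    min_afs: int = 10,
) -> tuple[int, float, bool]:
    """Integer copy number for one segment from its AF distribution.

    Returns ``(cn, fit_score, fallback)``.  Segments with relative GCN below
    0.5 are called homozygous deletions (the AF grid is undefined at N=0);
    segments with fewer than ``min_afs`` member AFs fall back to rounding the
    relative GCN.  Otherwise every candidate N in 1..max_cn is scored by
    :func:`peak_mismatch` and ties break toward the N nearest the relative GCN.
    """
    if rel_gcn < 0.5:
        return 0, float("nan"), False
    afs = [a for a in afs if 0.0 < a < 1.0]
    if len(afs) < min_afs:
        return max(int(round(rel_gcn)), 1), float("nan"), True
    grid, dens = af_density(afs, bandwidth=bandwidth)
    modes = density_modes(grid, dens)
    best_n, best_score = 2, float("inf")
    for n in range(1, max_cn + 1):
        if n == 1:
            # CN 1 has no het grid; treat as a single expected peak at 1.0
            # only reachable when AF mass sits near 1 (hemizygous alt)
            score = peak_mismatch(modes, 2) + 0.25
        else:
            score = peak_mismatch(modes, n)
        better = score < best_score - 1e-12
        tie = abs(score - best_score) <= 1e-12
        if better or (tie and abs(n - rel_gcn) < abs(best_n - rel_gcn)):
            best_n, best_score = n, score
    return best_n, best_score, False


@dataclass
class PloidyResult:
    """Per-segment absolute copy numbers plus the genome-wide CN summary."""

    segments: list[Segment]
    summary: dict[int, float]  # CN -> fraction of gene ordinals

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cn": list(self.summary), "fraction": list(self.summary.values())}
        )


def estimate_ploidy(
    profile: DepthProfile,
    variant_afs_by_gene: dict[str, list[float]],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    max_cn: int = 8,
    bandwidth: float = 0.03,
    min_afs: int = 10,
) -> PloidyResult:
    """Full two-step pipeline: relative GCN -> CBS -> AF-peak absolute CN.

    ``variant_afs_by_gene`` maps gene name to the heterozygous-variant AFs
    observed in that gene; a segment pools the AFs of its member genes.
    """
    gcn = relative_gcn(profile)
    segments: list[Segment] = []
    for chrom in profile.chroms():
        sub = gcn[gcn["chrom"] == chrom].sort_values("ordinal")
        ratios = np.log2(np.maximum(sub["relative_gcn"].to_numpy() / 2.0, 1e-6))
        cuts = cbs_segment(ratios, alpha=alpha, n_perm=n_perm, seed=seed)
        bounds = [0] + cuts + [len(sub)]
        ordinals = sub["ordinal"].to_numpy()
        genes = sub["gene"].to_numpy()
        rel = sub["relative_gcn"].to_numpy()
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg_afs: list[float] = []
            for g in genes[lo:hi]:
                seg_afs.extend(variant_afs_by_gene.get(g, []))
            seg_rel = float(np.mean(rel[lo:hi]))
            cn, score, fallback = absolute_cn(
                seg_rel, seg_afs, max_cn=max_cn, bandwidth=bandwidth, min_afs=min_afs
            )
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(ordinals[lo]),
                    end=int(ordinals[hi - 1]),
                    mean_log2=float(np.mean(np.log2(np.maximum(rel[lo:hi] / 2.0, 1e-6)))),
                    relative_gcn=seg_rel,
                    absolute_cn=cn,
                    n_afs=len(seg_afs),
                    fit_score=score,
                    fallback=fallback,
                )
            )
    total = sum(s.n_ordinals for s in segments)
    summary: dict[int, float] = {}
    for s in segments:
        summary[s.absolute_cn] = summary.get(s.absolute_cn, 0.0) + s.n_ordinals / total
    return PloidyResult(segments=segments, summary=dict(sorted(summary.items())))
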