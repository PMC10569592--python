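"""PBS/PBE temporal selection scan.

For a focal population and two non-focal populations, window FST values are
log-transformed into branch lengths d = -log(1 - FST); the population branch
statistic PBS = (d_f1 + d_f2 - d_12) / 2 estimates the focal branch length,
and population branch excess

    PBE = PBS - T * median(PBS) / median(T),      T = d_12,

subtracts the locus-specific expectation scaled from the non-focal pair's
branch, so loci where every branch is long (background selection, shared
sweeps) do not score. Outliers are the top 1% of window PBE; outlier windows
separated by at most 2 non-outlier windows merge into regions, within which
SNP-level PBE serves as a fine-mapping heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from museomics.datamodel import AlleleCounts, WindowSet
from museomics.diversity import fst, hudson_fst_components


def branch_lengths(fst_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """d = -log(1 - FST), flooring negative (noise) estimates at 0 first.

    FST = 1 is rejected (infinite branch; such windows are excluded
    upstream).
    """
    f = np.clip(np.asarray(fst_values, dtype=float), 0.0, None)
    if np.any(f >= 1.0):
        raise ValueError("FST = 1 gives an infinite branch length")
    return -np.log1p(-f)


def pbs(d_f1: np.ndarray, d_f2: np.ndarray, d_12: np.ndarray) -> np.ndarray:
    """Focal branch length from the three pairwise branch lengths."""
    return (np.asarray(d_f1) + np.asarray(d_f2) - np.asarray(d_12)) / 2.0


def pbe(
    pbs_values: np.ndarray,
    t_values: np.ndarray,
    median_ratio: float | None = None,
) -> tuple[np.ndarray, float]:
    """PBE per window and the genome-wide median(PBS)/median(T) ratio used.

    ``median_ratio`` may be supplied (e.g. to score SNPs with the window
    calibration); otherwise it is computed from the finite windows given.
    """
    pbs_values = np.asarray(pbs_values, dtype=float)
    t_values = np.asarray(t_values, dtype=float)
    if median_ratio is None:
        ok = np.isfinite(pbs_values) & np.isfinite(t_values)
        med_t = np.median(t_values[ok])
        if med_t <= 0:
            raise ValueError("median non-focal branch length is zero")
        median_ratio = float(np.median(pbs_values[ok]) / med_t)
    return pbs_values - t_values * median_ratio, median_ratio


def call_outliers(pbe_values: np.ndarray, quantile: float = 0.01) -> np.ndarray:
    """Boolean flag of the top ``quantile`` windows by PBE (ties included)."""
    v = np.asarray(pbe_values, dtype=float)
    finite = np.isfinite(v)
    n = int(finite.sum())
    k = max(1, math.ceil(quantile * n))
    threshold = np.sort(v[finite])[::-1][k - 1]
    return finite & (v >= threshold)


@dataclass
class OutlierRegion:
    chromosome: str
    start: int
    end: int
    windows: list
    max_pbe: float
    rank: int = 0
    genes: list = field(default_factory=list)


def merge_regions(
    outlier_flags: np.ndarray,
    windows: WindowSet,
    pbe_values: np.ndarray,
    max_gap: int = 2,
) -> list[OutlierRegion]:
    """Chain-merge outlier windows separated by <= max_gap non-outliers.

    Regions span first to last member window and are ranked by their
    maximal window PBE (rank 1 = highest).
    """
    idx = np.flatnonzero(outlier_flags)
    if idx.size == 0:
        return []
    groups: list[list[int]] = [[int(idx[0])]]
    for w in idx[1:]:
        if w - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(int(w))
        else:
            groups.append([int(w)])
    regions = [
        OutlierRegion(
            chromosome=windows.chromosome,
            start=int(windows.bounds[g[0], 0]),
            end=int(windows.bounds[g[-1], 1]),
            windows=g,
            max_pbe=float(np.max(pbe_values[g])),
        )
        for g in groups
    ]
    for rank, region in enumerate(
        sorted(regions, key=lambda r: -r.max_pbe), start=1
    ):
        region.rank = rank
    return sorted(regions, key=lambda r: r.start)


@dataclass
class ScanResult:
    windows: WindowSet
    table: pd.DataFrame  # per-window d/PBS/PBE columns
    regions: list
    median_ratio: float
    snp_table: pd.DataFrame | None = None


def run_scan(
    focal: AlleleCounts,
    out1: AlleleCounts,
    out2: AlleleCounts,
    windows: WindowSet,
    quantile: float = 0.01,
    max_gap: int = 2,
    snp_level: bool = True,
) -> ScanResult:
    """Window PBS/PBE scan of one focal population against two non-focal.

    Window FST is the ratio of summed Hudson components; windows with an
    undefined FST in any pair are dropped from outlier calling. SNP-level
    PBE is computed inside outlier regions only, calibrated with the
    window-level median ratio.
    """
    assign = {int(p): int(w) for p, w in
              zip(focal.positions, windows.assign(focal.positions))}
    n_w = windows.n_windows
    f_f1 = fst(focal, out1, assign, n_w)
    f_f2 = fst(focal, out2, assign, n_w)
    f_12 = fst(out1, out2, assign, n_w)
    ok = np.isfinite(f_f1) & np.isfinite(f_f2) & np.isfinite(f_12)
    ok &= (f_f1 < 1) & (f_f2 < 1) & (f_12 < 1)
    d_f1 = np.full(n_w, np.nan)
    d_f2 = np.full(n_w, np.nan)
    d_12 = np.full(n_w, np.nan)
    d_f1[ok] = branch_lengths(f_f1[ok])
    d_f2[ok] = branch_lengths(f_f2[ok])
    d_12[ok] = branch_lengths(f_12[ok])
    pbs_w = pbs(d_f1, d_f2, d_12)
    pbe_w, ratio = pbe(pbs_w, d_12)
    flags = np.zeros(n_w, dtype=bool)
    flags[np.isfinite(pbe_w)] = call_outliers(
        pbe_w[np.isfinite(pbe_w)], quantile
    )
    regions = merge_regions(flags, windows, pbe_w, max_gap)
    table = pd.DataFrame(
        {
            "window": np.arange(n_w),
            "start": windows.bounds[:, 0],
            "end": windows.bounds[:, 1],
            "fst_f1": f_f1,
            "fst_f2": f_f2,
            "fst_12": f_12,
            "d_f1": d_f1,
            "d_f2": d_f2,
            "d_12": d_12,
            "pbs": pbs_w,
            "pbe": pbe_w,
            "outlier": flags,
        }
    )
    snp_table = (
        snp_pbe(focal, out1, out2, windows, regions, ratio) if snp_level else None
    )
    return ScanResult(windows, table, regions, ratio, snp_table)


def snp_pbe(
    focal: AlleleCounts,
    out1: AlleleCounts,
    out2: AlleleCounts,
    windows: WindowSet,
    regions: Sequence[OutlierRegion],
    median_ratio: float,
) -> pd.DataFrame:
    """Per-SNP PBE inside outlier regions (fine-mapping heuristic).

    The same FST -> d -> PBS -> PBE chain is applied at single sites, with
    the genome-wide window median ratio as calibration; sites with an
    undefined FST in any pair are skipped.
    """
    pos1, num1, den1 = hudson_fst_components(focal, out1)
    pos2, num2, den2 = hudson_fst_components(focal, out2)
    pos3, num3, den3 = hudson_fst_components(out1, out2)
    common = np.intersect1d(np.intersect1d(pos1, pos2), pos3)
    rows = []
    region_bounds = [(r.start, r.end) for r in regions]
    if not region_bounds:
        return pd.DataFrame(columns=["pos", "pbs", "pbe", "region"])
    i1 = np.searchsorted(pos1, common)
    i2 = np.searchsorted(pos2, common)
    i3 = np.searchsorted(pos3, common)
    for c, a, b, d in zip(common, i1, i2, i3):
        p0 = int(c) - 1
        region_idx = next(
            (k for k, (s, e) in enumerate(region_bounds) if s <= p0 < e), None
        )
        if region_idx is None:
            continue
        dens = np.array([den1[a], den2[b], den3[d]])
        if np.any(dens <= 0):
            continue
        fsts = np.clip(
            np.array([num1[a], num2[b], num3[d]]) / dens,
            0.0,
            np.nextafter(1.0, 0.0),
        )
        d_trio = branch_lengths(fsts)
        site_pbs = float(pbs(d_trio[0], d_trio[1], d_trio[2]))
        site_pbe = site_pbs - d_trio[2] * median_ratio
        rows.append(
            {"pos": int(c), "pbs": site_pbs, "pbe": site_pbe, "region": region_idx}
        )
    return pd.DataFrame(rows, columns=["pos", "pbs", "pbe", "region"])


def annotate_regions(
    regions: Sequence[OutlierRegion], genes_df: pd.DataFrame
) -> None:
    """Attach overlapping gene IDs (from a GFF gene table) to each region."""
    for region in regions:
        sub = genes_df[genes_df["chrom"] == region.chromosome]
        hit = sub[(sub["start"] < region.end) & (sub["end"] > region.start)]
        region.genes = list(hit["gene_id"])
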