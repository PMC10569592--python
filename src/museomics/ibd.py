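"""Identity-by-descent detection and masking.

Relatedness between genomes and inbreeding within genomes are detected per
window (windows sized by reference-panel SNP content) from rescaled Hamming
distances, then converted to an interval mask:

* per-site distance between two genomes is the mismatch fraction over all
  cross-pairs of their alleles (4 comparisons diploid-diploid, 2
  haploid-diploid, 1 haploid-haploid), averaged over shared non-missing
  sites in the window;
* each genome's distances are rescaled by m_i = d_i / median(all focal
  vs. outgroup distances), where d_i is the genome's median distance to an
  unrelated outgroup panel, giving D'(i,j) = d(i,j) * m_i * m_j;
* a window is called IBD for a pair when D' falls below the midpoint
  between the expected IBD distance and the outbred baseline D: (7/8)D for
  diploid pairs (expected IBD distance (3/4)D, since 1 of 4 cross-pairs is
  identical), (3/4)D for haploid-diploid, (1/2)D for haploid-haploid;
* the baseline D (median pairwise D' among pairs with no obvious IBD) is
  circular, so it is iterated: flag, recompute excluding flagged pairs,
  repeat to convergence;
* a diploid whose within-window heterozygosity is below pi/2 (pi taken as
  the window's non-IBD median pairwise distance) is called inbred and one
  randomly chosen allele is masked;
* masking covers the called window plus the proximate halves of the two
  flanking windows, preferentially masking low-quality genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from museomics.datamodel import (
    GenotypeMatrix,
    MaskRecord,
    MaskTrack,
    SampleMeta,
    WindowSet,
)

_MAX_BASELINE_ITER = 5


@dataclass
class IBDCall:
    kind: str  # relatedness | inbreeding
    window: int
    sample_a: str
    sample_b: str | None
    value: float  # D'(i,j) for relatedness, heterozygosity for inbreeding
    threshold: float
    masked_sample: str | None = None
    masked_allele: int | None = None  # inbreeding only
    chromosome: str = ""


@dataclass
class DistanceWindowMatrix:
    """Per-window pairwise distances among focal genomes plus scaling data."""

    chromosome: str
    windows: WindowSet
    focal_samples: list[str]
    focal_ploidy: np.ndarray
    d: np.ndarray  # (n_windows, n_focal, n_focal), nan where undefined
    d_bg: np.ndarray  # (n_windows, n_focal): median distance vs outgroup
    bg_all_median: np.ndarray  # (n_windows,): median over all focal x outgroup
    m: np.ndarray | None = None
    d_prime: np.ndarray | None = None
    baseline: np.ndarray | None = None  # D per window
    flagged: np.ndarray | None = None  # boolean (n_windows, n_focal, n_focal)

    def pair_threshold_factor(self, i: int, j: int) -> float:
        p = int(self.focal_ploidy[i]) + int(self.focal_ploidy[j])
        return {4: 7 / 8, 3: 3 / 4, 2: 1 / 2}[p]


def _pairwise_window_distance(
    freq: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Mean cross-pair mismatch per window for every sample pair.

    ``freq`` is the (n_sites, n_samples) per-sample alt frequency with nan
    for missing; per-site distance is p_i + p_j - 2 p_i p_j.
    """
    n_w = len(lo)
    n = freq.shape[1]
    out = np.full((n_w, n, n), np.nan)
    for w in range(n_w):
        f = freq[lo[w] : hi[w]]
        if f.shape[0] == 0:
            continue
        present = ~np.isnan(f)
        fz = np.where(present, f, 0.0)
        both = present.astype(np.float64).T @ present.astype(np.float64)
        # sum over shared sites of p_i + p_j - 2 p_i p_j
        sum_p_shared = fz.T @ present.astype(np.float64)
        cross = fz.T @ fz
        total = sum_p_shared + sum_p_shared.T - 2.0 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            dw = np.where(both > 0, total / both, np.nan)
        out[w] = dw
    return out


def window_distances(
    matrix: GenotypeMatrix,
    windows: WindowSet,
    focal_samples: Sequence[str],
    outgroup_samples: Sequence[str],
) -> DistanceWindowMatrix:
    """Per-window pairwise distances among focal genomes and vs the outgroup."""
    if set(focal_samples) & set(outgroup_samples):
        raise ValueError("outgroup panel must be disjoint from focal samples")
    if not outgroup_samples:
        raise ValueError("outgroup panel is empty")
    freq = matrix.frequencies()
    site_w = windows.assign(matrix.positions)
    lo = np.searchsorted(site_w, np.arange(windows.n_windows), side="left")
    hi = np.searchsorted(site_w, np.arange(windows.n_windows), side="right")
    cols = {s: k for k, s in enumerate(matrix.samples)}
    idx = [cols[s] for s in list(focal_samples) + list(outgroup_samples)]
    sub = freq[:, idx]
    dist = _pairwise_window_distance(sub, lo, hi)
    nf = len(focal_samples)
    d_focal = dist[:, :nf, :nf].copy()
    d_cross = dist[:, :nf, nf:]
    with np.errstate(all="ignore"):
        d_bg = np.nanmedian(d_cross, axis=2)
        bg_all = np.nanmedian(d_cross.reshape(windows.n_windows, -1), axis=1)
    return DistanceWindowMatrix(
        chromosome=matrix.chromosome,
        windows=windows,
        focal_samples=list(focal_samples),
        focal_ploidy=np.array(
            [matrix.ploidy[cols[s]] for s in focal_samples], dtype=np.int8
        ),
        d=d_focal,
        d_bg=d_bg,
        bg_all_median=bg_all,
    )


def rescale_and_baseline(dwm: DistanceWindowMatrix) -> DistanceWindowMatrix:
    """Fill m_i scaling factors, D'(i,j), and the iterated baseline D.

    The baseline for a window is the median D' among pairs not flagged as
    IBD, resolved by iteration (flag, re-median excluding flagged pairs,
    repeat); windows left with fewer than 3 non-IBD pairs fall back to the
    chromosome-arm median.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        m = dwm.d_bg / dwm.bg_all_median[:, None]
    d_prime = dwm.d * m[:, :, None] * m[:, None, :]
    nf = len(dwm.focal_samples)
    iu = np.triu_indices(nf, k=1)
    factors = np.zeros((nf, nf))
    for i in range(nf):
        for j in range(nf):
            if i != j:
                factors[i, j] = dwm.pair_threshold_factor(i, j)

    n_w = dwm.windows.n_windows
    flagged = np.zeros((n_w, nf, nf), dtype=bool)
    baseline = np.full(n_w, np.nan)
    pair_vals = d_prime[:, iu[0], iu[1]]  # (n_w, n_pairs)
    pair_factors = factors[iu]
    for _ in range(_MAX_BASELINE_ITER):
        flat = flagged[:, iu[0], iu[1]]
        masked_vals = np.where(flat, np.nan, pair_vals)
        with np.errstate(all="ignore"):
            baseline = np.nanmedian(masked_vals, axis=1)
        ok_pairs = np.sum(~flat & ~np.isnan(pair_vals), axis=1)
        arm_vals = masked_vals[ok_pairs >= 3]
        arm_baseline = (
            np.nanmedian(arm_vals) if arm_vals.size else np.nanmedian(masked_vals)
        )
        baseline = np.where(ok_pairs >= 3, baseline, arm_baseline)
        new = pair_vals < pair_factors[None, :] * baseline[:, None]
        new &= ~np.isnan(pair_vals)
        new_flagged = np.zeros_like(flagged)
        new_flagged[:, iu[0], iu[1]] = new
        new_flagged[:, iu[1], iu[0]] = new
        if np.array_equal(new_flagged, flagged):
            break
        flagged = new_flagged
    dwm.m = m
    dwm.d_prime = d_prime
    dwm.baseline = baseline
    dwm.flagged = flagged
    return dwm


def classify_relatedness(dwm: DistanceWindowMatrix) -> list[IBDCall]:
    """Emit relatedness IBD calls from the rescaled distance matrix."""
    if dwm.flagged is None:
        raise ValueError("run rescale_and_baseline first")
    calls = []
    nf = len(dwm.focal_samples)
    for w in range(dwm.windows.n_windows):
        for i in range(nf):
            for j in range(i + 1, nf):
                if dwm.flagged[w, i, j]:
                    calls.append(
                        IBDCall(
                            kind="relatedness",
                            window=w,
                            sample_a=dwm.focal_samples[i],
                            sample_b=dwm.focal_samples[j],
                            value=float(dwm.d_prime[w, i, j]),
                            threshold=float(
                                dwm.pair_threshold_factor(i, j) * dwm.baseline[w]
                            ),
                            chromosome=dwm.chromosome,
                        )
                    )
    return calls


def classify_inbreeding(
    matrix: GenotypeMatrix,
    windows: WindowSet,
    pi_by_window: np.ndarray,
    focal_samples: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[IBDCall]:
    """Flag windows of depleted heterozygosity (< pi/2) in diploid genomes.

    ``pi_by_window`` is the per-window diversity reference, normally the
    non-IBD median pairwise distance (the relatedness baseline D). Haploid
    and pseudo-haploid samples are skipped. The masked allele (0 or 1) is a
    seeded random choice recorded on the call.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    focal = list(focal_samples) if focal_samples is not None else matrix.samples
    site_w = windows.assign(matrix.positions)
    calls = []
    for sid in focal:
        k = matrix.sample_index(sid)
        if matrix.ploidy[k] != 2:
            continue
        dosage = matrix.calls[:, k]
        present = dosage >= 0
        for w in range(windows.n_windows):
            pi = pi_by_window[w]
            if not np.isfinite(pi) or pi <= 0:
                continue
            in_w = (site_w == w) & present
            n = int(in_w.sum())
            if n == 0:
                continue
            het = float(np.mean(dosage[in_w] == 1))
            if het < pi / 2:
                calls.append(
                    IBDCall(
                        kind="inbreeding",
                        window=w,
                        sample_a=sid,
                        sample_b=None,
                        value=het,
                        threshold=pi / 2,
                        masked_sample=sid,
                        masked_allele=int(rng.integers(0, 2)),
                        chromosome=matrix.chromosome,
                    )
                )
    return calls


def _flank_interval(windows: WindowSet, w: int) -> tuple[int, int]:
    """Masked interval: window w plus proximate halves of flanking windows."""
    b = windows.bounds
    if w > 0:
        start = int((b[w - 1, 0] + b[w - 1, 1]) // 2)
    else:
        start = int(b[0, 0])
    if w < windows.n_windows - 1:
        end = int((b[w + 1, 0] + b[w + 1, 1] + 1) // 2)
    else:
        end = int(b[-1, 1])
    return start, end


def build_mask(
    calls: Sequence[IBDCall],
    windows: WindowSet,
    metas: Mapping[str, SampleMeta],
) -> MaskTrack:
    """Turn IBD calls into a MaskTrack with half-window flank extension.

    For each relatedness call exactly one pair member is masked: the
    low-quality member if tiers differ, otherwise the member with more
    windows already masked (concentrating data loss), with a lexicographic
    tie-break. Inbreeding calls mask one allele of the called sample over
    the same flank-extended interval.
    """
    track = MaskTrack()
    masked_windows: dict[str, set[int]] = {}
    chrom = windows.chromosome
    ordered = sorted(
        calls, key=lambda c: (c.window, c.kind, c.sample_a, c.sample_b or "")
    )
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for call in ordered:
        start, end = _flank_interval(windows, call.window)
        if call.kind == "relatedness":
            a, b = call.sample_a, call.sample_b
            tier_a, tier_b = metas[a].quality_tier, metas[b].quality_tier
            if tier_a != tier_b:
                victim = a if tier_a == "low" else b
            else:
                na = len(masked_windows.get(a, ()))
                nb = len(masked_windows.get(b, ()))
                if na != nb:
                    victim = a if na > nb else b
                else:
                    victim = max(a, b)
            call.masked_sample = victim
            masked_windows.setdefault(victim, set()).add(call.window)
            intervals.setdefault((victim, "relatedness"), []).append((start, end))
        else:
            call.masked_sample = call.sample_a
            intervals.setdefault((call.sample_a, "inbreeding"), []).append(
                (start, end)
            )
    for (sid, kind), ivs in intervals.items():
        for s, e in _merge_intervals(ivs):
            track.add(
                MaskRecord(
                    sample_id=sid,
                    chromosome=chrom,
                    start=s,
                    end=e,
                    kind=kind,
                    alleles_masked="all" if kind == "relatedness" else "one",
                )
            )
    return track


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_ibd(
    matrix: GenotypeMatrix,
    windows: WindowSet,
    focal_samples: Sequence[str],
    outgroup_samples: Sequence[str],
    metas: Mapping[str, SampleMeta],
    seed: int = 0,
) -> tuple[list[IBDCall], MaskTrack, DistanceWindowMatrix]:
    """Full per-chromosome IBD pass: distances, calls, mask."""
    dwm = window_distances(matrix, windows, focal_samples, outgroup_samples)
    rescale_and_baseline(dwm)
    rel = classify_relatedness(dwm)
    inb = classify_inbreeding(
        matrix, windows, dwm.baseline, focal_samples, seed=seed
    )
    mask = build_mask(rel + inb, windows, metas)
    return rel + inb, mask, dwm


def ibd_summary(
    calls: Sequence[IBDCall],
    mask: MaskTrack,
    windows_by_chrom: Mapping[str, WindowSet],
    chrom_lengths: Mapping[str, int],
    metas: Mapping[str, SampleMeta],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Masked-fraction summaries per sample and per pair.

    Per sample: fraction of each chromosome (and the genome) masked, split
    by kind. Per pair: fraction covered by relatedness-called windows (with
    flank extension) for that pair, regardless of which member was masked.
    """
    total_len = sum(chrom_lengths.values())
    sample_rows = []
    for sid in metas:
        for kind in ("relatedness", "inbreeding"):
            per_chrom = {}
            masked_total = 0
            for chrom, length in chrom_lengths.items():
                ivs = [
                    (r.start, min(r.end, length))
                    for r in mask.records
                    if r.sample_id == sid and r.chromosome == chrom and r.kind == kind
                ]
                covered = sum(e - s for s, e in _merge_intervals(ivs))
                per_chrom[chrom] = covered / length
                masked_total += covered
            sample_rows.append(
                {
                    "sample_id": sid,
                    "kind": kind,
                    "genome_fraction": masked_total / total_len,
                    **{f"frac_{c}": v for c, v in per_chrom.items()},
                }
            )
    pair_ivs: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for call in calls:
        if call.kind != "relatedness":
            continue
        ws = windows_by_chrom[_call_chrom(call, windows_by_chrom)]
        a, b = sorted([call.sample_a, call.sample_b])
        pair_ivs.setdefault((a, b, ws.chromosome), []).append(
            _flank_interval(ws, call.window)
        )
    pair_rows = []
    for (a, b, chrom), ivs in sorted(pair_ivs.items()):
        covered = sum(e - s for s, e in _merge_intervals(ivs))
        pair_rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "chromosome": chrom,
                "pair_fraction": covered / chrom_lengths[chrom],
            }
        )
    return (
        pd.DataFrame(sample_rows),
        pd.DataFrame(
            pair_rows, columns=["sample_a", "sample_b", "chromosome", "pair_fraction"]
        ),
    )


def _call_chrom(call: IBDCall, windows_by_chrom: Mapping[str, WindowSet]) -> str:
    if call.chromosome:
        return call.chromosome
    if len(windows_by_chrom) == 1:
        return next(iter(windows_by_chrom))
    raise ValueError("ambiguous chromosome for IBD call")
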