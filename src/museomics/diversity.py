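"""Diversity and differentiation statistics.

Within-population nucleotide diversity (pi), between-population Dxy, and
Hudson's two-population FST (per-site numerator/denominator terms aggregated
as a ratio of sums over windows), plus haplotype PCA and inversion frequency
estimation from marker panels. Allele counts are taken post-masking and may
be downsampled (hypergeometric, typically to 4 alleles per population) to
equalize sample sizes across cohorts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from museomics.datamodel import AlleleCounts


def _usable(counts: AlleleCounts, min_n: int = 2) -> np.ndarray:
    return counts.usable & (counts.n_total >= min_n)


def per_site_pi(counts: AlleleCounts) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*p*q*n/(n-1); nan where unusable."""
    n = counts.n_total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts.alt_count / n
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    pi[~_usable(counts)] = np.nan
    return pi


def nucleotide_diversity(counts: AlleleCounts) -> float:
    """Mean per-site pi over usable sites."""
    pi = per_site_pi(counts)
    if not np.any(np.isfinite(pi)):
        raise ValueError("no usable sites for nucleotide diversity")
    return float(np.nanmean(pi))


def _common_sites(a: AlleleCounts, b: AlleleCounts) -> tuple[np.ndarray, np.ndarray]:
    common, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    ok = _usable(a)[ia] & _usable(b)[ib]
    return ia[ok], ib[ok]


def per_site_dxy(a: AlleleCounts, b: AlleleCounts) -> tuple[np.ndarray, np.ndarray]:
    """(positions, per-site Dxy) over the shared usable site set."""
    ia, ib = _common_sites(a, b)
    if ia.size == 0:
        raise ValueError("populations share no usable sites")
    pa = a.alt_count[ia] / a.n_total[ia]
    pb = b.alt_count[ib] / b.n_total[ib]
    return a.positions[ia], pa * (1 - pb) + pb * (1 - pa)


def dxy(a: AlleleCounts, b: AlleleCounts) -> float:
    """Mean per-site between-population pairwise difference."""
    _, d = per_site_dxy(a, b)
    return float(d.mean())


def hudson_fst_components(
    a: AlleleCounts, b: AlleleCounts
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, numerator, denominator) of Hudson's FST per shared site.

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)
    """
    ia, ib = _common_sites(a, b)
    na = a.n_total[ia].astype(float)
    nb = b.n_total[ib].astype(float)
    pa = a.alt_count[ia] / na
    pb = b.alt_count[ib] / nb
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return a.positions[ia], num, den


def fst(
    a: AlleleCounts,
    b: AlleleCounts,
    window_of: Mapping[int, int] | np.ndarray | None = None,
    n_windows: int | None = None,
) -> float | np.ndarray:
    """Hudson FST as a ratio of summed components, clipped to [0, 1).

    Without ``window_of`` a single aggregate value is returned. With a
    per-position window assignment, per-window values are returned with nan
    for windows whose denominator sum is zero (excluded windows).
    """
    pos, num, den = hudson_fst_components(a, b)
    if window_of is None:
        total_den = den.sum()
        if total_den <= 0:
            raise ValueError("zero FST denominator over all shared sites")
        return float(np.clip(num.sum() / total_den, 0.0, np.nextafter(1.0, 0.0)))
    if isinstance(window_of, np.ndarray):
        widx = window_of
    else:
        widx = np.array([window_of.get(int(p), -1) for p in pos])
    if n_windows is None:
        n_windows = int(widx.max()) + 1
    out = np.full(n_windows, np.nan)
    for w in range(n_windows):
        sel = widx == w
        d = den[sel].sum()
        if d > 0:
            out[w] = np.clip(num[sel].sum() / d, 0.0, np.nextafter(1.0, 0.0))
    return out


def pca_haplotypes(hap_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a haplotype x site minor-allele (0/1) matrix.

    Computes all eigenvectors of the haplotype correlation matrix, so the
    component count equals the haplotype count (e.g. 35 components for 5
    haplotypes from each of 7 populations). Zero-variance sites are dropped.
    Returns (loadings, eigenvalues) with components ordered by decreasing
    eigenvalue; ``loadings[h, c]`` is haplotype h's loading on component c.
    """
    H = np.asarray(hap_matrix, dtype=float)
    keep = H.std(axis=0) > 0
    H = H[:, keep]
    if H.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic complete sites for PCA")
    R = np.corrcoef(H)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude entry of each component positive
    for c in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, c]))
        if vecs[pivot, c] < 0:
            vecs[:, c] = -vecs[:, c]
    return vecs, vals


def minor_allele_haplotypes(
    hap_matrix_alt: np.ndarray,
) -> np.ndarray:
    """Recode an alt-allele 0/1 haplotype matrix to minor-allele encoding."""
    H = np.asarray(hap_matrix_alt, dtype=np.int8)
    flip = H.mean(axis=0) > 0.5
    out = H.copy()
    out[:, flip] = 1 - out[:, flip]
    return out


def inversion_frequency(
    panel: pd.DataFrame,
    freq_lookup: Mapping[tuple[str, int], float],
) -> pd.Series:
    """Per-inversion frequency as the median over marker-site frequencies.

    ``panel`` rows carry (inversion, chrom, pos, linked_allele); markers with
    no data are dropped. The median (rather than the mean) keeps a handful
    of incompletely linked or error-derived marker alleles from producing a
    spurious nonzero frequency for an absent inversion.
    """
    out = {}
    for inv, grp in panel.groupby("inversion"):
        freqs = []
        for row in grp.itertuples(index=False):
            f = freq_lookup.get((row.chrom, int(row.pos)))
            if f is None or not np.isfinite(f):
                continue
            freqs.append(f if row.linked_allele == "alt" else 1.0 - f)
        out[inv] = float(np.median(freqs)) if freqs else np.nan
    series = pd.Series(out, name="inversion_frequency")
    if series.isna().all() and len(series):
        raise ValueError("all inversion markers missing")
    return series


def inversion_contrast(
    karyo_counts_a: tuple[int, int], karyo_counts_b: tuple[int, int]
) -> float:
    """Two-tailed Fisher exact p for a 2x2 karyotype count contrast."""
    table = np.array([karyo_counts_a, karyo_counts_b])
    if table.min() < 0:
        raise ValueError("karyotype counts must be nonnegative")
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def diversity_matrix(
    populations: Mapping[str, AlleleCounts],
) -> pd.DataFrame:
    """Square table with pi on the diagonal, FST below, Dxy above."""
    names = list(populations)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        out.loc[a, a] = nucleotide_diversity(populations[a])
        for b in names[i + 1 :]:
            out.loc[a, b] = dxy(populations[a], populations[b])
            out.loc[b, a] = fst(populations[a], populations[b])
    return out
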