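"""Pool-seq effective allele counts via the Stirling-number lineage model.

Pooled sequencing draws reads with replacement from the chromosomes of the
pooled flies, so the read count overstates the number of independently
sampled lineages. Given n_r reads at a site and n_c chromosomes in the pool
(240 for autosomes, 120 for an all-male pool's X), the number j of distinct
lineages sampled follows

    P(j | n_c, n_r) = S(n_r, j) * n_c! / (n_c - j)! / n_c^n_r,

where S(n_r, j) is a Stirling number of the second kind (the number of ways
to partition n_r reads into j nonempty lineages). The effective allele count
is the expectation of this distribution, which is used to downsample read
frequencies to a realistic per-site sample size. Stirling numbers are
computed by the triangular recurrence in log space (they overflow doubles
far below the read depths encountered).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

_log_table: np.ndarray | None = None


def log_stirling2_table(n_max: int) -> np.ndarray:
    """log S(n, k) for 0 <= k <= n <= n_max (-inf where S = 0), cached."""
    global _log_table
    if _log_table is not None and _log_table.shape[0] > n_max:
        return _log_table
    size = max(n_max + 1, 8)
    tab = np.full((size, size), -np.inf)
    tab[0, 0] = 0.0
    for n in range(1, size):
        k = np.arange(1, n + 1)
        # S(n,k) = k*S(n-1,k) + S(n-1,k-1), all terms nonnegative
        with np.errstate(divide="ignore"):
            a = np.log(k) + tab[n - 1, 1 : n + 1]
        b = tab[n - 1, 0:n]
        tab[n, 1 : n + 1] = np.logaddexp(a, b)
    _log_table = tab
    return tab


def lineage_distribution(n_r: int, n_c: int) -> np.ndarray:
    """P(j | n_c, n_r) for j = 0..min(n_r, n_c)."""
    if n_c < 1:
        raise ValueError("pool size n_c must be >= 1")
    if n_r < 0:
        raise ValueError("read count n_r must be >= 0")
    if n_r == 0:
        return np.array([1.0])
    tab = log_stirling2_table(n_r)
    j_max = min(n_r, n_c)
    j = np.arange(1, j_max + 1)
    log_fall = np.cumsum(np.log(n_c - np.arange(j_max)))  # log n_c!/(n_c-j)!
    logp = tab[n_r, 1 : j_max + 1] + log_fall - n_r * math.log(n_c)
    probs = np.zeros(j_max + 1)
    probs[1:] = np.exp(logp)  # not renormalized: the distribution sums to 1
    return probs


def effective_allele_count(n_r: int, n_c: int) -> tuple[float, int]:
    """Expected number of distinct lineages behind n_r reads, and its rounding.

    Equals the occupancy closed form n_c * (1 - (1 - 1/n_c)^n_r), which
    serves as an independent check on the Stirling-sum route.
    """
    probs = lineage_distribution(n_r, n_c)
    expect = float(np.dot(np.arange(len(probs)), probs))
    return expect, int(round(expect))


def call_pool_snps(pool: pd.DataFrame, min_minor_reads: int = 5) -> pd.DataFrame:
    """Flag sites as polymorphic when the minor read count meets the threshold.

    The default of 5 minor-allele reads guards against base-calling errors;
    the threshold is relaxed to 1 for the inversion assay, where even
    singleton minor alleles are informative.
    """
    if min_minor_reads < 1:
        raise ValueError("min_minor_reads must be >= 1")
    out = pool.copy()
    minor = np.minimum(out["ref_reads"], out["alt_reads"])
    depth = out["ref_reads"] + out["alt_reads"]
    out["polymorphic"] = (minor >= min_minor_reads) & (depth > 0)
    out["usable"] = depth > 0
    return out


def _largest_remainder(freqs: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainder."""
    raw = freqs * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def downsample_to_effective(pool: pd.DataFrame) -> pd.DataFrame:
    """Deterministically rescale read counts to effective allele counts.

    Per site the read frequency is multiplied by the (rounded) effective
    lineage count j_eff; allele counts are apportioned by largest remainder
    so they sum exactly to j_eff.
    """
    out = pool.copy()
    depth = (out["ref_reads"] + out["alt_reads"]).to_numpy(dtype=np.int64)
    n_c = out["n_c"].to_numpy(dtype=np.int64)
    j_eff_real = np.zeros(len(out))
    j_eff = np.zeros(len(out), dtype=np.int64)
    ref_ds = np.zeros(len(out), dtype=np.int64)
    alt_ds = np.zeros(len(out), dtype=np.int64)
    for i in range(len(out)):
        if depth[i] == 0:
            continue
        expect, rounded = effective_allele_count(int(depth[i]), int(n_c[i]))
        j_eff_real[i] = expect
        j_eff[i] = rounded
        f_alt = out["alt_reads"].iat[i] / depth[i]
        counts = _largest_remainder(np.array([1 - f_alt, f_alt]), rounded)
        ref_ds[i], alt_ds[i] = counts
    out["j_eff_real"] = j_eff_real
    out["j_eff"] = j_eff
    out["ref_ds"] = ref_ds
    out["alt_ds"] = alt_ds
    return out
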