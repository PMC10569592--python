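"""Per-genome quality profiling and quality-association tests.

Degraded historical DNA inflates sample-private variant calls, with cytosine
deamination (C->U read as T) biasing those errors toward A/T alleles. The
singleton profile tallies, for each genome, alleles observed exactly once
across the full panel at sites with no missing data, and the fraction of
those singleton alleles that are A or T. Association tests (Pearson r,
Mann-Whitney U, exact binomial) relate these metrics to per-sample
covariates such as read depth and genomic coverage, which are accepted as
metadata columns rather than computed from alignments.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from museomics.datamodel import GenotypeMatrix, SampleMeta


def singleton_profile(
    matrices: Mapping[str, GenotypeMatrix] | GenotypeMatrix,
    metas: Mapping[str, SampleMeta],
) -> pd.DataFrame:
    """Per-sample singleton counts and A/T fractions over complete sites.

    Only sites with zero missing data across the panel are considered. A
    singleton is an allele whose panel-wide count is exactly one; it is
    attributed to the unique carrying sample. Returns one row per sample:
    ``singleton_count``, ``singleton_fraction`` (of the panel total) and
    ``at_fraction`` (A/T share among that sample's singleton alleles).
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = {matrices.chromosome: matrices}
    mats = list(matrices.values())
    samples = mats[0].samples
    counts = np.zeros(len(samples), dtype=np.int64)
    at_counts = np.zeros(len(samples), dtype=np.int64)
    n_complete = 0
    for m in mats:
        if m.samples != samples:
            raise ValueError("matrices must share one sample panel")
        complete = np.all(m.calls >= 0, axis=1)
        if not np.any(complete):
            continue
        calls = m.calls[complete]
        ploidy = m.ploidy[None, :].astype(np.int64)
        alt_total = calls.astype(np.int64).sum(axis=1)
        ref_total = ploidy.sum() - alt_total
        is_at_alt = np.isin(m.alt[complete], ("A", "T"))
        is_at_ref = np.isin(m.ref[complete], ("A", "T"))
        n_complete += int(complete.sum())

        # alt-allele singletons: exactly one alt allele in the panel
        alt_single = alt_total == 1
        if np.any(alt_single):
            carrier = np.argmax(calls[alt_single] == 1, axis=1)
            np.add.at(counts, carrier, 1)
            np.add.at(at_counts, carrier, is_at_alt[alt_single].astype(np.int64))
        # ref-allele singletons: exactly one ref allele left in the panel
        ref_single = ref_total == 1
        if np.any(ref_single):
            has_ref = calls[ref_single] < ploidy
            carrier = np.argmax(has_ref, axis=1)
            np.add.at(counts, carrier, 1)
            np.add.at(at_counts, carrier, is_at_ref[ref_single].astype(np.int64))
    if n_complete == 0:
        raise ValueError("no sites free of missing data across the panel")
    total = counts.sum()
    with np.errstate(invalid="ignore"):
        at_frac = np.where(counts > 0, at_counts / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "era": [metas[s].era for s in samples],
            "quality_tier": [metas[s].quality_tier for s in samples],
            "singleton_count": counts,
            "singleton_fraction": counts / total if total else 0.0,
            "at_fraction": at_frac,
        }
    ).set_index("sample_id")


def association_tests(
    report: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    pairs: Sequence[tuple[str, str]] = (),
    group_tests: Sequence[tuple[str, str]] = (),
    binomial_tests: Sequence[tuple[int, int, float]] = (),
) -> pd.DataFrame:
    """Quality-association statistics table.

    ``pairs`` lists (x, y) column pairs for two-sided Pearson correlations;
    ``group_tests`` lists (value_column, group_column) for two-tailed
    Mann-Whitney U tests between the two groups of the group column; and
    ``binomial_tests`` lists (successes, trials, p0) for two-tailed exact
    binomial tests. A constant covariate makes the correlation undefined and
    is reported as NaN with a note.
    """
    data = report if covariates is None else report.join(covariates)
    rows = []
    for x, y in pairs:
        xv = data[x].astype(float).to_numpy()
        yv = data[y].astype(float).to_numpy()
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
        if len(xv) < 3:
            rows.append(_row("pearson", f"{x}~{y}", np.nan, np.nan, "fewer than 3 pairs"))
        elif np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append(_row("pearson", f"{x}~{y}", np.nan, np.nan, "constant covariate"))
        else:
            r, p = stats.pearsonr(xv, yv)
            rows.append(_row("pearson", f"{x}~{y}", r, p))
    for value_col, group_col in group_tests:
        groups = data[group_col].unique()
        if len(groups) != 2:
            raise ValueError(f"{group_col} must define exactly 2 groups")
        a = data.loc[data[group_col] == groups[0], value_col].astype(float)
        b = data.loc[data[group_col] == groups[1], value_col].astype(float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(_row("mannwhitney_u", f"{value_col}|{group_col}",
                         res.statistic, res.pvalue))
    for k, n, p0 in binomial_tests:
        res = stats.binomtest(k, n, p0, alternative="two-sided")
        rows.append(_row("binomial", f"{k}/{n} vs p0={p0}",
                         res.statistic, res.pvalue))
    return pd.DataFrame(rows, columns=["test", "what", "statistic", "p_value", "note"])


def _row(test, what, stat, p, note=""):
    return {"test": test, "what": what, "statistic": stat, "p_value": p, "note": note}
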