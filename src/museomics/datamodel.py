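"""Core data structures shared by all analysis stages.

Genotypes are stored as alternate-allele dosages per site per sample
(``-1`` = missing), with per-sample ploidy resolved per chromosome from the
sample metadata: males carry one X, and low-quality genomes are treated as
pseudo-haploid (a single called allele) on every chromosome.

Coordinates: VCF input/output is 1-based; all internal intervals (windows,
masks, BED) are half-open 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SEXES = ("male", "female", "unknown")
QUALITY_TIERS = ("high", "low")
MASK_KINDS = ("relatedness", "inbreeding")


@dataclass
class SampleMeta:
    """Per-sample metadata: era/location cohort labels, sex and quality tier.

    Ploidy is derived, not stored free-form: low-quality samples are
    pseudo-haploid everywhere; males are haploid on the X.
    """

    sample_id: str
    era: str
    location: str = ""
    sex: str = "unknown"
    quality_tier: str = "high"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.sample_id}")
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(
                f"unknown quality tier {self.quality_tier!r} for {self.sample_id}"
            )

    def ploidy(self, chromosome: str) -> int:
        if self.quality_tier == "low":
            return 1
        if chromosome in ("X", "chrX") and self.sex == "male":
            return 1
        return 2

    @property
    def population(self) -> str:
        return f"{self.era}_{self.location}" if self.location else self.era


@dataclass
class GenotypeMatrix:
    """Biallelic alt-dosage matrix for one chromosome.

    ``calls[s, k]`` is the alternate-allele dosage of sample *k* at site *s*
    in ``{0..ploidy}``, or ``-1`` if missing.
    """

    chromosome: str
    positions: np.ndarray  # 1-based, strictly increasing
    ref: np.ndarray  # per-site reference nucleotide
    alt: np.ndarray  # per-site alternate nucleotide
    calls: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str]
    ploidy: np.ndarray  # (n_samples,) per-sample ploidy on this chromosome
    length: int = 0  # chromosome length in bp (0 = unknown)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.calls.shape != (self.positions.size, len(self.samples)):
            raise ValueError("calls shape does not match positions x samples")
        observed = self.calls
        over = (observed >= 0) & (observed > self.ploidy[None, :])
        if np.any(over):
            s_idx, k_idx = np.argwhere(over)[0]
            raise ValueError(
                f"dosage exceeds ploidy for sample {self.samples[k_idx]} at "
                f"{self.chromosome}:{self.positions[s_idx]}"
            )
        if not self.length:
            self.length = int(self.positions[-1]) + 1 if self.positions.size else 0

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def frequencies(self) -> np.ndarray:
        """Per-site, per-sample alt frequency (nan where missing)."""
        with np.errstate(invalid="ignore"):
            freq = self.calls / self.ploidy[None, :].astype(float)
        freq[self.calls < 0] = np.nan
        return freq


@dataclass
class WindowSet:
    """Non-overlapping half-open windows tiling one chromosome.

    Built so each non-terminal window contains exactly ``snps_per_window``
    reference-panel SNPs; boundaries fall at midpoints between the flanking
    reference SNPs. A partial terminal window is retained and flagged.
    """

    chromosome: str
    bounds: np.ndarray  # (n_windows, 2) half-open 0-based
    snps_per_window: int
    snp_counts: np.ndarray
    partial_terminal: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    def assign(self, positions_1based: np.ndarray) -> np.ndarray:
        """Window index of each 1-based position (-1 if outside all windows)."""
        pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
        idx = np.searchsorted(self.bounds[:, 0], pos0, side="right") - 1
        idx[idx < 0] = -1
        inside = (idx >= 0) & (pos0 < self.bounds[np.clip(idx, 0, None), 1])
        idx[~inside] = -1
        return idx


def build_windows(
    ref_snp_positions: Sequence[int],
    snps_per_window: int,
    chromosome: str = "2L",
    chrom_length: int | None = None,
) -> WindowSet:
    """Partition a chromosome into windows of fixed reference-SNP content.

    Reference-panel SNP positions (1-based, sorted, unique) define window
    content; 25,000 SNPs per window is used for IBD detection, 250 for the
    selection scan. Fewer reference SNPs than ``snps_per_window`` yields a
    single chromosome-spanning window.
    """
    pos = np.asarray(ref_snp_positions, dtype=np.int64)
    if pos.size and (np.any(np.diff(pos) <= 0)):
        raise ValueError("reference SNP positions must be sorted and unique")
    if snps_per_window < 1:
        raise ValueError("snps_per_window must be >= 1")
    length = int(chrom_length) if chrom_length else (int(pos[-1]) + 1 if pos.size else 1)
    if pos.size < snps_per_window:
        bounds = np.array([[0, length]], dtype=np.int64)
        return WindowSet(chromosome, bounds, snps_per_window,
                         np.array([pos.size]), partial_terminal=True)
    n_full = pos.size // snps_per_window
    remainder = pos.size % snps_per_window
    cuts = []
    for k in range(1, n_full + (1 if remainder else 0)):
        left = pos[k * snps_per_window - 1] - 1  # 0-based
        right = pos[k * snps_per_window] - 1
        cuts.append((left + right + 1) // 2)
    edges = np.array([0] + cuts + [length], dtype=np.int64)
    bounds = np.stack([edges[:-1], edges[1:]], axis=1)
    counts = np.full(len(bounds), snps_per_window, dtype=np.int64)
    partial = bool(remainder)
    if partial:
        counts[-1] = remainder
    return WindowSet(chromosome, bounds, snps_per_window, counts, partial)


@dataclass(frozen=True)
class MaskRecord:
    sample_id: str
    chromosome: str
    start: int  # half-open 0-based
    end: int
    kind: str  # relatedness | inbreeding
    alleles_masked: str = "all"  # all | one

    def __post_init__(self) -> None:
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.kind == "relatedness" and self.alleles_masked != "all":
            raise ValueError("relatedness records mask all alleles of a sample")
        if self.kind == "inbreeding" and self.alleles_masked != "one":
            raise ValueError("inbreeding records mask exactly one allele")
        if self.end <= self.start:
            raise ValueError("empty mask interval")


@dataclass
class MaskTrack:
    """Interval-based per-sample allele masking with provenance."""

    records: list[MaskRecord] = field(default_factory=list)

    def add(self, record: MaskRecord) -> None:
        self.records.append(record)

    def for_chromosome(self, chromosome: str) -> list[MaskRecord]:
        return [r for r in self.records if r.chromosome == chromosome]

    def masked_alleles(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Number of alleles masked per site per sample (0, 1, or ploidy)."""
        out = np.zeros((matrix.n_sites, matrix.n_samples), dtype=np.int8)
        sample_idx = {s: i for i, s in enumerate(matrix.samples)}
        pos0 = matrix.positions - 1
        for rec in self.for_chromosome(matrix.chromosome):
            k = sample_idx.get(rec.sample_id)
            if k is None:
                continue
            in_iv = (pos0 >= rec.start) & (pos0 < rec.end)
            if rec.alleles_masked == "all":
                out[in_iv, k] = matrix.ploidy[k]
            else:
                out[in_iv, k] = np.maximum(out[in_iv, k], 1)
        return out


@dataclass
class SiteFilter:
    """Usability gate applied before population statistics.

    A total allele count of at least ``min_total_alleles`` (default 4) is
    required, singletons are optionally excluded, and sites inside an
    exclusion mask (e.g. low-recombination regions) are dropped.
    """

    min_total_alleles: int = 4
    exclude_singletons: bool = False
    exclusion_mask: Mapping[str, np.ndarray] | None = None  # chrom -> (n,2)

    def __post_init__(self) -> None:
        if self.min_total_alleles < 1:
            raise ValueError("min_total_alleles must be >= 1")

    def excluded_positions(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Boolean flag per (1-based) position: inside the exclusion mask."""
        if not self.exclusion_mask or chromosome not in self.exclusion_mask:
            return np.zeros(len(positions), dtype=bool)
        ivs = np.asarray(self.exclusion_mask[chromosome])
        pos0 = np.asarray(positions) - 1
        flag = np.zeros(len(pos0), dtype=bool)
        for start, end in ivs:
            flag |= (pos0 >= start) & (pos0 < end)
        return flag


@dataclass
class AlleleCounts:
    """Post-masking per-site allele bookkeeping for one cohort."""

    chromosome: str
    positions: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray
    usable: np.ndarray  # passes the site filter

    @property
    def n_total(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def frequencies(self) -> np.ndarray:
        n = self.n_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_count / n, np.nan)


def allele_counts(
    matrix: GenotypeMatrix,
    masks: MaskTrack | None = None,
    site_filter: SiteFilter | None = None,
    seed: int = 0,
) -> AlleleCounts:
    """Tally post-masking ref/alt allele counts per site.

    A relatedness-masked sample contributes no alleles inside the masked
    interval; an inbreeding-masked diploid contributes exactly one (for a
    heterozygous call the retained allele is a seeded coin flip). Missing
    calls contribute nothing. Sites failing the filter are flagged unusable
    rather than removed.
    """
    site_filter = site_filter or SiteFilter()
    calls = matrix.calls
    ploidy = matrix.ploidy[None, :].astype(np.int64)
    present = calls >= 0
    masked = (
        masks.masked_alleles(matrix).astype(np.int64)
        if masks is not None
        else np.zeros_like(calls, dtype=np.int64)
    )
    contributed = np.where(present, np.maximum(ploidy - masked, 0), 0)
    dosage = np.where(present, calls, 0).astype(np.int64)

    alt = np.zeros_like(contributed)
    full = contributed >= ploidy
    alt[full] = dosage[full]
    # inbreeding-masked diploids contribute one allele: hom keeps its allele,
    # het resolves by seeded coin flip
    one = (contributed == 1) & (ploidy == 2)
    if np.any(one):
        rng = np.random.default_rng(seed)
        coin = rng.integers(0, 2, size=calls.shape)
        alt_one = np.where(dosage == 2, 1, np.where(dosage == 1, coin, 0))
        alt[one] = alt_one[one]
    alt[contributed == 0] = 0

    n_total = contributed.sum(axis=1)
    alt_total = alt.sum(axis=1)
    ref_total = n_total - alt_total

    usable = n_total >= site_filter.min_total_alleles
    if site_filter.exclude_singletons:
        minor = np.minimum(ref_total, alt_total)
        usable &= minor != 1
    usable &= ~site_filter.excluded_positions(matrix.chromosome, matrix.positions)
    return AlleleCounts(
        matrix.chromosome,
        matrix.positions.copy(),
        ref_total,
        alt_total,
        usable,
    )


def downsample_counts(
    ref_count: int | np.ndarray,
    alt_count: int | np.ndarray,
    m: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample allele counts to ``m`` alleles without replacement.

    Hypergeometric draw of ``m`` alleles from the observed pool, e.g. the
    4-allele downsampling used for cross-population diversity comparisons.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ref = np.asarray(ref_count, dtype=np.int64)
    alt = np.asarray(alt_count, dtype=np.int64)
    total = ref + alt
    if np.any(total < m):
        raise ValueError(f"cannot downsample below m={m} alleles")
    alt_m = rng.hypergeometric(alt, ref, m)
    return (m - alt_m), alt_m
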