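"""Synthetic temporal cohorts with known truth.

The generator emulates the structure of a museum-genomics study: two small
historical cohorts of individually sequenced flies (mixed sex, a few genomes
pseudo-haploid due to low quality) plus a modern pool-seq cohort, with

* era-to-era Wright-Fisher drift of site frequencies at a configured Ne
  (15 generations per year),
* planted relatedness and inbreeding as copied haplotype segments,
* selective sweeps planted as deterministic logistic trajectories,
* deamination-style singleton errors whose A/T bias depends on genome quality,
* multinomial read sampling over the pool's allele pool for the modern cohort.

Sites are simulated as unlinked biallelic SNPs; founder frequencies follow a
symmetric Beta (folded-SFS-shaped) distribution. Every planted feature is
recorded in a :class:`TruthRecord` so downstream detectors can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from museomics.datamodel import GenotypeMatrix, SampleMeta

NUCLEOTIDES = np.array(["A", "C", "G", "T"])

# per-segment probability that one haplotype is copied, by relationship kind
_SHARE_PROB = {
    "parent_offspring": 1.0,
    "sib": 0.5,
    "second_order": 0.25,
}


@dataclass
class EraDesign:
    name: str
    year: int
    n_samples: int
    n_males: int = 0
    n_low_quality: int = 0
    location: str = "Lund"


@dataclass
class SweepSpec:
    """Deterministic logistic frequency trajectory planted at a site block.

    ``n_linked_sites`` > 1 emulates the hitchhiking footprint of a hard
    sweep: the trajectory is applied to that many consecutive sites
    starting at ``site_index``.
    """

    chromosome: str
    site_index: int
    start_freq: float
    end_freq: float
    era_from: str
    era_to: str
    n_linked_sites: int = 1


@dataclass
class RelationSpec:
    kind: str  # sib | parent_offspring | second_order | inbred
    sample_a: str
    sample_b: str | None = None  # None for inbred (within-genome IBD)


@dataclass
class DamageModel:
    """Per-quality-tier singleton error rate and A/T bias of injected errors."""

    rate_by_tier: dict = field(
        default_factory=lambda: {"high": 0.0, "low": 0.005}
    )
    at_bias_by_tier: dict = field(
        default_factory=lambda: {"high": 0.55, "low": 0.70}
    )


@dataclass
class PoolDesign:
    n_flies: int = 120
    mean_depth: float = 60.0
    all_male: bool = True  # X allele pool = n_flies rather than 2*n_flies


@dataclass
class SimConfig:
    seed: int = 0
    chromosomes: dict = field(default_factory=lambda: {"2L": 2_000_000, "X": 1_500_000})
    n_sites: int = 4000  # per chromosome
    eras: list = field(
        default_factory=lambda: [
            EraDesign("1800s", 1809, 9, n_males=3, n_low_quality=4),
            EraDesign("1933", 1933, 14, n_males=6, n_low_quality=2),
            EraDesign("2010s", 2015, 0),  # pool-seq only
        ]
    )
    ne_per_interval: list = field(default_factory=lambda: [3000.0, 3000.0])
    generations_per_year: int = 15
    founder_beta: tuple = (0.4, 0.4)
    missing_rate: float = 0.02
    pedigree: list = field(default_factory=list)
    damage: DamageModel = field(default_factory=DamageModel)
    sweeps: list = field(default_factory=list)
    pool_design: PoolDesign = field(default_factory=PoolDesign)
    ibd_segment_sites: int = 250  # granularity of planted IBD segments


@dataclass
class IBDSegment:
    kind: str  # relatedness | inbreeding
    sample_a: str
    sample_b: str | None
    chromosome: str
    start: int  # half-open 0-based bp
    end: int
    start_idx: int  # site-index interval (half-open)
    end_idx: int


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the synthetic cohorts."""

    ne_per_interval: list
    era_years: dict
    ibd_segments: list = field(default_factory=list)
    sweep_sites: list = field(default_factory=list)
    damage_positions: dict = field(default_factory=dict)
    pop_freqs: dict = field(default_factory=dict)  # chrom -> era -> freq array
    haplotypes: dict = field(default_factory=dict)  # (chrom, sample) -> array

    def segments_for_pair(self, a: str, b: str, chromosome: str) -> list:
        return [
            s
            for s in self.ibd_segments
            if s.chromosome == chromosome
            and s.kind == "relatedness"
            and {s.sample_a, s.sample_b} == {a, b}
        ]


def _drift_forward(freq: np.ndarray, n_hap: int, generations: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Iterate binomial Wright-Fisher resampling at haploid size n_hap."""
    f = freq.copy()
    for _ in range(generations):
        f = rng.binomial(n_hap, f) / n_hap
    return f


def _logistic_path(f0: float, f1: float, n_steps: int) -> np.ndarray:
    """Frequencies at n_steps+1 evenly spaced points from f0 to f1."""
    eps = 1e-6
    a = np.clip(f0, eps, 1 - eps)
    b = np.clip(f1, eps, 1 - eps)
    la, lb = np.log(a / (1 - a)), np.log(b / (1 - b))
    path = 1.0 / (1.0 + np.exp(-np.linspace(la, lb, n_steps + 1)))
    path[0], path[-1] = f0, f1
    return path


def _era_samples(era: EraDesign) -> list[SampleMeta]:
    metas = []
    for i in range(era.n_samples):
        sex = "male" if i < era.n_males else "female"
        # low-quality genomes are drawn from the females, mirroring the
        # greater decay of larger-bodied flies
        tier = "low" if i >= era.n_samples - era.n_low_quality else "high"
        metas.append(
            SampleMeta(
                sample_id=f"{era.name}_{i:02d}",
                era=era.name,
                location=era.location,
                sex=sex,
                quality_tier=tier,
            )
        )
    return metas


def simulate_cohorts(config: SimConfig) -> tuple[dict, dict, TruthRecord]:
    """Simulate genotype matrices for all eras plus the truth record.

    Returns ``(matrices, metas, truth)`` where ``matrices`` maps chromosome
    to a :class:`GenotypeMatrix` over all individually sequenced samples and
    ``truth.pop_freqs`` holds per-era population frequencies (the pool-seq
    cohort is sampled from the final era's frequencies separately).
    """
    rng = np.random.default_rng(config.seed)
    eras = config.eras
    if len(config.ne_per_interval) != len(eras) - 1:
        raise ValueError("need one Ne per consecutive era interval")
    metas: dict[str, SampleMeta] = {}
    for era in eras:
        for m in _era_samples(era):
            metas[m.sample_id] = m
    for rel in config.pedigree:
        for sid in (rel.sample_a, rel.sample_b):
            if sid is not None and sid not in metas:
                raise ValueError(f"pedigree references absent sample {sid}")

    truth = TruthRecord(
        ne_per_interval=list(config.ne_per_interval),
        era_years={e.name: e.year for e in eras},
    )
    matrices: dict[str, GenotypeMatrix] = {}
    for chrom, length in config.chromosomes.items():
        positions = np.sort(
            rng.choice(np.arange(1, length), size=config.n_sites, replace=False)
        )
        ref_idx = rng.integers(0, 4, size=config.n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
        ref = NUCLEOTIDES[ref_idx]
        alt = NUCLEOTIDES[alt_idx]

        # era-to-era population frequency trajectories; sweep overrides are
        # applied per era so later eras inherit (and drift from) the swept
        # frequency
        names = [e.name for e in eras]

        def apply_sweeps(era_idx: int, f: np.ndarray) -> None:
            for sw in config.sweeps:
                if sw.chromosome != chrom:
                    continue
                i0, i1 = names.index(sw.era_from), names.index(sw.era_to)
                if not i0 <= era_idx <= i1:
                    continue
                path = _logistic_path(sw.start_freq, sw.end_freq, i1 - i0)
                span = slice(
                    sw.site_index,
                    min(sw.site_index + sw.n_linked_sites, config.n_sites),
                )
                f[span] = path[era_idx - i0]

        freqs = {names[0]: rng.beta(*config.founder_beta, size=config.n_sites)}
        apply_sweeps(0, freqs[names[0]])
        for k, ne in enumerate(config.ne_per_interval):
            g = (eras[k + 1].year - eras[k].year) * config.generations_per_year
            freqs[names[k + 1]] = _drift_forward(
                freqs[names[k]], int(round(2 * ne)), g, rng
            )
            apply_sweeps(k + 1, freqs[names[k + 1]])
        for sw in config.sweeps:
            if sw.chromosome != chrom:
                continue
            stop = min(sw.site_index + sw.n_linked_sites, config.n_sites)
            for s in range(sw.site_index, stop):
                truth.sweep_sites.append((chrom, int(positions[s])))
        truth.pop_freqs[chrom] = {k: v.copy() for k, v in freqs.items()}

        # haplotypes per sample (before pseudo-haploid collapse)
        haps: dict[str, np.ndarray] = {}
        for era in eras:
            f = freqs[era.name]
            for m in _era_samples(era):
                n_hap = 1 if (chrom in ("X", "chrX") and m.sex == "male") else 2
                haps[m.sample_id] = (
                    rng.random((n_hap, config.n_sites)) < f[None, :]
                ).astype(np.int8)

        _plant_pedigree(config, chrom, positions, int(length), haps, truth, rng)
        for sid, h in haps.items():
            truth.haplotypes[(chrom, sid)] = h.copy()

        # collapse to calls; pseudo-haploid pick-one with seeded tie-break
        sample_ids = list(haps)
        ploidy = np.array(
            [metas[s].ploidy(chrom) for s in sample_ids], dtype=np.int8
        )
        calls = np.zeros((config.n_sites, len(sample_ids)), dtype=np.int8)
        for k, sid in enumerate(sample_ids):
            h = haps[sid]
            dosage = h.sum(axis=0).astype(np.int8)
            if ploidy[k] == 1 and h.shape[0] == 2:
                # pseudo-haploid: most frequent base; het ties broken at random
                pick = rng.integers(0, 2, size=config.n_sites)
                dosage = np.where(dosage == 1, pick, dosage // 2).astype(np.int8)
            calls[:, k] = dosage
        if config.missing_rate > 0:
            miss = rng.random(calls.shape) < config.missing_rate
            calls[miss] = -1
        matrices[chrom] = GenotypeMatrix(
            chromosome=chrom,
            positions=positions,
            ref=ref,
            alt=alt,
            calls=calls,
            samples=sample_ids,
            ploidy=ploidy,
            length=int(length),
        )
    return matrices, metas, truth


def _plant_pedigree(
    config: SimConfig,
    chrom: str,
    positions: np.ndarray,
    length: int,
    haps: dict[str, np.ndarray],
    truth: TruthRecord,
    rng: np.random.Generator,
) -> None:
    """Copy haplotype segments between/within genomes per the pedigree spec."""
    n_sites = config.n_sites
    seg = config.ibd_segment_sites
    edges = list(range(0, n_sites, seg)) + [n_sites]
    for rel in config.pedigree:
        if rel.kind == "inbred":
            h = haps[rel.sample_a]
            if h.shape[0] < 2:
                continue
            for lo, hi in zip(edges[:-1], edges[1:]):
                if rng.random() < 0.5:
                    h[1, lo:hi] = h[0, lo:hi]
                    truth.ibd_segments.append(
                        _segment("inbreeding", rel.sample_a, None, chrom,
                                 positions, length, lo, hi)
                    )
            continue
        p_share = _SHARE_PROB[rel.kind]
        ha, hb = haps[rel.sample_a], haps[rel.sample_b]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if rng.random() < p_share:
                ia = rng.integers(0, ha.shape[0])
                ib = rng.integers(0, hb.shape[0])
                hb[ib, lo:hi] = ha[ia, lo:hi]
                truth.ibd_segments.append(
                    _segment("relatedness", rel.sample_a, rel.sample_b, chrom,
                             positions, length, lo, hi)
                )


def _segment(kind, a, b, chrom, positions, length, lo, hi) -> IBDSegment:
    start = int(positions[lo]) - 1
    end = int(positions[hi - 1])  # inclusive last site -> half-open bp
    return IBDSegment(kind, a, b, chrom, start, end, lo, hi)


def inject_damage(
    matrix: GenotypeMatrix,
    metas: dict[str, SampleMeta],
    damage: DamageModel,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, dict[str, list[int]]]:
    """Inject deamination-style singleton errors private to single samples.

    For each sample, sites at which the panel is monomorphic-reference (and
    the sample call is present) are candidates; a binomial number of them
    (site count x tier rate) receive a private derived allele. The error
    allele is A or T with the tier's configured bias (cytosine deamination
    reads C->T / G->A, inflating A/T singletons), otherwise C or G.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    calls = matrix.calls.copy()
    alt = matrix.alt.copy()
    injected: dict[str, list[int]] = {}
    alt_total = np.where(calls > 0, calls, 0).sum(axis=1)
    available = alt_total == 0  # monomorphic reference in the panel
    for k, sid in enumerate(matrix.samples):
        tier = metas[sid].quality_tier
        rate = damage.rate_by_tier.get(tier, 0.0)
        if rate <= 0:
            continue
        candidates = np.flatnonzero(available & (calls[:, k] == 0))
        n_err = rng.binomial(matrix.n_sites, rate)
        n_err = min(n_err, candidates.size)
        if n_err == 0:
            injected[sid] = []
            continue
        sites = rng.choice(candidates, size=n_err, replace=False)
        available[sites] = False
        calls[sites, k] = 1  # one damaged allele (het on diploids)
        bias = damage.at_bias_by_tier.get(tier, 0.55)
        for s in sites:
            to_at = rng.random() < bias
            pool = ("A", "T") if to_at else ("C", "G")
            choices = [b for b in pool if b != matrix.ref[s]]
            alt[s] = choices[rng.integers(0, len(choices))]
        injected[sid] = sorted(int(matrix.positions[s]) for s in sites)
    new = GenotypeMatrix(
        chromosome=matrix.chromosome,
        positions=matrix.positions.copy(),
        ref=matrix.ref.copy(),
        alt=alt,
        calls=calls,
        samples=list(matrix.samples),
        ploidy=matrix.ploidy.copy(),
        length=matrix.length,
    )
    return new, injected


def simulate_poolseq_reads(
    freqs: np.ndarray,
    positions: np.ndarray,
    chromosome: str,
    design: PoolDesign,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample pool-seq read counts from population frequencies.

    A pool of ``n_flies`` flies is drawn from the population (allele pool of
    2*n_flies chromosomes on autosomes, or n_flies on the X for an all-male
    pool); per-site read depth is Poisson and reads are binomial over the
    realized pool allele frequency.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    is_x = chromosome in ("X", "chrX")
    n_pool = design.n_flies if (is_x and design.all_male) else 2 * design.n_flies
    pool_alt = rng.binomial(n_pool, freqs)
    depth = rng.poisson(design.mean_depth, size=len(freqs))
    alt_reads = rng.binomial(depth, pool_alt / n_pool)
    return pd.DataFrame(
        {
            "chrom": chromosome,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref_reads": depth - alt_reads,
            "alt_reads": alt_reads,
            "n_c": n_pool,
        }
    )


def make_toy_annotation(
    chrom_lengths: dict,
    n_genes: int = 100,
    n_terms: int = 20,
    terms_per_gene: tuple = (1, 5),
    n_clustered_terms: int = 0,
    cluster_size: int = 5,
    inversion_markers: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy gene annotation, gene->GO map, and inversion marker panel.

    Genes tile the chromosomes (proportionally to length) with gaps; each
    gene carries 1-5 random GO terms. ``n_clustered_terms`` extra terms are
    each assigned to a run of physically adjacent genes, exercising the
    clustering-control property of region-permutation enrichment.
    ``inversion_markers`` maps inversion name -> (chrom, positions array);
    markers report the alt allele as inversion-linked.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    total = sum(chrom_lengths.values())
    genes = []
    gid = 0
    for chrom, length in chrom_lengths.items():
        k = max(1, round(n_genes * length / total))
        pitch = length // k
        glen = max(200, int(pitch * 0.6))
        for i in range(k):
            start = i * pitch + (pitch - glen) // 2
            genes.append(
                {"chrom": chrom, "start": start, "end": start + glen,
                 "gene_id": f"gene{gid:04d}"}
            )
            gid += 1
    genes_df = pd.DataFrame(genes)

    go_rows = []
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    for g in genes_df["gene_id"]:
        k = rng.integers(terms_per_gene[0], terms_per_gene[1] + 1)
        for t in rng.choice(terms, size=k, replace=False):
            go_rows.append({"gene_id": g, "go_term": t})
    for c in range(n_clustered_terms):
        start = int(rng.integers(0, max(1, len(genes_df) - cluster_size)))
        for g in genes_df["gene_id"].iloc[start : start + cluster_size]:
            go_rows.append({"gene_id": g, "go_term": f"GO:clustered{c:02d}"})
    go_df = pd.DataFrame(go_rows).drop_duplicates()

    inv_rows = []
    for name, (chrom, marker_pos) in (inversion_markers or {}).items():
        for p in marker_pos:
            inv_rows.append(
                {"inversion": name, "chrom": chrom, "pos": int(p),
                 "linked_allele": "alt"}
            )
    inv_df = pd.DataFrame(
        inv_rows, columns=["inversion", "chrom", "pos", "linked_allele"]
    )
    return genes_df, go_df, inv_df


def write_gff(genes_df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes_df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tmuseomics\tgene\t{row.start + 1}\t{row.end}\t."
                f"\t+\t.\tID={row.gene_id}\n"
            )


def write_manifest(config: SimConfig, truth: TruthRecord, path: str | Path) -> None:
    """JSON manifest recording the generating config and scalar truth."""
    payload = {
        "config": {
            "seed": config.seed,
            "chromosomes": config.chromosomes,
            "n_sites": config.n_sites,
            "eras": [asdict(e) for e in config.eras],
            "ne_per_interval": config.ne_per_interval,
            "generations_per_year": config.generations_per_year,
            "founder_beta": list(config.founder_beta),
            "missing_rate": config.missing_rate,
        },
        "truth": {
            "ne_per_interval": truth.ne_per_interval,
            "era_years": truth.era_years,
            "n_ibd_segments": len(truth.ibd_segments),
            "sweep_sites": [[c, int(p)] for c, p in truth.sweep_sites],
            "damage_positions": truth.damage_positions,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def scan_trio_fixture(
    seed: int,
    sweep: bool = True,
    n_windows: int = 200,
    snps_per_window: int = 10,
    n_alleles: int = 40,
    focal_shift: float = 0.0,
    outgroup_shift: float = 0.0,
):
    """Three-population window counts for scan power/specificity experiments.

    Frequencies for the focal and two non-focal populations share a common
    Beta(2,2) base with small independent jitter; optional ``focal_shift``
    or ``outgroup_shift`` add extra per-site divergence, and ``sweep``
    plants one window of near-fixed focal-specific differentiation. Returns
    ``(windows, focal_counts, out1_counts, out2_counts, sweep_window)``
    where counts are binomial samples of ``n_alleles`` alleles per site.
    """
    from museomics.datamodel import AlleleCounts, WindowSet

    rng = np.random.default_rng(seed)
    n_sites = n_windows * snps_per_window
    positions = np.arange(n_sites) * 100 + 51
    base = rng.beta(2, 2, n_sites)

    def jitter():
        return np.clip(base + rng.normal(0, 0.05, n_sites), 0.01, 0.99)

    f_focal, f_o1, f_o2 = jitter(), jitter(), jitter()
    if focal_shift:
        f_focal = np.clip(
            f_focal + rng.normal(0, focal_shift, n_sites), 0.01, 0.99
        )
    if outgroup_shift:
        f_o1 = np.clip(f_o1 + rng.normal(0, outgroup_shift, n_sites), 0.01, 0.99)
        f_o2 = np.clip(f_o2 - rng.normal(0, outgroup_shift, n_sites), 0.01, 0.99)
    sweep_window = None
    if sweep:
        sweep_window = int(rng.integers(0, n_windows))
        lo = sweep_window * snps_per_window
        hi = lo + snps_per_window
        f_focal[lo:hi] = np.clip(f_o1[lo:hi] + 0.75, 0, 0.99)
    windows = WindowSet(
        "2L",
        np.array(
            [[i * snps_per_window * 100, (i + 1) * snps_per_window * 100]
             for i in range(n_windows)]
        ),
        snps_per_window,
        np.full(n_windows, snps_per_window),
    )

    def counts(f):
        alt = rng.binomial(n_alleles, f)
        return AlleleCounts(
            "2L", positions, n_alleles - alt, alt,
            np.ones(n_sites, dtype=bool),
        )

    return windows, counts(f_focal), counts(f_o1), counts(f_o2), sweep_window
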