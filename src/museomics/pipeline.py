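"""End-to-end pipeline: simulate -> qc -> ibd-mask -> pool-counts -> stats ->
ne-fit -> scan -> enrich, with one global seed deriving per-stage seeds.

Stage defaults are the production parameters: 25,000-SNP IBD windows and 250-SNP
scan windows, minimum total allele count 4, pool minor-allele threshold 5,
N* grid 1,000..20,000 step 1,000 refined in steps of 100 with 1,000
replicates, top-1% outliers merged across gaps of at most 2 windows, 10,000
enrichment permutations, 15 generations per year and a site mutation rate
of 5.21e-10. The synthetic driver scales window SNP content down with the
simulated site count so small cohorts still yield multi-window chromosomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from museomics import __version__
from museomics.datamodel import SiteFilter, allele_counts
from museomics.demography import (
    TemporalFreqData,
    TerminalDesign,
    fit_ne,
    generations_between,
)
from museomics.diversity import diversity_matrix, inversion_frequency
from museomics.enrichment import AnnotationIndex, permutation_pvalues
from museomics.ibd import detect_ibd, ibd_summary
from museomics.poolseq import call_pool_snps, downsample_to_effective
from museomics.qc import association_tests, singleton_profile
from museomics.scan import annotate_regions, run_scan
from museomics.simulate import (
    DamageModel,
    SimConfig,
    inject_damage,
    make_toy_annotation,
    simulate_cohorts,
    simulate_poolseq_reads,
    write_gff,
    write_manifest,
)
from museomics.datamodel import build_windows
from museomics import vcfio

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "qc", "ibd", "pool", "stats", "nefit", "scan", "enrich",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulation
    n_sites: int = 4000
    chromosomes: dict = field(default_factory=lambda: {"2L": 2_000_000, "X": 1_500_000})
    ne_per_interval: list = field(default_factory=lambda: [3000.0, 3000.0])
    n_sweeps: int = 2
    damage_rate_low: float = 0.004
    damage_at_bias_low: float = 0.70
    # windows
    ibd_window_snps: int = 1000  # scaled-down analogue of the 25,000-SNP windows
    scan_window_snps: int = 50  # scaled-down analogue of the 250-SNP windows
    # filtering
    min_alleles: int = 4
    pool_min_minor: int = 5
    # Ne fit
    grid_min: int = 1000
    grid_max: int = 20000
    grid_step: int = 1000
    refine_step: int = 100
    reps: int = 1000
    gens_per_year: int = 15
    nefit_max_sites: int = 150
    # scan / enrichment
    quantile: float = 0.01
    max_gap: int = 2
    n_perm: int = 10000

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def run(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the in-memory bundle.

    Each stage consumes only declared upstream outputs; a disabled upstream
    stage makes dependents fail with a message naming the missing stage.
    Tables are written under ``config.outdir`` and the config itself is
    serialized alongside them.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log.info("museomics %s pipeline, seed=%d", __version__, config.seed)
    bundle: dict = {"config": config}
    for stage in config.stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
    for stage in STAGES:
        if stage in config.stages:
            _STAGE_FUNCS[stage](config, bundle, outdir)
            log.info("stage %s done", stage)
    return bundle


def _require(bundle: dict, key: str, stage: str, needed_by: str):
    if key not in bundle:
        raise PipelineError(
            f"stage {needed_by!r} requires output of stage {stage!r}, "
            "which did not run"
        )
    return bundle[key]


def _stage_simulate(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    seed = config.stage_seed("simulate")
    rng = np.random.default_rng(seed)
    sim = SimConfig(
        seed=seed,
        chromosomes=dict(config.chromosomes),
        n_sites=config.n_sites,
        ne_per_interval=list(config.ne_per_interval),
        generations_per_year=config.gens_per_year,
        damage=DamageModel(
            rate_by_tier={"high": 0.0005, "low": config.damage_rate_low},
            at_bias_by_tier={"high": 0.55, "low": config.damage_at_bias_low},
        ),
    )
    # plant sweeps on the first chromosome between the first two eras: the
    # scan stage makes the first era focal, so the swept allele must rise
    # after it and persist in both non-focal cohorts
    first_chrom = next(iter(sim.chromosomes))
    eras = [e.name for e in sim.eras]
    n_linked = 10  # hitchhiking footprint of a hard sweep
    starts = rng.choice(
        config.n_sites // n_linked, size=config.n_sweeps, replace=False
    ) * n_linked
    from museomics.simulate import SweepSpec

    sim.sweeps = [
        SweepSpec(first_chrom, int(s), 0.1, 0.95, eras[0], eras[1],
                  n_linked_sites=n_linked)
        for s in starts
    ]
    matrices, metas, truth = simulate_cohorts(sim)
    for chrom in list(matrices):
        matrices[chrom], injected = inject_damage(
            matrices[chrom], metas, sim.damage, rng
        )
        for sid, pos in injected.items():
            truth.damage_positions.setdefault(sid, []).extend(pos)
    vcfio.write_vcf(matrices, outdir / "cohorts.vcf")
    vcfio.write_meta(metas.values(), outdir / "samples.tsv")
    write_manifest(sim, truth, outdir / "manifest.json")
    pool_chrom = first_chrom
    marker_pos = rng.choice(
        matrices[pool_chrom].positions, size=20, replace=False
    )
    genes, go_map, inv_panel = make_toy_annotation(
        sim.chromosomes, n_genes=120, n_terms=30, n_clustered_terms=2,
        inversion_markers={"Inv(1)toy": (pool_chrom, np.sort(marker_pos))},
        seed=rng,
    )
    write_gff(genes, outdir / "genes.gff")
    go_map.to_csv(outdir / "gene2go.tsv", sep="\t", index=False)
    inv_panel.to_csv(outdir / "inversion_panel.tsv", sep="\t", index=False)
    final_era = eras[-1]
    pool = simulate_poolseq_reads(
        truth.pop_freqs[pool_chrom][final_era],
        matrices[pool_chrom].positions,
        pool_chrom,
        sim.pool_design,
        rng,
    )
    pool.to_csv(outdir / "pool_counts.tsv", sep="\t", index=False)
    bundle.update(
        sim=sim, matrices=matrices, metas=metas, truth=truth,
        genes=genes, go_map=go_map, inv_panel=inv_panel, pool=pool,
    )


def _stage_qc(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    matrices = _require(bundle, "matrices", "simulate", "qc")
    metas = bundle["metas"]
    report = singleton_profile(matrices, metas)
    tests = association_tests(
        report.reset_index(),
        pairs=[("singleton_count", "at_fraction")],
        group_tests=[("singleton_count", "quality_tier")],
    )
    report.to_csv(outdir / "qc_report.tsv", sep="\t")
    tests.to_csv(outdir / "qc_tests.tsv", sep="\t", index=False)
    bundle["qc_report"] = report
    bundle["qc_tests"] = tests


def _stage_ibd(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    matrices = _require(bundle, "matrices", "simulate", "ibd")
    metas = bundle["metas"]
    seed = config.stage_seed("ibd")
    eras = sorted({m.era for m in metas.values()})
    masks = {}
    calls_all = []
    windows_by_chrom = {}
    for chrom, matrix in matrices.items():
        windows = build_windows(
            matrix.positions, config.ibd_window_snps, chrom, matrix.length
        )
        windows_by_chrom[chrom] = windows
        for era in eras:
            focal = [s for s in matrix.samples if metas[s].era == era]
            outgroup = [s for s in matrix.samples if metas[s].era != era]
            if len(focal) < 2 or not outgroup:
                continue
            calls, mask, _ = detect_ibd(
                matrix, windows, focal, outgroup, metas, seed=seed
            )
            calls_all.extend(calls)
            masks.setdefault(chrom, []).append(mask)
    from museomics.datamodel import MaskTrack

    merged = MaskTrack()
    for chrom_masks in masks.values():
        for m in chrom_masks:
            merged.records.extend(m.records)
    chrom_lengths = {c: m.length for c, m in matrices.items()}
    sample_tab, pair_tab = ibd_summary(
        calls_all, merged, windows_by_chrom, chrom_lengths, metas
    )
    vcfio.write_mask_bed(merged, outdir / "ibd_mask.bed")
    sample_tab.to_csv(outdir / "ibd_sample_fractions.tsv", sep="\t", index=False)
    pair_tab.to_csv(outdir / "ibd_pair_fractions.tsv", sep="\t", index=False)
    bundle["mask"] = merged
    bundle["ibd_calls"] = calls_all
    bundle["windows_by_chrom"] = windows_by_chrom


def _stage_pool(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    pool = _require(bundle, "pool", "simulate", "pool")
    called = call_pool_snps(pool, config.pool_min_minor)
    effective = downsample_to_effective(called)
    effective.to_csv(outdir / "pool_effective.tsv", sep="\t", index=False)
    bundle["pool_effective"] = effective


def _stage_stats(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    matrices = _require(bundle, "matrices", "simulate", "stats")
    mask = _require(bundle, "mask", "ibd", "stats")
    metas = bundle["metas"]
    seed = config.stage_seed("stats")
    sf = SiteFilter(min_total_alleles=config.min_alleles)
    pops = {}
    counts_by_era_chrom = {}
    for chrom, matrix in matrices.items():
        for era in sorted({m.era for m in metas.values()}):
            cols = [s for s in matrix.samples if metas[s].era == era]
            if not cols:
                continue
            sub_idx = [matrix.sample_index(s) for s in cols]
            from museomics.datamodel import GenotypeMatrix

            sub = GenotypeMatrix(
                chromosome=matrix.chromosome,
                positions=matrix.positions.copy(),
                ref=matrix.ref.copy(),
                alt=matrix.alt.copy(),
                calls=matrix.calls[:, sub_idx],
                samples=cols,
                ploidy=matrix.ploidy[sub_idx],
                length=matrix.length,
            )
            ac = allele_counts(sub, mask, sf, seed=seed)
            counts_by_era_chrom[(era, chrom)] = ac
            if chrom == next(iter(matrices)):
                pops[era] = ac
    div = diversity_matrix(pops)
    div.to_csv(outdir / "diversity_matrix.tsv", sep="\t")

    # haplotype PCA on the X: haploid calls used directly, diploid het
    # calls collapsed by a seeded coin flip, complete sites only
    x_chrom = next((c for c in matrices if c in ("X", "chrX")), None)
    if x_chrom is not None:
        pca_tab = _x_haplotype_pca(matrices[x_chrom], seed)
        if pca_tab is not None:
            pca_tab.to_csv(outdir / "pca_loadings.tsv", sep="\t")
            bundle["pca_loadings"] = pca_tab

    # inversion frequencies per era cohort from marker-site frequencies
    inv_panel = bundle.get("inv_panel")
    if inv_panel is not None and len(inv_panel):
        rows = {}
        for (era, chrom), ac in counts_by_era_chrom.items():
            lookup = {
                (chrom, int(p)): float(f)
                for p, f in zip(ac.positions, ac.frequencies())
            }
            try:
                rows[era] = inversion_frequency(inv_panel, lookup)
            except ValueError:
                continue
        inv_tab = pd.DataFrame(rows)
        inv_tab.to_csv(outdir / "inversion_frequencies.tsv", sep="\t")
        bundle["inversion_frequencies"] = inv_tab

    bundle["population_counts"] = counts_by_era_chrom
    bundle["diversity_matrix"] = div


def _x_haplotype_pca(matrix, seed: int) -> pd.DataFrame | None:
    from museomics.diversity import minor_allele_haplotypes, pca_haplotypes

    rng = np.random.default_rng(seed)
    complete = np.all(matrix.calls >= 0, axis=1)
    calls = matrix.calls[complete]
    if calls.shape[0] < 2:
        return None
    haps = np.empty_like(calls)
    for k in range(matrix.n_samples):
        col = calls[:, k]
        if matrix.ploidy[k] == 1:
            haps[:, k] = col
        else:
            pick = rng.integers(0, 2, size=col.shape)
            haps[:, k] = np.where(col == 1, pick, col // 2)
    H = minor_allele_haplotypes(haps.T)
    try:
        loadings, eigvals = pca_haplotypes(H)
    except ValueError:
        return None
    cols = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    tab = pd.DataFrame(loadings, index=matrix.samples, columns=cols)
    tab.index.name = "sample_id"
    return tab


def _stage_nefit(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    counts = _require(bundle, "population_counts", "stats", "nefit")
    truth = bundle["truth"]
    metas = bundle["metas"]
    years = truth.era_years
    eras = sorted(years, key=years.get)
    chrom = next(iter(bundle["matrices"]))
    a = counts[(eras[0], chrom)]
    b = counts[(eras[1], chrom)]
    usable = a.usable & b.usable
    minor = np.minimum(a.alt_count, a.ref_count)
    usable &= minor != 1  # singletons excluded from demographic inference
    idx = np.flatnonzero(usable & (a.alt_count > 0) & (a.alt_count < a.n_total))
    rng = np.random.default_rng(config.stage_seed("nefit"))
    if idx.size > config.nefit_max_sites:
        idx = np.sort(rng.choice(idx, size=config.nefit_max_sites, replace=False))
    data = TemporalFreqData(
        count_t0=a.alt_count[idx],
        n_t0=a.n_total[idx],
        count_t1=b.alt_count[idx],
        n_t1=b.n_total[idx],
        generations=generations_between(
            years[eras[0]], years[eras[1]], config.gens_per_year
        ),
    )
    n_term = int(np.median(b.n_total[idx]))
    result = fit_ne(
        data,
        TerminalDesign("individual", max(n_term, 2)),
        seed=config.stage_seed("nefit"),
        grid_min=config.grid_min,
        grid_max=config.grid_max,
        grid_step=config.grid_step,
        refine_step=config.refine_step,
        replicates=config.reps,
    )
    trace = pd.DataFrame(
        {
            "n_star": np.concatenate([result.grid, result.refined_grid]),
            "sim_delta": np.concatenate([result.sim_delta, result.refined_delta]),
            "phase": ["coarse"] * len(result.grid)
            + ["refine"] * len(result.refined_grid),
        }
    )
    trace.to_csv(outdir / "nefit_trace.tsv", sep="\t", index=False)
    (outdir / "nefit.json").write_text(
        json.dumps(
            {
                "n_star": result.n_star,
                "diploid_ne": result.diploid_ne,
                "observed_delta": result.observed_delta,
                "replicates": result.replicates,
                "at_boundary": result.at_boundary,
            },
            indent=2,
        )
    )
    bundle["nefit"] = result


def _stage_scan(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    counts = _require(bundle, "population_counts", "stats", "scan")
    truth = bundle["truth"]
    years = truth.era_years
    eras = sorted(years, key=years.get)
    chrom = next(iter(bundle["matrices"]))
    matrix = bundle["matrices"][chrom]
    windows = build_windows(
        matrix.positions, config.scan_window_snps, chrom, matrix.length
    )
    pool_eff = bundle.get("pool_effective")
    from museomics.datamodel import AlleleCounts

    if pool_eff is not None:
        sub = pool_eff[pool_eff["chrom"] == chrom]
        out2 = AlleleCounts(
            chrom,
            sub["pos"].to_numpy(np.int64),
            sub["ref_ds"].to_numpy(np.int64),
            sub["alt_ds"].to_numpy(np.int64),
            (sub["ref_ds"] + sub["alt_ds"]).to_numpy() >= config.min_alleles,
        )
    else:
        out2 = counts[(eras[2], chrom)]
    result = run_scan(
        counts[(eras[0], chrom)],
        counts[(eras[1], chrom)],
        out2,
        windows,
        quantile=config.quantile,
        max_gap=config.max_gap,
    )
    annotate_regions(result.regions, bundle["genes"])
    result.table.to_csv(outdir / "scan_windows.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": r.chromosome,
                "start": r.start,
                "end": r.end,
                "rank": r.rank,
                "max_pbe": r.max_pbe,
                "genes": ";".join(r.genes),
            }
            for r in result.regions
        ]
    ).to_csv(outdir / "scan_regions.tsv", sep="\t", index=False)
    if result.snp_table is not None:
        result.snp_table.to_csv(outdir / "scan_snps.tsv", sep="\t", index=False)
    bundle["scan"] = result


def _stage_enrich(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    scan_result = _require(bundle, "scan", "scan", "enrich")
    genes = _require(bundle, "genes", "simulate", "enrich")
    go_map = bundle["go_map"]
    chrom_lengths = {c: m.length for c, m in bundle["matrices"].items()}
    index = AnnotationIndex(genes, go_map, chrom_lengths)
    regions = [(r.chromosome, r.start, r.end) for r in scan_result.regions]
    table = permutation_pvalues(
        regions, index, n_perm=config.n_perm, seed=config.stage_seed("enrich")
    )
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    bundle["enrichment"] = table


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "ibd": _stage_ibd,
    "pool": _stage_pool,
    "stats": _stage_stats,
    "nefit": _stage_nefit,
    "scan": _stage_scan,
    "enrich": _stage_enrich,
}
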