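"""File IO: VCF genotypes (cyvcf2), metadata TSV, mask BED, GFF, GO maps.

VCF columns follow the ploidy implied by the metadata sidecar: diploid calls
are ``0/0``, ``0/1``, ``1/1`` or ``./.``; haploid (male X or pseudo-haploid)
calls are ``0``, ``1`` or ``.``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from museomics.datamodel import GenotypeMatrix, MaskRecord, MaskTrack, SampleMeta

log = logging.getLogger(__name__)

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


def read_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read a sample metadata TSV (sample_id, era, location, sex, quality_tier)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        if row.sample_id in metas:
            raise ValueError(f"duplicate sample_id {row.sample_id}")
        metas[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            era=row.era,
            location=getattr(row, "location", ""),
            sex=getattr(row, "sex", "unknown") or "unknown",
            quality_tier=getattr(row, "quality_tier", "high") or "high",
        )
    return metas


def write_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "era": m.era,
                "location": m.location,
                "sex": m.sex,
                "quality_tier": m.quality_tier,
            }
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def load_genotypes(
    vcf_path: str | Path,
    metas: dict[str, SampleMeta],
) -> tuple[dict[str, GenotypeMatrix], dict[str, SampleMeta]]:
    """Load biallelic genotypes from a VCF into per-chromosome matrices.

    Every VCF sample must appear in the metadata; non-biallelic sites are
    excluded with a logged count. A heterozygous call on a haploid sample
    (e.g. a male X) violates the ploidy model and raises.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in metas]
    if unknown:
        raise ValueError(f"VCF samples absent from metadata: {unknown}")
    by_chrom: dict[str, dict[str, list]] = {}
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        store = by_chrom.setdefault(
            var.CHROM, {"pos": [], "ref": [], "alt": [], "calls": []}
        )
        ploidy = np.array([metas[s].ploidy(var.CHROM) for s in samples], dtype=np.int8)
        gt = np.asarray(var.gt_types)
        row = np.full(len(samples), -1, dtype=np.int8)
        row[gt == _HOM_REF] = 0
        het = gt == _HET
        if np.any(het & (ploidy == 1)):
            bad = samples[int(np.argwhere(het & (ploidy == 1))[0][0])]
            raise ValueError(
                f"heterozygous call for haploid sample {bad} at "
                f"{var.CHROM}:{var.POS}"
            )
        row[het] = 1
        hom_alt = gt == _HOM_ALT
        row[hom_alt] = ploidy[hom_alt]
        store["pos"].append(var.POS)
        store["ref"].append(var.REF)
        store["alt"].append(var.ALT[0])
        store["calls"].append(row)
    if n_skipped:
        log.warning("excluded %d non-biallelic site(s)", n_skipped)
    matrices = {}
    for chrom, store in by_chrom.items():
        ploidy = np.array([metas[s].ploidy(chrom) for s in samples], dtype=np.int8)
        matrices[chrom] = GenotypeMatrix(
            chromosome=chrom,
            positions=np.array(store["pos"], dtype=np.int64),
            ref=np.array(store["ref"]),
            alt=np.array(store["alt"]),
            calls=np.vstack(store["calls"]),
            samples=samples,
            ploidy=ploidy,
        )
    return matrices, {s: metas[s] for s in samples}


def _format_call(dosage: int, ploidy: int) -> str:
    if ploidy == 1:
        return "." if dosage < 0 else str(dosage)
    if dosage < 0:
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]


def write_vcf(
    matrices: dict[str, GenotypeMatrix] | Sequence[GenotypeMatrix],
    path: str | Path,
) -> None:
    """Write per-chromosome genotype matrices as a VCFv4.2 text file."""
    if isinstance(matrices, dict):
        mats = list(matrices.values())
    else:
        mats = list(matrices)
    if not mats:
        raise ValueError("nothing to write")
    samples = mats[0].samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=museomics\n")
        for m in mats:
            fh.write(f"##contig=<ID={m.chromosome},length={m.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for m in mats:
            if m.samples != samples:
                raise ValueError("all chromosomes must share the sample set")
            for s in range(m.n_sites):
                gts = "\t".join(
                    _format_call(int(m.calls[s, k]), int(m.ploidy[k]))
                    for k in range(m.n_samples)
                )
                fh.write(
                    f"{m.chromosome}\t{m.positions[s]}\t.\t{m.ref[s]}\t{m.alt[s]}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )


def write_mask_bed(mask: MaskTrack, path: str | Path) -> None:
    """Mask track as BED: chrom, start, end, sample_id, 0, kind, alleles."""
    with open(path, "w") as fh:
        for r in sorted(
            mask.records, key=lambda r: (r.chromosome, r.start, r.sample_id)
        ):
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{r.sample_id}\t0\t"
                f"{r.kind}\t{r.alleles_masked}\n"
            )


def read_mask_bed(path: str | Path) -> MaskTrack:
    track = MaskTrack()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, sample_id, _, kind, alleles = line.split("\t")[:7]
            track.add(
                MaskRecord(
                    sample_id=sample_id,
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    kind=kind,
                    alleles_masked=alleles.strip(),
                )
            )
    return track


def read_bed_intervals(path: str | Path) -> dict[str, np.ndarray]:
    """Plain BED intervals (e.g. a low-recombination exclusion mask)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GFF3 file: chrom, start, end (half-open 0-based), gene_id."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "gene_id": gene_id,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Gene -> GO term TSV with columns gene_id, go_term."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_pool_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Pool-seq read counts TSV: chrom, pos, ref_reads, alt_reads[, n_c]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref_reads", "alt_reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"pool counts TSV must have columns {sorted(required)}")
    return df
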