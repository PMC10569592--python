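"""PBS/PBE window scan for the last era interval.

Focal population = second era, outgroups = first era and the pool-seq
cohort (effective counts). The two planted sweeps should surface among the
top-1% PBE windows. Writes scan_windows.tsv, scan_regions.tsv,
scan_snps.tsv.
"""

from common import RESULTS, run_through


def main() -> None:
    bundle = run_through("scan")
    result = bundle["scan"]
    truth = bundle["truth"]
    regions = sorted(result.regions, key=lambda r: r.rank)
    print(f"{int(result.table['outlier'].sum())} outlier windows -> "
          f"{len(regions)} merged regions")
    for r in regions[:5]:
        print(f"  rank {r.rank}: {r.chromosome}:{r.start}-{r.end} "
              f"max PBE {r.max_pbe:.3f} genes={','.join(r.genes) or '-'}")
    hits = [
        (chrom, pos)
        for chrom, pos in truth.sweep_sites
        if any(r.chromosome == chrom and r.start <= pos - 1 < r.end
               for r in regions)
    ]
    print(f"planted sweeps recovered in outlier regions: "
          f"{len(hits)}/{len(truth.sweep_sites)}")
    print(f"tables in {RESULTS}")


if __name__ == "__main__":
    main()
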