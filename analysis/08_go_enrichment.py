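"""Permutation GO enrichment of the scan's outlier regions.

Regions are relocated uniformly at random (length preserved,
length-weighted chromosome choice); a term's raw p is the share of
permutations reaching its observed region count. Writes enrichment.tsv.
"""

from common import RESULTS, run_through


def main() -> None:
    bundle = run_through("enrich")
    table = bundle["enrichment"].sort_values("p_value")
    scored = table[table["region_count"] > 0]
    print(f"{len(scored)} GO terms overlap at least one outlier region")
    print(scored.head(10).to_string(index=False))
    print(f"tables in {RESULTS}")


if __name__ == "__main__":
    main()
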