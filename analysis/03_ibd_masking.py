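"""Detect relatedness/inbreeding IBD and build the genotype mask.

Window Hamming distances among same-era genomes are rescaled against the
other era as outgroup; windows below the ploidy-dependent threshold
((7/8)D for diploid pairs) are masked in one pair member, with half-window
flanks. Writes ibd_mask.bed plus per-sample and per-pair masked-fraction
tables.
"""

from common import RESULTS, run_through


def main() -> None:
    bundle = run_through("ibd")
    sample_tab = bundle["mask"]
    calls = bundle["ibd_calls"]
    n_rel = sum(1 for c in calls if c.kind == "relatedness")
    n_inb = sum(1 for c in calls if c.kind == "inbreeding")
    print(f"{n_rel} relatedness window calls, {n_inb} inbreeding window calls")
    print(f"{len(sample_tab.records)} merged mask intervals")
    # the default cohorts plant no pedigree, so calls reflect the false
    # positive rate of the window test at this window size
    print(f"tables in {RESULTS}")


if __name__ == "__main__":
    main()
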