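"""Per-genome quality profile: singletons and their A/T fraction.

Low-quality genomes carry injected deamination-style errors, so they should
show elevated singleton counts and singleton A/T fractions above the ~55%
baseline of undamaged genomes; the association tests quantify both
patterns. Writes qc_report.tsv and qc_tests.tsv.
"""

from common import RESULTS, run_through


def main() -> None:
    bundle = run_through("qc")
    report = bundle["qc_report"]
    by_tier = report.groupby("quality_tier")[
        ["singleton_count", "at_fraction"]
    ].mean()
    print("mean singleton count and A/T fraction by quality tier:")
    print(by_tier.round(3))
    print("\nassociation tests:")
    print(bundle["qc_tests"].round(4).to_string(index=False))
    print(f"\ntables in {RESULTS}")


if __name__ == "__main__":
    main()
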