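"""Within- and between-cohort diversity: pi, Dxy, Hudson FST.

Post-masking allele counts per era feed the diversity matrix (pi on the
diagonal, FST below, Dxy above). Under pure drift at the configured Ne the
1800s-1933 FST should sit near 1 - exp(-G/2N). Writes
diversity_matrix.tsv.
"""

import numpy as np

from common import RESULTS, config, run_through


def main() -> None:
    bundle = run_through("stats")
    div = bundle["diversity_matrix"]
    print("diversity matrix (pi diagonal, FST below, Dxy above):")
    print(div.round(4))
    cfg = config()
    years = sorted(
        bundle["truth"].era_years.values()
    )
    g = (years[1] - years[0]) * cfg.gens_per_year
    expected_fst = 1 - np.exp(-g / (4 * cfg.ne_per_interval[0]))
    print(f"\ndrift expectation for the first interval: "
          f"FST ~ {expected_fst:.3f} at diploid Ne="
          f"{cfg.ne_per_interval[0]:.0f} over {g} generations")
    print(f"tables in {RESULTS}")


if __name__ == "__main__":
    main()
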