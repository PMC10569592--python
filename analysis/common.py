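"""Shared configuration for the numbered analysis drivers.

One seed, one configuration: every driver re-derives the stages it needs
(stages are deterministic under the per-stage seeds), so each script can be
run on its own and all of them agree on intermediate results. Tables land
in results/analysis/.
"""

from __future__ import annotations

from pathlib import Path

from museomics.pipeline import STAGES, PipelineConfig, run

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def config() -> PipelineConfig:
    return PipelineConfig(
        seed=2023,
        outdir=str(RESULTS),
        n_sites=6000,
        chromosomes={"2L": 2_000_000, "X": 1_500_000},
        ne_per_interval=[3000.0, 3000.0],
        # moderate Monte-Carlo sizes so each driver finishes in minutes
        reps=300,
        nefit_max_sites=120,
        n_perm=5000,
        ibd_window_snps=1500,
        scan_window_snps=50,
    )


def run_through(last_stage: str):
    """Run the pipeline from the start through ``last_stage`` inclusive."""
    cfg = config()
    cfg.stages = list(STAGES[: STAGES.index(last_stage) + 1])
    return run(cfg)
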