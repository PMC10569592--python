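"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from museomics.datamodel import GenotypeMatrix, SampleMeta
from museomics.simulate import (
    DamageModel,
    EraDesign,
    RelationSpec,
    SimConfig,
    simulate_cohorts,
)


def study_metas() -> dict[str, SampleMeta]:
    """Nine-genome historical cohort: 6 females / 3 males, 4 low-quality females."""
    metas = {}
    for i in range(3):
        metas[f"m{i}"] = SampleMeta(f"m{i}", era="1800s", sex="male")
    for i in range(2):
        metas[f"f{i}"] = SampleMeta(f"f{i}", era="1800s", sex="female")
    for i in range(2, 6):
        metas[f"f{i}"] = SampleMeta(
            f"f{i}", era="1800s", sex="female", quality_tier="low"
        )
    return metas


def matrix_for(
    metas: dict[str, SampleMeta],
    chromosome: str,
    calls: np.ndarray,
    positions: np.ndarray | None = None,
    ref: np.ndarray | None = None,
    alt: np.ndarray | None = None,
) -> GenotypeMatrix:
    samples = list(metas)
    n_sites = calls.shape[0]
    return GenotypeMatrix(
        chromosome=chromosome,
        positions=(
            positions if positions is not None
            else np.arange(1, n_sites + 1) * 100
        ),
        ref=ref if ref is not None else np.full(n_sites, "A"),
        alt=alt if alt is not None else np.full(n_sites, "G"),
        calls=calls,
        samples=samples,
        ploidy=np.array([metas[s].ploidy(chromosome) for s in samples]),
        length=int(n_sites * 100 + 100),
    )


@pytest.fixture(scope="session")
def nine_genome_metas():
    return study_metas()


@pytest.fixture(scope="session")
def sib_cohort():
    """Two-era cohort with a planted full-sib pair and an inbred genome."""
    # window-scale SNP counts chosen so the D/8 decision margin spans several
    # standard errors of the window mean distance, as with the production
    # 25,000-SNP windows
    config = SimConfig(
        seed=11,
        chromosomes={"2L": 2_000_000},
        n_sites=12_000,
        eras=[
            EraDesign("1800s", 1809, 8, n_males=0, n_low_quality=0),
            EraDesign("1933", 1933, 8, n_males=0, n_low_quality=0),
        ],
        ne_per_interval=[3000.0],
        missing_rate=0.01,
        pedigree=[
            RelationSpec("sib", "1800s_00", "1800s_01"),
            RelationSpec("inbred", "1933_02"),
        ],
        damage=DamageModel(rate_by_tier={"high": 0.0, "low": 0.0}),
        ibd_segment_sites=2000,
    )
    return (config, *simulate_cohorts(config))


@pytest.fixture(scope="session")
def plain_cohort():
    """Small two-era cohort without pedigree or damage (specificity checks)."""
    config = SimConfig(
        seed=5,
        chromosomes={"2L": 2_000_000},
        n_sites=24_000,
        eras=[
            EraDesign("1800s", 1809, 8, n_males=0, n_low_quality=0),
            EraDesign("1933", 1933, 8, n_males=0, n_low_quality=0),
        ],
        ne_per_interval=[3000.0],
        missing_rate=0.01,
        damage=DamageModel(rate_by_tier={"high": 0.0, "low": 0.0}),
        ibd_segment_sites=3000,
    )
    return (config, *simulate_cohorts(config))
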