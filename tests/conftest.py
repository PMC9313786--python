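"""Shared fixtures: a seeded synthetic recovery study used across tests.

The study emulates the staged design: four sample types x three biological
replicates, 600 transcripts with 15 planted housekeepers and 10 planted
markers per stage at a 3 log2 effect, NB dispersion 0.05.
"""

from dataclasses import dataclass

import pandas as pd
import pytest

import haustostage as hs


@dataclass
class RecoveryStudy:
    config: hs.SimulationConfig
    counts: hs.CountMatrix
    truth: dict[str, str]
    kept: hs.CountMatrix
    contrasts: dict
    gs: hs.GeneSignificance
    housekeepers: object
    markers: object


@pytest.fixture(scope="session")
def recovery_study() -> RecoveryStudy:
    config = hs.SimulationConfig(
        n_transcripts=600,
        n_housekeepers=15,
        n_markers_per_stage={s: 10 for s in hs.STAGES},
        marker_effect_log2fc=3.0,
        nb_dispersion=0.05,
        replicates_per_stage=3,
        seed=7,
    )
    counts, truth = hs.simulate_counts(config)
    kept = hs.filter_expressed(counts)
    contrasts = hs.all_pairwise_contrasts(kept)
    gs = hs.gene_significance(kept)
    housekeepers = hs.select_housekeepers(kept, contrasts)
    markers = hs.select_markers(kept, contrasts, gs, relax_stage="ATT")
    return RecoveryStudy(
        config=config,
        counts=counts,
        truth=truth,
        kept=kept,
        contrasts=contrasts,
        gs=gs,
        housekeepers=housekeepers,
        markers=markers,
    )


@pytest.fixture
def small_sheet() -> hs.SampleSheet:
    rows = [
        {"sample_id": f"{stage}_{rep}", "stage": stage, "replicate": rep, "system": "host-free"}
        for stage in hs.STAGES
        for rep in (1, 2, 3)
    ]
    return hs.SampleSheet(pd.DataFrame(rows))
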