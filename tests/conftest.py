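"""Shared fixtures: one full simulated dataset + pipeline run per session."""

from __future__ import annotations

import pytest

from paleofam import pipeline, simulate
from paleofam.ksclust import DEFAULT_RATE


def wgd_calibration(species: list[str]) -> dict[str, list]:
    """Calibration intervals centered on the simulated event ages
    (the analog of taking published median-Ks ranges as input)."""
    intervals = []
    for label, t in (("wgd_recent", 10e6), ("wgd_shared", 50e6)):
        ks = 2.0 * DEFAULT_RATE * t
        intervals.append((label, 0.7 * ks, 1.3 * ks))
    return {sp: list(intervals) for sp in species}


@pytest.fixture(scope="session")
def sim_dataset():
    """Default three-lineage simulation: shared WGD at 50 My, sp1-specific
    WGD at 10 My, sp3 as undisturbed baseline."""
    return simulate.simulate_dataset(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline") / "out"
    config = pipeline.PipelineConfig(
        outdir=str(outdir),
        calibration=wgd_calibration(sim_dataset.species),
        species_events=sim_dataset.species_events,
        seed=1,
    )
    data = pipeline.PipelineData(
        sim_dataset.proteins,
        sim_dataset.cds,
        sim_dataset.genes,
        {},
        sim_dataset.anchors,
    )
    return pipeline.run_pipeline(config, data)
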