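"""Shared fixtures: a toy annotated genome and one full synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from degradome import expression_quant as eq
from degradome import synthetic_data as sd
from degradome.genome_io import GeneModel, GenomeRecord


@pytest.fixture
def toy_record() -> GenomeRecord:
    """Linear 1 kb genome with three genes, one on the minus strand."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    genes = [
        GeneModel("g1", 100, 200, "+", "CDS", {"role": "CAZyme"}),
        GeneModel("g2", 300, 400, "-", "CDS", {"role": "other"}),
        GeneModel("g3", 600, 800, "+", "CDS", {"role": "other"}),
    ]
    return GenomeRecord("toy", seq, circular=False, genes=genes)


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-condition synthetic dataset: config, genome, truth, coverage, NTA."""
    cfg = sd.SimulationConfig(seed=1)
    record, truth = sd.simulate_genome(cfg)
    tracks = {c: sd.simulate_coverage(record, truth, cfg, c) for c in cfg.conditions}
    expr = eq.compute_nta_table(tracks, record)
    return {"config": cfg, "record": record, "truth": truth,
            "tracks": tracks, "expr": expr}
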