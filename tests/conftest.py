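"""Shared fixtures: simulated studies reused across test modules.

The default study (300 transcripts, depth 500, 3+3 replicates, seed 42)
is generated once per session; the larger feature study provides
>= 200 uORFs per translation group for the directional analyses.
"""

from __future__ import annotations

import logging

import pandas as pd
import pytest

from riboprof import coding_potential as cp
from riboprof.orf_discovery import enumerate_all
from riboprof.synthetic_data import SimConfig, simulate_annotation, simulate_reads

logging.getLogger("riboprof").setLevel(logging.ERROR)


class Study:
    """A simulated study plus its pooled observations."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.models, self.genome, self.gff3, self.truth = simulate_annotation(config)
        self.reads = simulate_reads(self.truth, config)
        self.psites = pd.concat(self.reads.psites.values(), ignore_index=True)
        self.rna_positions = pd.concat(
            self.reads.rna_positions.values(), ignore_index=True
        )


class ScoredStudy(Study):
    """Study with ORF enumeration, coding scores and translation calls."""

    def __init__(self, config: SimConfig):
        super().__init__(config)
        self.orfs = enumerate_all(self.models)
        self.hexamer_table = cp.default_hexamer_table(self.models, seed=config.seed)
        self.scores = cp.score_orfs(
            self.orfs, self.psites, self.rna_positions, self.models,
            hexamer_table=self.hexamer_table,
        )
        self.null = cp.null_scores(
            self.orfs, self.scores, self.models, self.hexamer_table, seed=config.seed
        )
        candidates = [s for s in self.scores if s.category == "uORF"]
        self.calls, self.thresholds = cp.call_translated(candidates, self.null)
        self.called = {c.orf_id: c.translated for c in self.calls}


@pytest.fixture(scope="session")
def default_study() -> ScoredStudy:
    """The default study conditions: 300 transcripts, half of uORFs
    translated, mean depth 500, seed 42."""
    return ScoredStudy(SimConfig(n_transcripts=300, p_translated_uorf=0.5,
                                 mean_depth=500.0, seed=42))


@pytest.fixture(scope="session")
def feature_study() -> ScoredStudy:
    """Larger study for group comparisons: >= 200 uORFs per group."""
    return ScoredStudy(SimConfig(n_transcripts=1200, uorf_probability=0.6, seed=42))
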