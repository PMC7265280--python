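"""Shared fixtures: small synthetic panels and read sets.

Everything is generated at test time from fixed seeds; expensive
fixtures are session-scoped so the suite stays within a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from operonscope import synth


def cohort_metadata(designs) -> pd.DataFrame:
    return pd.DataFrame([{"sample_id": d.sample_id, "genotype": d.genotype,
                          "activity": d.activity} for d in designs])


def truth_frame(reads) -> pd.DataFrame:
    return pd.DataFrame([{"read_id": r.read_id, "species_id": r.truth[0],
                          "copy_id": r.truth[1], "direction": r.truth[2]}
                         for r in reads if r.truth is not None])


@pytest.fixture(scope="session")
def two_species_panel():
    """Two species at 94% 16S identity, one operon copy each."""
    return synth.make_reference_panel(2, copies_per_species=1,
                                      divergence=synth.DivergenceSpec(0.94), seed=11)


@pytest.fixture(scope="session")
def multicopy_panel():
    """Three species (90% identity to backbone), four operon copies each."""
    return synth.make_reference_panel(3, copies_per_species=4,
                                      divergence=synth.DivergenceSpec(0.90), seed=7)


@pytest.fixture(scope="session")
def single_species_reads():
    """40 noisy reads of one single-copy species (8% total error)."""
    panel = synth.make_reference_panel(1, copies_per_species=1, seed=3)
    designs = [synth.SampleDesign("s1", "WT", "sedentary", {"sp01": 1.0}, 40)]
    reads = synth.simulate_reads(panel, designs, synth.ErrorModel(seed=11))
    return panel, reads


@pytest.fixture(scope="session")
def recovery_reads(multicopy_panel):
    """200 reads at 8% error over a >=10%-divergent panel, with truth."""
    designs = synth.default_cohort(multicopy_panel, n_reads=50, group_sizes=(1, 1, 1, 1))
    reads = synth.simulate_reads(multicopy_panel, designs, synth.ErrorModel(seed=23))
    return designs, reads


@pytest.fixture
def rng():
    return np.random.default_rng(0)
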