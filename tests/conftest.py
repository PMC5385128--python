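"""Shared fixtures: toy trees and simulated alignments reused across the
suite. Everything is generated programmatically and seeded."""

import numpy as np
import pytest

from codonsel.likelihood import fit
from codonsel.simulate import (
    SimulationSpec,
    make_study_like_fixture,
    simulate_alignment,
)
from codonsel.siteclass import get_model
from codonsel.tree import parse_newick

FOUR_TAXON_NEWICK = "((A:0.11,B:0.23):0.07,(C:0.16,D:0.31):0.09);"


@pytest.fixture(scope="session")
def four_taxon_tree():
    return parse_newick(FOUR_TAXON_NEWICK)


@pytest.fixture(scope="session")
def small_m0_data(four_taxon_tree):
    """A 60-codon alignment simulated under M0 on the 4-taxon tree."""
    spec = SimulationSpec(
        tree=four_taxon_tree,
        model=get_model("M0"),
        theta={"kappa": 2.0, "omega": 0.3},
        n_sites=60,
        seed=11,
    )
    aln, truth = simulate_alignment(spec)
    return aln, truth, spec


@pytest.fixture(scope="session")
def small_m0_fit(small_m0_data, four_taxon_tree):
    aln, _, _ = small_m0_data
    return fit(aln, four_taxon_tree, "M0", restarts=1, seed=0)


@pytest.fixture(scope="session")
def cmc_sim_200():
    """A 200-codon alignment from the divergent-selection preset."""
    spec = make_study_like_fixture("cmc-divergent", seed=42)
    spec.n_sites = 200
    aln, truth = simulate_alignment(spec)
    return aln, truth, spec
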