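"""Shared fixtures: small communities and random-sequence helpers."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from foramtx.synth import CommunitySpec, SampleSpec, TaxonSpec


def random_contig_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def tiny_spec() -> CommunitySpec:
    """Three taxa x 10 genes, two samples; fast to simulate."""
    taxa = (
        TaxonSpec("Foram_sp", "Foraminifera", "Bolivina", 10, gc=0.42),
        TaxonSpec("Ciliate_sp", "Ciliophora", "Euplotes", 10, gc=0.35),
        TaxonSpec("Bacterium_sp", "Bacteria", "Desulfobacter", 10, gc=0.5),
    )
    samples = (
        SampleSpec("s1", "oxic", {"Foram_sp": 0.2, "Ciliate_sp": 0.8, "Bacterium_sp": 0.8}, 10.0),
        SampleSpec("s2", "anoxic", {"Foram_sp": 0.9, "Ciliate_sp": 0.8, "Bacterium_sp": 0.8}, 10.0),
    )
    return CommunitySpec(taxa=taxa, samples=samples, amplification_sigma=1.0, seed=7)


@pytest.fixture(scope="session")
def contaminated_spec() -> CommunitySpec:
    taxa = (
        TaxonSpec("Foram_sp", "Foraminifera", "Bolivina", 12, gc=0.42),
        TaxonSpec("Ciliate_sp", "Ciliophora", "Euplotes", 12, gc=0.35),
        TaxonSpec("Contam_sp", "Bacteria", "Pseudomonas", 8, gc=0.6, is_contaminant=True),
    )
    samples = (
        SampleSpec("s1", "oxic", {"Foram_sp": 0.5, "Ciliate_sp": 0.5, "Contam_sp": 0.5}, 10.0),
    )
    return CommunitySpec(taxa=taxa, samples=samples, amplification_sigma=0.0, seed=11)
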