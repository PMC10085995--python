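"""Shared fixtures: tiny hand-built urns/ontologies and one simulated dataset.

Everything is generated programmatically; the simulated dataset is session-
scoped because mining it is the expensive part shared by several tests.
"""

import numpy as np
import pytest

from enrichsphere.core_io import AbundanceTable, BiomeCounts, SampleMeta
from enrichsphere.ontology import OntologyGraph
from enrichsphere.synthetic import (
    make_ontology,
    plant_truth,
    simulate_dataset,
)


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """A three-term chain C is_a B is_a A in one namespace."""
    return OntologyGraph.from_terms(
        {
            "T:A": ("alpha", "biological_process"),
            "T:B": ("beta", "biological_process"),
            "T:C": ("gamma", "biological_process"),
        },
        [("T:B", "T:A"), ("T:C", "T:B")],
    )


@pytest.fixture
def star_graph() -> OntologyGraph:
    """A root with three children plus an isolated second namespace."""
    return OntologyGraph.from_terms(
        {
            "T:R": ("root", "biological_process"),
            "T:X": ("x", "biological_process"),
            "T:Y": ("y", "biological_process"),
            "T:Z": ("z", "biological_process"),
            "T:LONE": ("lone", "molecular_function"),
        },
        [("T:X", "T:R"), ("T:Y", "T:R"), ("T:Z", "T:R")],
    )


@pytest.fixture
def proportion_table() -> AbundanceTable:
    samples = [
        SampleMeta("S1", "BiomeA", 1000),
        SampleMeta("S2", "BiomeA", 2000),
        SampleMeta("S3", "BiomeB", 1000),
    ]
    values = np.array(
        [
            [0.25, 0.10, 0.50],
            [0.50, 0.40, 0.20],
            [0.25, 0.50, 0.30],
        ]
    )
    return AbundanceTable(
        feature_ids=["F1", "F2", "F3"],
        samples=samples,
        values=values,
        kind="go_term",
        stage="proportion",
    )


@pytest.fixture
def toy_counts() -> BiomeCounts:
    """A small urn with one clearly biome-A-specific feature."""
    counts = np.array(
        [
            [50, 0, 0],  # all mass in biome A
            [20, 20, 20],  # flat
            [10, 30, 50],  # mild gradient
        ]
    )
    return BiomeCounts(
        feature_ids=["F1", "F2", "F3"], biomes=["A", "B", "C"], counts=counts
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """One simulated dataset at reduced size with its ground truth.

    Reduced from the generator defaults (300 terms, 15 samples/biome, depth
    5000) so unit tests stay fast; the full-scale conditions are exercised by
    the acceptance suite.
    """
    seed = 11
    graph = make_ontology(300, 3, 1.5, seed=seed)
    truth = plant_truth(graph, n_spheres=4, sphere_size_range=(3, 5), seed=seed)
    term_table, species_table, samples, gene_map = simulate_dataset(
        truth, samples_per_biome=15, depth=5000, seed=seed
    )
    return {
        "graph": graph,
        "truth": truth,
        "term_table": term_table,
        "species_table": species_table,
        "samples": samples,
        "gene_map": gene_map,
    }
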