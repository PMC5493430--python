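import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kbt2 import (
    InteractionScores,
    PathwayCollection,
    PathwayDefinition,
    ProcessingConfig,
    SimulationDesign,
    build_profile,
    generate_expression_records,
    generate_interaction_network,
    generate_pathway_collection,
)


@pytest.fixture
def small_scores() -> InteractionScores:
    return InteractionScores.from_edges(
        [("A", "B", 0.9), ("B", "C", 0.6), ("A", "D", 0.45)]
    )


@pytest.fixture
def small_collection() -> PathwayCollection:
    return PathwayCollection(
        [
            PathwayDefinition("pwA", "big pathway", frozenset("ABCD")),
            PathwayDefinition("pwB", "nested pathway", frozenset("AB")),
            PathwayDefinition("pwC", "disjoint pathway", frozenset(("X", "Y"))),
        ]
    )


@pytest.fixture
def default_design() -> SimulationDesign:
    return SimulationDesign(seed=17)


@pytest.fixture
def synthetic_study(default_design):
    """A full mid-size synthetic study: profile, collection, scores."""
    scores = generate_interaction_network(default_design)
    collection = generate_pathway_collection(default_design)
    records = generate_expression_records(default_design, collection)
    profile = build_profile(records, None, ProcessingConfig())
    return profile, collection, scores
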