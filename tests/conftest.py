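"""Shared fixtures: synthetic study data and trained models.

Heavy artifacts (gene embeddings, the base predictor, the per-composite
extended predictors) are session-scoped so the whole suite trains them
once.  The generators run at their default desk scale: a depth-4 binary
tissue tree (16 leaves, 6 composites), 6 atlas subjects, 40 cohort
subjects, 200 genes.
"""

from __future__ import annotations

import numpy as np
import pytest

from bronte.embeddings import train_gene_embeddings
from bronte.model import (aggregate_to_composites, fit_lm_bank,
                          train_bronte, train_extended_bronte)
from bronte.ontology import BrainOntology
from bronte.simdata import SimConfig, simulate_expression, simulate_ontology

# desk-scale model configuration used throughout the suite
MODEL_CONFIG = dict(gcn_sizes=(64, 32), mlp_hidden=(128, 64, 32, 16),
                    epochs_atlas=25, epochs_cohort=10)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def ontology(sim_config):
    c = sim_config
    return simulate_ontology(c.depth, c.branching, c.n_composites, c.seed)


@pytest.fixture(scope="session")
def atlas_expr(ontology, sim_config):
    expr, _ = simulate_expression(ontology, sim_config,
                                  sim_config.n_atlas_subjects, seed=7)
    return expr


@pytest.fixture(scope="session")
def cohort_data(ontology, sim_config):
    """(leaf-level tensor, composite-level tensor, truth record)."""
    leaf, truth = simulate_expression(ontology, sim_config,
                                      sim_config.n_cohort_subjects, seed=8)
    return leaf, aggregate_to_composites(leaf, ontology), truth


@pytest.fixture(scope="session")
def gene_embedding(atlas_expr):
    return train_gene_embeddings(atlas_expr, dim_g=32, steps=120,
                                 pairs_per_step=2048, seed=1)


@pytest.fixture(scope="session")
def base_model(atlas_expr, cohort_data, ontology, gene_embedding):
    return train_bronte(atlas_expr, cohort_data[1], ontology, gene_embedding,
                        MODEL_CONFIG, seed=3)


@pytest.fixture(scope="session")
def extended_models(atlas_expr, cohort_data, ontology, gene_embedding):
    return {c: train_extended_bronte(c, atlas_expr, cohort_data[1], ontology,
                                     gene_embedding, MODEL_CONFIG, seed=3)
            for c in ontology.composite_ids}


@pytest.fixture(scope="session")
def lm_bank(cohort_data):
    return fit_lm_bank(cohort_data[1])


@pytest.fixture(scope="session")
def big_ontology():
    """A 103-leaf, 10-composite tree mirroring the scale of a real brain
    atlas hierarchy (generated programmatically; synthetic ids)."""
    sizes = [8, 10, 10, 10, 10, 10, 11, 11, 11, 12]
    nodes = [{"id": "root", "name": "brain", "level": 0, "parent": None}]
    leaves, composites = [], {}
    for k, size in enumerate(sizes):
        comp = f"region{k}"
        nodes.append({"id": comp, "name": f"region {k}", "level": 1,
                      "parent": "root"})
        members = []
        for j in range(size):
            leaf = f"{comp}_leaf{j}"
            nodes.append({"id": leaf, "name": leaf, "level": 2, "parent": comp})
            members.append(leaf)
        leaves.extend(members)
        composites[comp] = members
    return BrainOntology(nodes=nodes, leaf_ids=leaves, composite_map=composites)


def random_tree_nodes(n: int, rng: np.random.Generator) -> list[dict]:
    """Random rooted tree as a node list (helper for property tests)."""
    nodes = [{"id": "n0", "name": "n0", "level": 0, "parent": None}]
    levels = {0: 0}
    for i in range(1, n):
        p = int(rng.integers(0, i))
        levels[i] = levels[p] + 1
        nodes.append({"id": f"n{i}", "name": f"n{i}", "level": levels[i],
                      "parent": f"n{p}"})
    return nodes
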