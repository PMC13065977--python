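"""Shared fixtures: a synthetic screen, its morphospace, a parametric
embedding, simulations at the three reference densities, and a separable
compound library.  Session-scoped because several are expensive to build.
"""

from __future__ import annotations

import numpy as np
import pytest

from gastrumap.embedding import TrainConfig, train_embedding
from gastrumap.morphospace import build_morphospace, label_failure_modes
from gastrumap.pde import ModelParams, simulate
from gastrumap.phenotype import radial_bin, robust_scale
from gastrumap.synth import PatternSpec, gen_colony, gen_compound_library, gen_screen


@pytest.fixture(scope="session")
def screen():
    """14 treatments x 10 reps: controls + 3 colonies per pattern class."""
    return gen_screen(n_treatments=14, reps=10, seed=7)


@pytest.fixture(scope="session")
def screen_vectors(screen):
    vectors = [radial_bin(c) for c in screen.colonies]
    plates = [c.plate_id for c in screen.colonies]
    scaled, scalers = robust_scale(vectors, plates)
    return scaled, scalers


@pytest.fixture(scope="session")
def screen_raw_vectors(screen):
    return [radial_bin(c) for c in screen.colonies]


@pytest.fixture(scope="session")
def screen_truth(screen):
    """Per-colony ground truth: pattern class and binary failure flag."""
    classes = [screen.treatment_map[c.treatment].pattern_class for c in screen.colonies]
    failure = np.array([cls != "canonical" for cls in classes])
    return classes, failure


@pytest.fixture(scope="session")
def morpho(screen, screen_vectors, screen_raw_vectors):
    scaled, _ = screen_vectors
    model = build_morphospace(scaled, [c.colony_id for c in screen.colonies],
                              perplexity=30.0, seed=0,
                              raw_vectors=screen_raw_vectors)
    label_failure_modes(model, colonies=screen.colonies)
    return model


@pytest.fixture(scope="session")
def emb_net(screen_vectors, morpho):
    scaled, _ = screen_vectors
    X = np.stack([v.values for v in scaled])
    return train_embedding(X, morpho.coords, TrainConfig(seed=0))


@pytest.fixture(scope="session")
def sims_by_density():
    return {d: simulate(ModelParams(d=d)) for d in (750, 950, 1150)}


@pytest.fixture(scope="session")
def compound_library():
    return gen_compound_library(n_compounds=100, n_clusters=5, sep=10.0, seed=3)


@pytest.fixture()
def canonical_colony():
    return gen_colony(PatternSpec(noise_sd=0.0, density=1000, seed=1), colony_id="canon")
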