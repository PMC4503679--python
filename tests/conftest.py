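import numpy as np
import pytest

from rangerisk import geometry, occurrences, pipeline, synth


@pytest.fixture(scope="session")
def world():
    """A small synthetic study system shared across tests."""
    terrain = synth.make_terrain(64, 64, 4000, seed=11)
    climate = synth.make_climate(terrain, seed=23)
    forest = synth.make_forest(terrain, 0.85, seed=37)
    mask = geometry.habitat_mask(forest, terrain)
    return {"terrain": terrain, "climate": climate, "forest": forest, "mask": mask}


@pytest.fixture(scope="session")
def montane_niche(world):
    """A thermally specialised niche centred on ~2500 m climate."""
    terrain, climate = world["terrain"], world["climate"]
    elev = terrain.data
    cand = np.argwhere((elev >= 2450) & (elev <= 2550))
    r, c = cand[0]
    optimum = np.array([climate.layers[v][r, c] for v in climate.names])
    sds = np.array([climate.layers[v].std() for v in climate.names])
    breadth = sds * np.array([0.25, 1.0, 1.0, 1.0])
    return synth.NicheSpec("NICHE-2500", optimum, breadth, prevalence=40)


@pytest.fixture(scope="session")
def montane_occurrences(world, montane_niche):
    occ = synth.sample_occurrences(
        montane_niche, world["climate"], world["terrain"], world["forest"], seed=5
    )
    return occurrences.dedupe(occ)


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run at the default configuration (seed 0),
    shared by the pipeline and acceptance tests."""
    return pipeline.run(pipeline.PipelineConfig())
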