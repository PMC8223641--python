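import numpy as np
import pandas as pd
import pytest

from dietmeta import pipeline, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210402)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete 4-cohort simulation."""
    return simulate.SimulationConfig(
        n_per_cohort=(120, 60, 60, 40), n_foods=12, n_food_blocks=4,
        n_taxa=24, n_pathways=30,
        planted_effects=(
            simulate.PlantedEffect(food=0, feature=3, kind="pathway",
                                   beta=0.5),
            simulate.PlantedEffect(food=5, feature=10, kind="taxa",
                                   beta=0.3),
        ),
        seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate.simulate_cohorts(tiny_config)


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    """One full pipeline run on the tiny simulated study."""
    return pipeline.run_pipeline(
        pipeline.PipelineConfig(simulation=tiny_config, seed=42))


@pytest.fixture()
def simple_intake():
    """Three subjects x three foods, hand-checkable numbers."""
    from dietmeta import ffq

    items = pd.DataFrame(
        {"yoghurt": [100.0, 0.0, 50.0],
         "buttermilk": [150.0, 0.0, 0.0],
         "milk": [50.0, 200.0, 0.0]},
        index=pd.Index(["s1", "s2", "s3"], name="subject_id"))
    kcal = pd.Series([2000.0, 1500.0, 1000.0], index=items.index, name="kcal")
    return ffq.IntakeMatrix(items=items,
                            nutrients=pd.DataFrame(index=items.index),
                            kcal=kcal)
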