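import warnings

import numpy as np
import pytest

import msmcox as mc
from msmcox.simulate import (
    illness_death_graph,
    illness_death_spec,
    simulate_paths,
)


@pytest.fixture(scope="session")
def toy():
    return mc.make_fixture("toy-3-subjects")


@pytest.fixture(scope="session")
def illness_death():
    """Mid-size illness-death cohort with a binary covariate (true log HR =
    ln 2 on healthy -> ill), shared across tests."""
    graph = illness_death_graph()
    spec = illness_death_spec()
    subjects, truth = simulate_paths(graph, spec, n=500, seed=4242)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        episodes = mc.expand_to_episodes(subjects, graph)
    return {
        "graph": graph, "spec": spec, "subjects": subjects,
        "truth": truth, "episodes": episodes,
    }


@pytest.fixture(scope="session")
def id_fit(illness_death):
    return mc.fit_msm(
        illness_death["episodes"], illness_death["graph"],
        {("healthy", "ill"): ["treat"]},
    )


@pytest.fixture(scope="session")
def two_state():
    """Simple alive -> dead cohort for survival-reduction identities."""
    graph = mc.build_graph(["alive", "dead"], [("alive", "dead")])
    spec = mc.IntensitySpec(
        hazards={("alive", "dead"): mc.TransitionHazard(rate=0.1)},
        censoring_time=15.0,
        initial_dist={"alive": 1.0},
    )
    subjects, truth = simulate_paths(graph, spec, n=300, seed=77)
    episodes = mc.expand_to_episodes(subjects, graph)
    return {"graph": graph, "spec": spec, "subjects": subjects,
            "truth": truth, "episodes": episodes}
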