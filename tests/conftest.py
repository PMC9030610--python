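import pytest

import herbvec as hv


@pytest.fixture(scope="session")
def activity_profiles():
    return hv.load_fixture_activity()


@pytest.fixture(scope="session")
def trait_profiles():
    return hv.load_fixture_traits()


@pytest.fixture(scope="session")
def score_table(activity_profiles):
    return hv.score_panel(activity_profiles)


@pytest.fixture(scope="session")
def ab_clustering(score_table):
    """Exact k=3 clustering of the 15-herb (alpha, beta) panel, canonical labels."""
    points = score_table.coordinates("alpha", "beta")
    return hv.kmeans_exact(points, hv.ClusterConfig(k=3))
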