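import pytest
from hypothesis import HealthCheck, settings

import orgroutes as orr

settings.register_profile(
    "default",
    max_examples=60,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trp_db():
    return orr.build_trp_fixture()


@pytest.fixture(scope="session")
def carnitine_db():
    return orr.build_carnitine_fixture()


@pytest.fixture(scope="session")
def ahl_db():
    return orr.build_ahl_fixture()


@pytest.fixture(scope="session")
def trp_selection(trp_db):
    return orr.select_organisms(trp_db.org_matrix, orr.GI_HUMAN_QUERY)


def gi_human_config(db, starts, goals, **kw):
    selected = orr.select_organisms(db.org_matrix, orr.GI_HUMAN_QUERY)
    return orr.SearchConfig(tuple(starts), tuple(goals), selected, **kw)


@pytest.fixture(scope="session")
def trp_routes(trp_db):
    cfg = gi_human_config(trp_db, ["L-TRYPTOPHAN"], ["INDOXYL-SULFATE"], k=3, max_len=9)
    routes, status = orr.search_routes(trp_db, cfg)
    assert status == "complete"
    return routes


@pytest.fixture(scope="session")
def carnitine_routes(carnitine_db):
    cfg = gi_human_config(carnitine_db, ["L-CARNITINE"], ["TMAO"], k=3, max_len=7)
    routes, status = orr.search_routes(carnitine_db, cfg)
    assert status == "complete"
    return routes


@pytest.fixture(scope="session")
def ahl_routes(ahl_db):
    cfg = gi_human_config(
        ahl_db, ["S-ADENOSYLMETHIONINE"], ["L-HOMOSERINE-LACTONE"], k=4, max_len=4
    )
    routes, status = orr.search_routes(ahl_db, cfg)
    assert status == "complete"
    return routes
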