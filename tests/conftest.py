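import numpy as np
import pytest

from hdml.builders import build
from hdml.core_schema import core_registry
from hdml.fixtures import SessionRecipe, generate_session


@pytest.fixture(scope="session")
def reg():
    """Shared read-only registry with the mini core schema."""
    return core_registry()


@pytest.fixture(scope="session")
def session_container():
    return generate_session(SessionRecipe(seed=1))


@pytest.fixture(scope="session")
def session_tree(reg, session_container):
    return build(session_container, reg)


def random_container(rng, reg):
    """A random small standalone container (no cross-tree references) for
    mapper round-trip checks."""
    from hdml.containers import DynamicTable, Position, SpatialSeries, TimeSeries
    from hdml.containers import add_ragged_column

    kind = rng.integers(4)
    if kind == 0:
        n = int(rng.integers(1, 30))
        ndim = int(rng.integers(1, 3))
        shape = (n,) if ndim == 1 else (n, int(rng.integers(1, 4)))
        data = rng.normal(size=shape)
        if rng.random() < 0.5:
            return TimeSeries(
                f"ts{rng.integers(100)}", data, unit="volts",
                rate=float(rng.uniform(1, 100)),
                starting_time=float(rng.uniform(0, 5)),
                description="random series",
            )
        return TimeSeries(
            f"ts{rng.integers(100)}", data, unit="volts",
            timestamps=np.sort(rng.uniform(0, 10, size=n)),
            description="random series",
        )
    if kind == 1:
        t = DynamicTable(f"table{rng.integers(100)}", description="random table")
        n = int(rng.integers(0, 8))
        t.add_column("value", rng.normal(size=n), description="numbers")
        t.add_column("label", [f"l{i}" for i in range(n)], description="labels")
        if rng.random() < 0.7:
            rows = [rng.normal(size=int(rng.integers(0, 4))) for _ in range(n)]
            add_ragged_column(t, "events", rows, description="ragged numbers")
        return t
    if kind == 2:
        n = int(rng.integers(1, 20))
        return Position(
            "Position",
            [
                SpatialSeries(
                    "pos", rng.normal(size=(n, 2)),
                    reference_frame="origin", rate=30.0,
                    description="walk",
                )
            ],
        )
    from hdml.fixtures import generate_session as gen

    return gen(SessionRecipe(seed=int(rng.integers(100)), duration_s=2.0,
                             sampling_rate_hz=50.0, n_units=2, n_rois=1))
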