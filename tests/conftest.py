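import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from karyocourt.formats_io import ScaffoldSet


@pytest.fixture
def small_set():
    return ScaffoldSet("asm", [("A", 2_000_000), ("B", 5_000_000), ("C", 1_000_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pairs_frame(rng, scaffolds, n):
    """Random canonical pairs over a scaffold set, as a DataFrame."""
    import pandas as pd

    names = scaffolds.names
    order = {n_: i for i, n_ in enumerate(names)}
    lengths = {s.name: s.length for s in scaffolds}
    c1 = rng.integers(0, len(names), size=n)
    c2 = rng.integers(0, len(names), size=n)
    p1 = (rng.random(n) * np.array([lengths[names[i]] for i in c1])).astype(int)
    p2 = (rng.random(n) * np.array([lengths[names[i]] for i in c2])).astype(int)
    rows = []
    for i in range(n):
        a = (names[c1[i]], int(p1[i]))
        b = (names[c2[i]], int(p2[i]))
        if (order[a[0]], a[1]) > (order[b[0]], b[1]):
            a, b = b, a
        rows.append((f"r{i}", a[0], a[1], b[0], b[1], "+", "-", "UU"))
    return pd.DataFrame(rows, columns=[
        "read_id", "scaffold1", "pos1", "scaffold2", "pos2",
        "strand1", "strand2", "pair_type"])
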