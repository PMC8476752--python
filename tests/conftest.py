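import numpy as np
import pandas as pd
import pytest

from icpscore.signatures import GeneSet, SignatureCollection


def make_clinical(times, events):
    """Clinical table from parallel time/event sequences."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    return pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index([f"s{i}" for i in range(len(times))], name="sample"),
    )


def random_survival(rng, n, beta=0.0, x=None, censor_scale=None):
    """Exponential survival with optional covariate effect and censoring."""
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(1.0 / np.exp(beta * x))
    if censor_scale is None:
        time, event = t, np.ones(n, dtype=int)
    else:
        c = rng.exponential(censor_scale, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    return x, make_clinical(time, event)


@pytest.fixture
def clinical_basic():
    return make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])


@pytest.fixture
def tiny_collection():
    return SignatureCollection([
        GeneSet("Bcell", frozenset({"CD19", "MS4A1", "CD79A"}), ["lit1"]),
        GeneSet("NK", frozenset({"NKG7", "GNLY", "KLRD1"}), ["lit2"]),
        GeneSet("CD8T", frozenset({"CD8A", "CD8B", "GZMK"}), ["lit3"]),
    ])


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sig.gmt"
    path.write_text(
        "Bcell\tsrc1\tCD19\tMS4A1\n"
        "NK\tsrc2\tNKG7\tGNLY\tKLRD1\n"
        "CD8T\tsrc3\tCD8A\tCD8B\n",
        encoding="utf-8",
    )
    return path
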