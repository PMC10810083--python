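import numpy as np
import pytest

from cofluct import edges, events, synth


@pytest.fixture(scope="session")
def default_dataset():
    """Stock synthetic dataset plus every per-subject derived object."""
    cfg = synth.default_config()
    sc, truth = synth.generate_modular_connectome(cfg)
    ts = synth.generate_parcel_timeseries(cfg, truth)
    z = edges.standardize_timeseries(ts)
    ets = edges.compute_edge_timeseries(z)
    fc = edges.compute_static_fc(z)
    rms = edges.compute_rms(ets)
    extrema = events.find_local_extrema(rms)
    null = events.build_null_peak_distribution(z, n_runs=100, seed=0)
    table = events.detect_events(extrema, null)
    cats = events.categorize_frames(extrema, table, rms.n_frames)
    return {
        "cfg": cfg, "sc": sc, "truth": truth, "ts": ts, "z": z, "ets": ets,
        "fc": fc, "rms": rms, "extrema": extrema, "null": null,
        "events": table, "categories": cats,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_standardized(n=5, t=50, seed=0):
    r = np.random.default_rng(seed)
    ts = edges.ParcelTimeSeries(r.standard_normal((n, t)))
    return edges.standardize_timeseries(ts)
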