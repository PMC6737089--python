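import numpy as np
import pytest

from avakit import BinaryRaster, make_stimulus_protocol


@pytest.fixture(scope="session")
def protocol_2p():
    """The 2-photon tone design: 9 freqs x 3 levels x 5 reps."""
    return make_stimulus_protocol(seed=42)


@pytest.fixture(scope="session")
def protocol_small():
    """A short protocol for fast end-to-end tests."""
    return make_stimulus_protocol(reps=2, isi_range=(1.0, 1.5), seed=7)


def naive_extract(active: np.ndarray):
    """Frame-walking reference for ensemble extraction (deliberately naive).

    Returns a list of dicts with start, end, size, duration and the
    member -> frames-active map, scanning frame by frame in pure Python.
    """
    n_neurons, n_frames = active.shape
    out = []
    cur = None
    for t in range(n_frames):
        frame_active = [i for i in range(n_neurons) if active[i, t]]
        if frame_active:
            if cur is None:
                cur = {"start": t, "members": {}}
            cur["end"] = t
            for i in frame_active:
                cur["members"][i] = cur["members"].get(i, 0) + 1
        else:
            if cur is not None:
                out.append(cur)
                cur = None
    if cur is not None:
        out.append(cur)
    for e in out:
        e["duration"] = e["end"] - e["start"] + 1
        e["size"] = sum(e["members"].values())
    return out


@pytest.fixture
def random_binary_raster():
    def make(n_neurons=30, n_frames=300, p=0.02, seed=0, frame_rate=30.0):
        rng = np.random.default_rng(seed)
        return BinaryRaster(
            rng.random((n_neurons, n_frames)) < p, frame_rate=frame_rate
        )

    return make
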