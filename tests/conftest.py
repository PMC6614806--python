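import numpy as np
import pytest

from pitbind.config import RunConfig


def _deep_merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@pytest.fixture
def make_config():
    """Factory for small, fast run configurations (overridable per test)."""

    base = {
        "seed": 1,
        "n_replicates": 3,
        "geometry": {"n_pits": 2},
        "schedule": {
            "frames_per_video": 25,
            "video_interval_s": 600.0,
            "total_duration_s": 3600.0,
        },
        "species": {"n_probes_per_pit": 10, "n_plasmids_per_pit": 5},
        "kinetics": {"P0": 100.0, "U0": 10.0, "K": 5e-4},
        "analysis": {"min_track_length": 10, "n_reference": 100},
    }

    def factory(**overrides) -> RunConfig:
        return RunConfig.from_dict(_deep_merge(base, overrides))

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
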