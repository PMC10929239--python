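import numpy as np
import pytest
from hypothesis import settings

from gliaquant.synthetic import SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_cfg():
    """Desk-scale acquisition geometry (same calibration, smaller field/lapse)."""

    def make(seed=0, **kw):
        defaults = dict(image_shape=(160, 160), n_frames=6, seed=seed)
        defaults.update(kw)
        return SimConfig(**defaults)

    return make


def brute_force_counts(mask_t: np.ndarray, mask_t1: np.ndarray) -> tuple[int, int, int]:
    """Independent per-pixel loop oracle for extend/retract/stable tallies."""
    extend = retract = stable = 0
    h, w = mask_t.shape
    for y in range(h):
        for x in range(w):
            a, b = bool(mask_t[y, x]), bool(mask_t1[y, x])
            if a and b:
                stable += 1
            elif b:
                extend += 1
            elif a:
                retract += 1
    return extend, retract, stable
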