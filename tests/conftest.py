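import numpy as np
import pytest

import repcount as rc


@pytest.fixture(scope="session")
def template_bank():
    """Noiseless default template registries for all four positions."""
    return rc.default_template_bank()


@pytest.fixture(scope="session")
def chest_registry(template_bank):
    return template_bank[rc.WearPosition.CHEST]


def make_series(xyz, fs=100.0, position=rc.WearPosition.CHEST):
    xyz = np.asarray(xyz, dtype=float)
    return rc.AccelSeries(
        fs=fs, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2], position=position
    )


def make_segment(data, fs=100.0, position="chest", label=None, start=0):
    data = np.asarray(data, dtype=float)
    return rc.MotionSegment(
        start_idx=start,
        end_idx=start + len(data),
        data=data,
        fs=fs,
        position=position,
        label=label,
    )
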