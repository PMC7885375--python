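import numpy as np
import pytest

from tactconn.montage import Montage, TrialSet, load_default_montage


@pytest.fixture(scope="session")
def montage():
    """The packaged 62-channel montage with default neighbours."""
    return load_default_montage()


@pytest.fixture(scope="session")
def small_montage():
    """A minimal 6-channel montage: 2 left, 2 right, 2 midline."""
    return Montage(
        name="toy6",
        channel_names=("L1", "L2", "R1", "R2", "Z1", "Z2"),
        positions=np.array(
            [[-1.0, 0.5], [-1.0, -0.5], [1.0, 0.5], [1.0, -0.5],
             [0.0, 0.5], [0.0, -0.5]]
        ),
        hemisphere=("left", "left", "right", "right", "midline", "midline"),
        flip_map={"L1": "R1", "R1": "L1", "L2": "R2", "R2": "L2",
                  "Z1": "Z1", "Z2": "Z2"},
        neighbors={
            "L1": frozenset({"L2", "Z1"}), "L2": frozenset({"L1", "Z2"}),
            "R1": frozenset({"R2", "Z1"}), "R2": frozenset({"R1", "Z2"}),
            "Z1": frozenset({"L1", "R1", "Z2"}),
            "Z2": frozenset({"L2", "R2", "Z1"}),
        },
    )


def grid_montage(n_side: int = 4) -> Montage:
    """A square-grid montage with equal left/right columns (no midline)."""
    names, pos, hemi, flip = [], [], [], {}
    half = n_side // 2
    for r in range(n_side):
        for c in range(n_side):
            name = f"G{r}{c}"
            names.append(name)
            pos.append([c - (n_side - 1) / 2.0, -(r - (n_side - 1) / 2.0)])
            hemi.append("left" if c < half else "right")
            flip[name] = f"G{r}{n_side - 1 - c}"
    return Montage(
        name=f"grid{n_side}",
        channel_names=tuple(names),
        positions=np.array(pos),
        hemisphere=tuple(hemi),
        flip_map=flip,
    )


@pytest.fixture(scope="session")
def grid16():
    return grid_montage(4)


def make_trials(data, rate=1000.0, channel_names=None, condition=None,
                limb=None, **kw):
    n_trials, n_ch, _ = data.shape
    return TrialSet(
        data=data,
        rate=rate,
        channel_names=channel_names or tuple(f"ch{i}" for i in range(n_ch)),
        condition=np.array(condition or ["baseline"] * n_trials, dtype=object),
        limb=np.array(limb or ["left"] * n_trials, dtype=object),
        **kw,
    )
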