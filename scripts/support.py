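"""Helpers for the acceptance script."""

import numpy as np

from tactconn.montage import Montage


def grid_montage_16() -> Montage:
    """A 4x4 grid montage with two left and two right columns."""
    names, pos, hemi, flip = [], [], [], {}
    for r in range(4):
        for c in range(4):
            name = f"G{r}{c}"
            names.append(name)
            pos.append([c - 1.5, -(r - 1.5)])
            hemi.append("left" if c < 2 else "right")
            flip[name] = f"G{r}{3 - c}"
    return Montage(
        name="grid4",
        channel_names=tuple(names),
        positions=np.array(pos),
        hemisphere=tuple(hemi),
        flip_map=flip,
    )
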