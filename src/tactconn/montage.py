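"""Sensor montage and recording data model.

A :class:`Montage` carries everything the pipeline needs to know about the
electrode array: channel labels (10–20 nomenclature), flattened 2-D scalp
positions (x positive toward the right ear, y anterior), the hemisphere
partition used by the inter/intra-hemispheric indices, the left/right
homologue map used for the mid-sagittal flip, and a spatial neighbour
relation used by the edge-clustering step.

The packaged default is a 62-channel layout (a standard 64-channel 10–20
cap with ground and reference removed), with positions symmetrised across
the mid-sagittal plane so that the flip is an exact involution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, distance_matrix

__all__ = [
    "Montage",
    "Recording",
    "TrialSet",
    "MontageError",
    "load_default_montage",
    "neighbors_from_positions",
    "flip_mid_sagittal",
]

#: |x| below this is considered on the mid-sagittal line.
MIDLINE_TOL = 1e-6


class MontageError(ValueError):
    """Raised for inconsistent montage definitions or unknown channels."""


@dataclass(frozen=True)
class Montage:
    """Channel identities, scalp geometry and hemisphere structure."""

    name: str
    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), x = right, y = anterior
    hemisphere: tuple[str, ...]  # each in {"left", "right", "midline"}
    flip_map: Mapping[str, str]
    neighbors: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (n, 2):
            raise MontageError(f"positions must be ({n}, 2), got {pos.shape}")
        object.__setattr__(self, "positions", pos)
        if len(self.hemisphere) != n:
            raise MontageError("hemisphere labels must match channel count")
        if len(set(self.channel_names)) != n:
            raise MontageError("duplicate channel labels")
        for ch, hemi in zip(self.channel_names, self.hemisphere):
            x = pos[self.channel_names.index(ch), 0]
            if hemi == "midline" and abs(x) > MIDLINE_TOL:
                raise MontageError(f"midline channel {ch} has |x| = {abs(x)}")
            if hemi == "left" and x >= -MIDLINE_TOL:
                raise MontageError(f"left channel {ch} has x = {x}")
            if hemi == "right" and x <= MIDLINE_TOL:
                raise MontageError(f"right channel {ch} has x = {x}")
        for ch in self.channel_names:
            if ch not in self.flip_map:
                raise MontageError(f"flip_map missing channel {ch}")
            if self.flip_map[self.flip_map[ch]] != ch:
                raise MontageError(f"flip_map not involutive at {ch}")
        for ch, nbrs in self.neighbors.items():
            if ch in nbrs:
                raise MontageError(f"channel {ch} is its own neighbor")
            for other in nbrs:
                if ch not in self.neighbors.get(other, frozenset()):
                    raise MontageError(
                        f"neighbor relation not symmetric: {ch}-{other}"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_pairs(self) -> int:
        """Number of unordered channel pairs (1891 for 62 channels)."""
        n = self.n_channels
        return n * (n - 1) // 2

    def index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise MontageError(f"unknown channel {label!r}") from None

    def hemisphere_of(self, label: str) -> str:
        return self.hemisphere[self.index(label)]

    def channels_in(self, hemi: str) -> tuple[str, ...]:
        return tuple(
            ch for ch, h in zip(self.channel_names, self.hemisphere) if h == hemi
        )

    @property
    def left_channels(self) -> tuple[str, ...]:
        return self.channels_in("left")

    @property
    def right_channels(self) -> tuple[str, ...]:
        return self.channels_in("right")

    @property
    def midline_channels(self) -> tuple[str, ...]:
        return self.channels_in("midline")

    def pair_labels(self) -> list[tuple[str, str]]:
        """All unordered channel pairs in row-major (i < j) order."""
        names = self.channel_names
        return [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]

    def with_neighbors(self, neighbors: Mapping[str, frozenset[str]]) -> "Montage":
        return replace(self, neighbors={k: frozenset(v) for k, v in neighbors.items()})

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_json(cls, doc: Mapping) -> "Montage":
        chans = doc["channels"]
        names = tuple(c["label"] for c in chans)
        positions = np.array([[c["x"], c["y"]] for c in chans], dtype=float)
        hemisphere = tuple(c["hemisphere"] for c in chans)
        flip_map = {c["label"]: c.get("homologue", c["label"]) for c in chans}
        return cls(
            name=doc.get("name", "unnamed"),
            channel_names=names,
            positions=positions,
            hemisphere=hemisphere,
            flip_map=flip_map,
        )

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "version": 1,
            "channels": [
                {
                    "label": ch,
                    "x": float(self.positions[i, 0]),
                    "y": float(self.positions[i, 1]),
                    "hemisphere": self.hemisphere[i],
                    "homologue": self.flip_map[ch],
                }
                for i, ch in enumerate(self.channel_names)
            ],
        }

    @classmethod
    def from_file(cls, path) -> "Montage":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def load_default_montage(with_neighbors: bool = True) -> Montage:
    """Load the packaged 62-channel montage.

    Parameters
    ----------
    with_neighbors
        If true (default), attach the default Delaunay-based spatial
        neighbour relation.
    """
    text = resources.files("tactconn.data").joinpath("montage62.json").read_text()
    montage = Montage.from_json(json.loads(text))
    if with_neighbors:
        montage = montage.with_neighbors(neighbors_from_positions(montage))
    return montage


def neighbors_from_positions(
    montage: Montage,
    rule: str = "delaunay",
    param: float | None = None,
) -> dict[str, frozenset[str]]:
    """Derive a symmetric, irreflexive spatial neighbour relation.

    ``rule="delaunay"`` triangulates the 2-D positions and drops edges
    longer than ``param`` (default 1.5) times the median edge length —
    the long border-hugging edges of a Delaunay triangulation of a head
    outline are not physically adjacent sensors. ``rule="distance"``
    connects channels closer than the absolute threshold ``param``.
    """
    pos = montage.positions
    names = montage.channel_names
    if len(names) < 2:
        raise MontageError("need at least 2 channels for a neighbor relation")
    edges: set[tuple[int, int]] = set()
    if rule == "delaunay":
        if len(names) < 3:
            raise MontageError("Delaunay rule needs >= 3 channels")
        try:
            tri = Delaunay(pos)
        except Exception as exc:  # QhullError on degenerate input
            raise MontageError(f"Delaunay triangulation failed: {exc}") from exc
        if tri.simplices.size == 0:
            raise MontageError("Delaunay triangulation produced no simplices")
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                edges.add((int(i), int(j)))
        lengths = {e: float(np.linalg.norm(pos[e[0]] - pos[e[1]])) for e in edges}
        cutoff = (1.5 if param is None else float(param)) * float(
            np.median(list(lengths.values()))
        )
        edges = {e for e in edges if lengths[e] <= cutoff}
    elif rule == "distance":
        if param is None:
            raise MontageError("distance rule requires a threshold param")
        dm = distance_matrix(pos, pos)
        idx_i, idx_j = np.nonzero((dm <= float(param)) & (dm > 0))
        edges = {(int(i), int(j)) for i, j in zip(idx_i, idx_j) if i < j}
    else:
        raise MontageError(f"unknown neighbor rule {rule!r}")

    out: dict[str, set[str]] = {ch: set() for ch in names}
    for i, j in edges:
        out[names[i]].add(names[j])
        out[names[j]].add(names[i])
    return {ch: frozenset(v) for ch, v in out.items()}


@dataclass
class Recording:
    """Continuous multichannel recording with condition markers.

    ``samples`` is channel x time in microvolts; ``annotations`` is a list
    of ``(onset_seconds, label)`` condition markers.
    """

    samples: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channel x time")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match samples rows")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        dur = self.duration
        for onset, _label in self.annotations:
            if not (0 <= onset <= dur):
                raise ValueError(f"annotation onset {onset} outside record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class TrialSet:
    """Epoched trials with condition / limb / subject labels.

    ``data`` is trial x channel x sample. ``condition`` and ``limb`` are
    per-trial label arrays; all trials are equal length.
    """

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    condition: np.ndarray  # per trial, e.g. "baseline" / "stimulation"
    limb: np.ndarray  # per trial, e.g. "left" / "right"
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trial x channel x sample")
        self.condition = np.asarray(self.condition, dtype=object)
        self.limb = np.asarray(self.limb, dtype=object)
        n = self.data.shape[0]
        if len(self.condition) != n or len(self.limb) != n:
            raise ValueError("condition/limb labels must match trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, condition: str | None = None, limb: str | None = None) -> "TrialSet":
        """Subset of trials matching the given condition and/or limb."""
        mask = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            mask &= self.condition == condition
        if limb is not None:
            mask &= self.limb == limb
        return TrialSet(
            data=self.data[mask],
            rate=self.rate,
            channel_names=self.channel_names,
            condition=self.condition[mask],
            limb=self.limb[mask],
            subject_id=self.subject_id,
            group=self.group,
        )


def flip_mid_sagittal(trials: TrialSet, montage: Montage) -> TrialSet:
    """Exchange homologous left/right channels (midline unchanged).

    Used to pool subjects with left- and right-hemisphere lesions: after
    the flip the affected hemisphere occupies the same side for everyone.
    Applying the flip twice restores the original trial set exactly.
    """
    perm = np.empty(len(trials.channel_names), dtype=int)
    idx = {ch: i for i, ch in enumerate(trials.channel_names)}
    for i, ch in enumerate(trials.channel_names):
        try:
            target = montage.flip_map[ch]
        except KeyError:
            raise MontageError(f"channel {ch} has no homologue in flip_map") from None
        if target not in idx:
            raise MontageError(f"homologue {target} of {ch} not in trial set")
        perm[idx[target]] = i
    return TrialSet(
        data=trials.data[:, perm, :],
        rate=trials.rate,
        channel_names=trials.channel_names,
        condition=trials.condition.copy(),
        limb=trials.limb.copy(),
        subject_id=trials.subject_id,
        group=trials.group,
    )
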