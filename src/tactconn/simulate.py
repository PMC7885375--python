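"""Synthetic cohorts with planted phase-lagged coupling.

The generator emulates the recording design of a two-group fabric-
stimulation study: per group, 8 subjects x 2 forearms x 2 conditions
(baseline / stimulation) x 9 four-second trials at 1000 Hz on the
62-channel montage — 288 trials per group.

Each trial is pink (1/f) background noise per channel, on which coupling
is planted edge by edge: a band-limited latent source is injected into
one channel and a lag-delayed copy into the other, producing genuine
imaginary coherence at the edge's band. A zero-lag "volume-conduction"
mixer adds the *same* instantaneous source to several channels — this
creates real cross-spectral correlation whose coherency is purely real,
so imaginary coherence must (and does) suppress it.

Source amplitudes are calibrated so that the planted pair's band
coherence magnitude is approximately the requested ``strength``: if the
per-channel in-band noise power is P_n, injecting source power
a^2 = P_n * s / (1 - s) into both channels gives in-band coherence
a^2 / (a^2 + P_n) = s. Hann tapering and finite segments blur this
slightly; the planted ImCoh is further scaled by |sin(2*pi*f*lag)|.

Lateralization: stimulation-condition edges are written as if the *left*
forearm were stimulated (channels on the contralateral right hemisphere).
A fraction ``lateralization`` of the planted edges stays contralateral to
the stimulated limb; the remaining ``round((1 - f) * n_edges)`` edges are
mirrored to the ipsilateral side. The mirrored subset is drawn once per
group x limb (seeded), so every subject of a group carries the same edge
layout and the within-subject stimulation-baseline contrast accumulates
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .montage import Montage, MontageError, TrialSet, load_default_montage

__all__ = [
    "CoupledEdge",
    "ZeroLagMixing",
    "BackgroundModulation",
    "LaggedBroadcast",
    "CouplingSpec",
    "CohortConfig",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "default_control_specs",
    "default_stroke_specs",
]


@dataclass(frozen=True)
class CoupledEdge:
    """One planted coupling: a lagged shared source between two channels."""

    ch_i: str
    ch_j: str
    band_hz: tuple[float, float] = (20.0, 25.0)
    lag_ms: float = 12.5
    strength: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError(f"strength must be in [0, 1], got {self.strength}")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError(f"invalid band {self.band_hz}")


@dataclass(frozen=True)
class ZeroLagMixing:
    """Instantaneous spread of one source into several channels (nuisance)."""

    channels: tuple[str, ...]
    weights: tuple[float, ...]
    band_hz: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.weights):
            raise ValueError("channels and weights must align")


@dataclass(frozen=True)
class BackgroundModulation:
    """Subject-specific diffuse network recruitment in one condition.

    For every subject, ``n_sources`` latent band-limited sources are each
    broadcast to ``channels_per_source`` randomly chosen channels with
    channel-specific lags — emulating the broad recruitment of a cortical
    network: every channel pair sharing a source acquires genuine
    imaginary coherence, and the shared-source structure produces the
    triangles that give subject networks realistic local efficiency. The
    layout is fixed within a subject (so the trial-wise stimulation
    vs baseline contrast detects it and the subject's binary network
    reaches a realistic density) but differs across subjects, so the
    diffuse component does not align into group-level SFC.
    """

    n_sources: int = 3
    channels_per_source: int = 15
    strength: float = 0.6
    #: draw source channels only from channels free of planted edges, so
    #: the diffuse sources do not split band power with the planted
    #: coupling (which would dilute both below the detection floor)
    avoid_planted: bool = True
    band_hz: tuple[float, float] = (20.0, 25.0)
    #: channels of one source are split into three lag groups a third of
    #: a beta-2 cycle apart, so every cross-group pair carries a large
    #: phase lag (strong imaginary coherence) and detected pairs form
    #: tri-partite motifs rich in triangles
    phase_lags_ms: tuple[float, ...] = (3.0, 17.8, 32.6)
    lag_jitter_ms: float = 1.0


@dataclass(frozen=True)
class LaggedBroadcast:
    """A concrete latent source spread to several channels with lags."""

    channels: tuple[str, ...]
    weights: tuple[float, ...]
    lags_ms: tuple[float, ...]
    band_hz: tuple[float, float] = (20.0, 25.0)


@dataclass(frozen=True)
class CouplingSpec:
    """Coupling planted in one condition (optionally one stimulated limb).

    ``limb=None`` applies to stimulation of either forearm. Edge channels
    name the layout for *left*-forearm stimulation; the generator mirrors
    them for the right forearm (and for ipsilateral placements).
    """

    condition: str = "stimulation"
    limb: str | None = None
    edges: tuple[CoupledEdge, ...] = ()
    zero_lag: tuple[ZeroLagMixing, ...] = ()
    lateralized: bool = True  # subject to the lateralization fraction
    background: BackgroundModulation | None = None
    broadcasts: tuple[LaggedBroadcast, ...] = ()  # filled per subject


@dataclass(frozen=True)
class CohortConfig:
    """Design of one simulated cohort (defaults follow the study design)."""

    n_subjects: int = 8
    rate: float = 1000.0
    trial_s: float = 4.0
    n_trials: int = 9  # per condition per limb
    conditions: tuple[str, str] = ("baseline", "stimulation")
    limbs: tuple[str, str] = ("left", "right")
    noise_model: str = "pink"
    noise_sd: float = 1.0
    lateralization: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "limbs", tuple(self.limbs))
        if min(self.n_subjects, self.n_trials) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.lateralization <= 1.0):
            raise ValueError("lateralization must be a fraction in [0, 1]")
        if self.noise_model not in ("pink", "white"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.rate))

    @property
    def trials_per_group(self) -> int:
        """N = N_condition x N_trial x N_forearm x N_subject."""
        return (
            len(self.conditions) * self.n_trials * len(self.limbs) * self.n_subjects
        )


# -- noise and sources ---------------------------------------------------


def _noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, rate: float,
    model: str, sd: float,
) -> np.ndarray:
    white = rng.standard_normal((n_ch, n_samp))
    if model == "white":
        return sd * white
    # pink: shape the amplitude spectrum by 1/sqrt(f), then rescale to sd
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    pink *= sd / pink.std(axis=-1, keepdims=True)
    return pink


from functools import lru_cache


@lru_cache(maxsize=64)
def _band_sos(lo: float, hi: float, rate: float) -> np.ndarray:
    return signal.butter(4, (lo, hi), btype="bandpass", fs=rate, output="sos")


def _bandlimited_source(
    rng: np.random.Generator, n_samp: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError(f"band {band} outside (0, {rate / 2})")
    x = rng.standard_normal(n_samp)
    y = signal.sosfiltfilt(_band_sos(lo, hi, rate), x)
    return y / y.std()


def _inband_noise_power(
    rate: float, band: tuple[float, float], model: str, sd: float
) -> float:
    """Approximate variance of the noise inside ``band``.

    White noise spreads its power evenly over (0, rate/2]; pink noise
    spreads it as 1/f between 1 Hz and Nyquist, so the in-band fraction
    is log(hi/lo) / log(nyquist/1).
    """
    lo, hi = band
    nyq = rate / 2
    if model == "white":
        frac = (hi - lo) / nyq
    else:
        lo = max(lo, 1.0)
        frac = np.log(hi / lo) / np.log(nyq / 1.0)
    return sd**2 * frac


def simulate_trial(
    spec: CouplingSpec | Sequence[CouplingSpec],
    config: CohortConfig,
    rng: np.random.Generator,
    montage: Montage | None = None,
) -> np.ndarray:
    """One channel x sample trial realizing the planted couplings.

    ``spec`` may be a single :class:`CouplingSpec` or a sequence; all
    edges and zero-lag mixers found are planted (condition/limb labels
    are not interpreted here — the caller selects what applies).
    """
    montage = montage or load_default_montage(with_neighbors=False)
    specs = [spec] if isinstance(spec, CouplingSpec) else list(spec)
    n_samp = config.n_samples
    data = _noise(
        rng, montage.n_channels, n_samp, config.rate, config.noise_model,
        config.noise_sd,
    )
    active = []
    for sp in specs:
        for edge in sp.edges:
            lag = int(round(edge.lag_ms * config.rate / 1000.0))
            if lag >= n_samp:
                raise ValueError(
                    f"lag {edge.lag_ms} ms is not shorter than the trial"
                )
            if edge.strength > 0:
                active.append(
                    (montage.index(edge.ch_i), montage.index(edge.ch_j), edge, lag)
                )
    extra_power = np.zeros(montage.n_channels)
    for sp in specs:
        for mix in sp.zero_lag:
            for ch, w in zip(mix.channels, mix.weights):
                # roughly a third of the (band-uniform) mixer power falls
                # in a 5 Hz sub-band of the 15 Hz mixing band
                extra_power[montage.index(ch)] += w**2 / 3.0
        for bc in sp.broadcasts:
            for ch, w in zip(bc.channels, bc.weights):
                extra_power[montage.index(ch)] += w**2
    amps = _calibrate_amplitudes(active, config, montage.n_channels, extra_power)
    for (i, j, edge, lag), amp in zip(active, amps):
        src = _bandlimited_source(rng, n_samp + lag, config.rate, edge.band_hz)
        data[i] += amp * src[lag:]
        data[j] += amp * src[: n_samp]  # j lags i by `lag` samples
    for sp in specs:
        for bc in sp.broadcasts:
            max_lag = int(round(max(bc.lags_ms) * config.rate / 1000.0))
            src = _bandlimited_source(
                rng, n_samp + max_lag, config.rate, bc.band_hz
            )
            for ch, w, lag_ms in zip(bc.channels, bc.weights, bc.lags_ms):
                lag = int(round(lag_ms * config.rate / 1000.0))
                start = max_lag - lag
                data[montage.index(ch)] += w * src[start : start + n_samp]
        for mix in sp.zero_lag:
            src = _bandlimited_source(rng, n_samp, config.rate, mix.band_hz)
            for ch, w in zip(mix.channels, mix.weights):
                data[montage.index(ch)] += w * src
    return data


def _calibrate_amplitudes(
    active, config: CohortConfig, n_ch: int,
    extra_power: np.ndarray | None = None,
) -> np.ndarray:
    """Solve source amplitudes so each edge's band coherence ~ its strength.

    Edge e between channels i, j with amplitude a_e has in-band coherence
    a_e^2 / sqrt(P_i P_j), where P_i = (in-band noise power) + sum of the
    squared amplitudes of every source feeding channel i. The coupled
    system is solved by fixed-point iteration; it is feasible only while
    the per-channel sum of target strengths stays below 1 (the shared
    fraction of a channel's band power cannot exceed the whole), which
    :func:`_background_edges` enforces at draw time.
    """
    if not active:
        return np.array([])
    p_noise = np.array([
        _inband_noise_power(
            config.rate, e.band_hz, config.noise_model, config.noise_sd
        )
        for _, _, e, _ in active
    ])
    s = np.array([min(e.strength, 0.95) for _, _, e, _ in active])
    idx_i = np.array([i for i, _, _, _ in active])
    idx_j = np.array([j for _, j, _, _ in active])
    # project infeasible strength sums back inside the unit budget: a
    # channel's sources cannot claim more than the whole of its band power
    for _ in range(20):
        budget = np.zeros(n_ch)
        np.add.at(budget, idx_i, s)
        np.add.at(budget, idx_j, s)
        worst = budget.max()
        if worst < 0.9:
            break
        scale = np.minimum(
            0.9 / np.maximum(budget[idx_i], 1e-12),
            0.9 / np.maximum(budget[idx_j], 1e-12),
        )
        s = s * np.minimum(scale, 1.0)
    # mixer / broadcast sources add in-band power that dilutes the
    # planted edges' coherence; account for it as a fixed baseline
    base = np.zeros(n_ch) if extra_power is None else extra_power
    a2 = p_noise * s / (1.0 - s)
    for _ in range(200):
        p_ch = base.copy()
        np.add.at(p_ch, idx_i, a2)
        np.add.at(p_ch, idx_j, a2)
        new = s * np.sqrt((p_noise + p_ch[idx_i]) * (p_noise + p_ch[idx_j]))
        if np.allclose(new, a2, rtol=1e-10):
            a2 = new
            break
        a2 = 0.5 * a2 + 0.5 * new
    return np.sqrt(a2)


def _mirror_edge(edge: CoupledEdge, montage: Montage) -> CoupledEdge:
    return replace(
        edge, ch_i=montage.flip_map[edge.ch_i], ch_j=montage.flip_map[edge.ch_j]
    )


def _resolve_specs(
    specs: Sequence[CouplingSpec],
    montage: Montage,
    limb: str,
    condition: str,
    lateralization: float,
    rng: np.random.Generator,
) -> list[CouplingSpec]:
    """Resolve specs for one group x limb x condition.

    Edges are written for left-forearm stimulation; stimulating the right
    forearm mirrors the whole layout first. Of the lateralized edges,
    ``round((1 - lateralization) * n)`` (a seed-chosen subset, shared by
    all subjects) are then mirrored to the ipsilateral side.
    """
    out = []
    for sp in specs:
        if sp.condition != condition:
            continue
        if sp.limb is not None and sp.limb != limb:
            continue
        base_edges = [
            edge if limb == "left" else _mirror_edge(edge, montage)
            for edge in sp.edges
        ]
        mirror = np.zeros(len(base_edges), dtype=bool)
        if sp.lateralized and condition == "stimulation" and base_edges:
            n_mirror = int(round((1.0 - lateralization) * len(base_edges)))
            if n_mirror:
                mirror[rng.choice(len(base_edges), size=n_mirror, replace=False)] = True
        edges = [
            _mirror_edge(e, montage) if flip else e
            for e, flip in zip(base_edges, mirror)
        ]
        zero_lag = sp.zero_lag
        if limb != "left":
            zero_lag = tuple(
                replace(m, channels=tuple(montage.flip_map[c] for c in m.channels))
                for m in zero_lag
            )
        out.append(replace(sp, edges=tuple(edges), zero_lag=zero_lag))
    return out


def _background_broadcasts(
    bg: BackgroundModulation,
    config: CohortConfig,
    montage: Montage,
    rng: np.random.Generator,
    exclude: frozenset[int] = frozenset(),
) -> tuple[LaggedBroadcast, ...]:
    """Draw a subject's diffuse broadcast layout.

    Each source reaches a random channel subset with per-channel lags;
    weights are set so that a pair sharing one source has in-band
    coherence magnitude about ``bg.strength`` on otherwise-quiet
    channels (a share r/(1+r) of the channel's band power, r solved
    from the target).
    """
    p_noise = _inband_noise_power(
        config.rate, bg.band_hz, config.noise_model, config.noise_sd
    )
    s = min(bg.strength, 0.95)
    w = float(np.sqrt(p_noise * s / (1.0 - s)))
    # disjoint channel sets: a channel fed by several diffuse sources
    # would split its band power among them and dilute every pair below
    # the detection floor of the 3-segment trial estimates
    avail = np.array(
        [c for c in range(montage.n_channels)
         if not (bg.avoid_planted and c in exclude)],
        dtype=int,
    )
    pool = rng.permutation(avail)
    out = []
    for k in range(bg.n_sources):
        lo = k * bg.channels_per_source
        hi = lo + bg.channels_per_source
        if hi > len(pool):  # more requested than available: recycle
            pool = np.concatenate([pool, rng.permutation(avail)])
        chans = pool[lo:hi]
        groups = rng.integers(0, len(bg.phase_lags_ms), size=len(chans))
        lags = np.array([bg.phase_lags_ms[g] for g in groups])
        lags = lags + rng.uniform(-bg.lag_jitter_ms, bg.lag_jitter_ms, len(chans))
        out.append(
            LaggedBroadcast(
                channels=tuple(montage.channel_names[int(c)] for c in chans),
                weights=(w,) * len(chans),
                lags_ms=tuple(float(l) for l in lags),
                band_hz=bg.band_hz,
            )
        )
    return tuple(out)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: reproducible regardless of calling order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_subject(
    config: CohortConfig,
    specs: Sequence[CouplingSpec],
    montage: Montage,
    group: str,
    group_idx: int,
    subject_idx: int,
) -> TrialSet:
    """All trials of one subject (conditions x limbs x repetitions)."""
    for sp in specs:
        for edge in sp.edges:
            montage.index(edge.ch_i)
            montage.index(edge.ch_j)
        for mix in sp.zero_lag:
            for ch in mix.channels:
                montage.index(ch)
    trials, conds, limbs = [], [], []
    for li, limb in enumerate(config.limbs):
        # lateralization subset: one substream per group x limb so every
        # subject of a group carries the same layout
        lat_rng = _stream(config.seed, group_idx, li, 1 << 16)
        resolved = {
            cond: _resolve_specs(
                specs, montage, limb, cond, config.lateralization, lat_rng
            )
            for cond in config.conditions
        }
        # diffuse per-subject background: the layout differs per subject
        # but is fixed across that subject's trials
        bg_rng = _stream(config.seed, group_idx, subject_idx, li, 1 << 17)
        for cond, spec_list in resolved.items():
            planted = frozenset(
                montage.index(ch)
                for sp in spec_list
                for e in sp.edges
                for ch in (e.ch_i, e.ch_j)
            )
            for k, sp in enumerate(spec_list):
                if sp.background is not None:
                    spec_list[k] = replace(
                        sp,
                        broadcasts=sp.broadcasts + _background_broadcasts(
                            sp.background, config, montage, bg_rng, planted
                        ),
                    )
        for ci, cond in enumerate(config.conditions):
            for t in range(config.n_trials):
                rng = _stream(config.seed, group_idx, subject_idx, li, ci, t)
                trials.append(
                    simulate_trial(resolved[cond], config, rng, montage)
                )
                conds.append(cond)
                limbs.append(limb)
    return TrialSet(
        data=np.stack(trials),
        rate=config.rate,
        channel_names=montage.channel_names,
        condition=np.array(conds, dtype=object),
        limb=np.array(limbs, dtype=object),
        subject_id=f"{group}{subject_idx:02d}",
        group=group,
    )


def simulate_cohort(
    config: CohortConfig,
    group_specs: dict[str, Sequence[CouplingSpec]] | None = None,
    montage: Montage | None = None,
) -> dict[str, list[TrialSet]]:
    """Simulate every subject of every group; deterministic given seed.

    Returns ``{group: [TrialSet per subject]}``. With the default config
    each group carries ``config.trials_per_group`` (288) trials.
    """
    montage = montage or load_default_montage(with_neighbors=False)
    if group_specs is None:
        group_specs = {
            "control": default_control_specs(),
            "stroke": default_stroke_specs(),
        }
    out: dict[str, list[TrialSet]] = {}
    for gi, (group, specs) in enumerate(sorted(group_specs.items())):
        out[group] = [
            simulate_subject(config, specs, montage, group, gi, si)
            for si in range(config.n_subjects)
        ]
    return out


# -- default study conditions -------------------------------------------

#: Planted stimulation coupling for an unimpaired subject: beta-2
#: phase-lagged edges over the somatosensory region contralateral to the
#: stimulated (left) forearm.
_S1_EDGES = (
    ("FC4", "C4"), ("C4", "CP4"), ("CP4", "P4"), ("P4", "PO4"),
    ("FC6", "C6"), ("C6", "CP6"), ("CP6", "P6"), ("P6", "P8"),
    ("FT10", "FT8"), ("FT8", "T8"), ("T8", "TP8"), ("TP8", "TP10"),
)


def _edges(pairs, strength: float, band=(20.0, 25.0), lag_ms: float = 12.5):
    return tuple(
        CoupledEdge(a, b, band_hz=band, lag_ms=lag_ms, strength=strength)
        for a, b in pairs
    )


def default_control_specs(strength: float = 0.45) -> list[CouplingSpec]:
    """Unimpaired-group coupling: strongly contralateral S1 edges, a
    diffuse subject-specific modulation, and a central zero-lag mixer as
    a volume-conduction nuisance."""
    return [
        CouplingSpec(
            condition="stimulation",
            edges=_edges(_S1_EDGES, strength),
            background=BackgroundModulation(),
            zero_lag=(
                ZeroLagMixing(("Cz", "C1", "C2", "CPz"), (0.5, 0.4, 0.4, 0.3)),
            ),
        ),
        CouplingSpec(
            condition="baseline",
            lateralized=False,
            zero_lag=(
                ZeroLagMixing(("Cz", "C1", "C2", "CPz"), (0.5, 0.4, 0.4, 0.3)),
            ),
        ),
    ]


#: Additional distributed (frontal / temporal / parietal) edges emulating
#: the wider recruitment seen when the affected forearm is stimulated.
_DISTRIBUTED_EDGES = (
    ("F5", "F7"), ("F7", "FT7"), ("FT7", "T7"), ("T7", "TP7"), ("TP7", "P7"),
    ("C5", "CP5"), ("CP5", "P5"), ("P5", "PO7"), ("PO7", "O1"),
)


def default_stroke_specs(
    strength: float = 0.45, distributed_strength: float = 0.4
) -> list[CouplingSpec]:
    """Stroke-group coupling.

    Affected-forearm ("left", by the flipping convention) stimulation
    adds weakly-lateralized distributed (frontal / temporal / parietal)
    edges and a denser diffuse recruitment on top of the S1 set,
    producing the denser, less lateralized networks expected after a
    lesion; unaffected-forearm stimulation recruits a sparser diffuse
    component. At most one diffuse background is planted per limb —
    overlapping diffuse sources would split channel band power and
    dilute each other's coherence.
    """
    mixer = (ZeroLagMixing(("Cz", "C1", "C2", "CPz"), (0.5, 0.4, 0.4, 0.3)),)
    return [
        CouplingSpec(
            condition="stimulation",
            edges=_edges(_S1_EDGES, strength),
            zero_lag=mixer,
        ),
        CouplingSpec(
            condition="stimulation",
            limb="left",  # affected forearm by convention after flipping
            lateralized=False,
            edges=_edges(
                tuple((a, b) for a, b in _DISTRIBUTED_EDGES),
                distributed_strength,
            ),
            background=BackgroundModulation(n_sources=3, channels_per_source=12),
        ),
        CouplingSpec(
            condition="stimulation",
            limb="right",  # unaffected forearm
            lateralized=False,
            background=BackgroundModulation(n_sources=2, channels_per_source=10),
        ),
        CouplingSpec(
            condition="baseline",
            lateralized=False,
            zero_lag=mixer,
        ),
    ]
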