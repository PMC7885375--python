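"""Signal conditioning: band-pass, average reference, epoching, artifacts.

The conditioning chain runs in a fixed order — band-pass filter, average
re-reference, artifact hook, retain/epoch, optional mid-sagittal flip —
mirroring common practice for stimulus-locked sensor-space connectivity
analyses. Re-running the chain on identical input is bit-identical: every
step is deterministic.

The band-pass is zero-phase (forward-backward), realized as a cascade of
a 4th-order Butterworth high-pass and a 12th-order Butterworth low-pass.
Zero-phase filtering avoids group delay that would smear the 2-s
coherence windows; the low-pass order is chosen so that the doubled
(forward + backward) attenuation reaches 40 dB within 10 Hz of the upper
band edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .montage import Montage, Recording, TrialSet, flip_mid_sagittal

__all__ = [
    "PreprocConfig",
    "bandpass",
    "average_reference",
    "epoch",
    "artifact_hook",
    "amplitude_rejector",
    "preprocess_recording",
]

log = logging.getLogger(__name__)

HIGHPASS_ORDER = 4
LOWPASS_ORDER = 12


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the conditioning chain.

    ``retain_s`` seconds are kept from each condition onset (the window
    in which the transient tactile response is expected) and cut into
    consecutive non-overlapping ``epoch_s``-second trials.
    """

    bandpass_hz: tuple[float, float] = (1.0, 45.0)
    reference: str = "average"
    retain_s: float = 12.0
    epoch_s: float = 4.0
    flip_left_lesion: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not (0 < lo < hi):
            raise ValueError(f"invalid band-pass ({lo}, {hi})")
        if self.reference != "average":
            raise ValueError("only average reference is supported")
        n_epochs = self.retain_s / self.epoch_s
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValueError(
                f"retain_s={self.retain_s} not divisible by epoch_s={self.epoch_s}"
            )


def bandpass(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase band-pass between ``low`` and ``high`` Hz."""
    nyq = rec.rate / 2
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    hp = signal.butter(HIGHPASS_ORDER, low, btype="highpass", fs=rec.rate, output="sos")
    lp = signal.butter(LOWPASS_ORDER, high, btype="lowpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(np.vstack([hp, lp]), rec.samples, axis=-1)
    return Recording(
        samples=filtered,
        rate=rec.rate,
        channel_names=rec.channel_names,
        annotations=list(rec.annotations),
    )


def bandpass_response_db(rate: float, low: float, high: float, freqs) -> np.ndarray:
    """Gain (dB) of the zero-phase band-pass at ``freqs`` (transfer-function
    evaluation; the doubling accounts for the forward-backward pass)."""
    hp = signal.butter(HIGHPASS_ORDER, low, btype="highpass", fs=rate, output="sos")
    lp = signal.butter(LOWPASS_ORDER, high, btype="lowpass", fs=rate, output="sos")
    _, h = signal.sosfreqz(np.vstack([hp, lp]), worN=np.atleast_1d(freqs), fs=rate)
    return 40.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous mean over all channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    referenced = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return Recording(
        samples=referenced,
        rate=rec.rate,
        channel_names=rec.channel_names,
        annotations=list(rec.annotations),
    )


def _parse_label(label: str) -> tuple[str, str]:
    """Split an annotation label ``condition/limb`` (limb may be absent)."""
    if "/" in label:
        cond, limb = label.split("/", 1)
    else:
        cond, limb = label, ""
    return cond, limb


def epoch(
    rec: Recording,
    config: PreprocConfig = PreprocConfig(),
    subject_id: str = "",
    group: str = "",
) -> TrialSet:
    """Cut ``retain_s`` from each condition onset into ``epoch_s`` trials.

    Annotation labels are ``condition`` or ``condition/limb``. Epochs are
    half-open sample windows ``[onset, onset + epoch_s)``. An annotation
    with fewer than ``retain_s`` seconds of data after it is an error.
    """
    n_per = int(round(config.retain_s / config.epoch_s))
    epoch_samples = int(round(config.epoch_s * rec.rate))
    trials, conds, limbs = [], [], []
    for onset, label in rec.annotations:
        start = int(round(onset * rec.rate))
        needed = start + n_per * epoch_samples
        if needed > rec.n_samples:
            raise ValueError(
                f"annotation {label!r} at {onset}s has only "
                f"{(rec.n_samples - start) / rec.rate:.3f}s of data, "
                f"needs {config.retain_s}s"
            )
        cond, limb = _parse_label(label)
        for k in range(n_per):
            a = start + k * epoch_samples
            trials.append(rec.samples[:, a : a + epoch_samples])
            conds.append(cond)
            limbs.append(limb)
    if not trials:
        raise ValueError("recording has no condition annotations")
    return TrialSet(
        data=np.stack(trials),
        rate=rec.rate,
        channel_names=rec.channel_names,
        condition=np.array(conds, dtype=object),
        limb=np.array(limbs, dtype=object),
        subject_id=subject_id,
        group=group,
    )


def artifact_hook(
    trials: TrialSet,
    strategy: Callable[[TrialSet], TrialSet] | None = None,
) -> TrialSet:
    """Apply a pluggable artifact-handling strategy (identity by default).

    A strategy may drop trials but must preserve channel count, sampling
    rate and trial length; anything else is a contract error.
    """
    if strategy is None:
        return trials
    out = strategy(trials)
    if not isinstance(out, TrialSet):
        raise TypeError("artifact strategy must return a TrialSet")
    if (
        out.data.shape[1:] != trials.data.shape[1:]
        or out.rate != trials.rate
        or out.channel_names != trials.channel_names
    ):
        raise ValueError(
            "artifact strategy changed channels/rate/trial length: "
            f"{out.data.shape} vs {trials.data.shape}"
        )
    if out.n_trials != trials.n_trials:
        log.info(
            "artifact strategy dropped %d of %d trials",
            trials.n_trials - out.n_trials, trials.n_trials,
        )
    return out


def amplitude_rejector(threshold_uv: float) -> Callable[[TrialSet], TrialSet]:
    """Deterministic artifact strategy: drop any trial with |sample|
    exceeding ``threshold_uv`` microvolts on any channel."""

    def strategy(trials: TrialSet) -> TrialSet:
        keep = np.abs(trials.data).max(axis=(1, 2)) <= threshold_uv
        for k in np.nonzero(~keep)[0]:
            log.info("rejecting trial %d: amplitude above %g uV", k, threshold_uv)
        return TrialSet(
            data=trials.data[keep],
            rate=trials.rate,
            channel_names=trials.channel_names,
            condition=trials.condition[keep],
            limb=trials.limb[keep],
            subject_id=trials.subject_id,
            group=trials.group,
        )

    return strategy


def preprocess_recording(
    rec: Recording,
    config: PreprocConfig = PreprocConfig(),
    montage: Montage | None = None,
    artifact_strategy: Callable[[TrialSet], TrialSet] | None = None,
    subject_id: str = "",
    group: str = "",
) -> TrialSet:
    """Full conditioning chain on one continuous recording.

    Order: band-pass -> average reference -> epoch -> artifact hook ->
    optional mid-sagittal flip (requires ``montage``).
    """
    log.info("bandpass %s Hz", config.bandpass_hz)
    rec = bandpass(rec, *config.bandpass_hz)
    log.info("average reference over %d channels", rec.n_channels)
    rec = average_reference(rec)
    trials = epoch(rec, config, subject_id=subject_id, group=group)
    trials = artifact_hook(trials, artifact_strategy)
    if config.flip_left_lesion:
        if montage is None:
            raise ValueError("flip requires a montage")
        log.info("flipping along the mid-sagittal plane")
        trials = flip_mid_sagittal(trials, montage)
    return trials
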