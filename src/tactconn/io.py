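"""Recording I/O: EDF and delimited-matrix formats.

Two on-disk representations are supported for continuous recordings:

* ``edf`` — European Data Format. Reading goes through :mod:`mne`;
  writing uses a small built-in EDF+C writer (16-bit samples, one-second
  data records, annotations stored as EDF+ time-stamped annotation
  lists), so round trips are exact up to the 16-bit quantization step.
* ``delimited`` — a plain-text tab-separated channel x sample matrix plus
  a JSON sidecar ``{rate, channel_names, annotations}``.

If a montage is supplied, channels are validated against it and reordered
into montage order; a file channel absent from the montage is an error
naming the offending label.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .montage import Montage, MontageError, Recording, TrialSet

__all__ = [
    "read_recording",
    "write_recording",
    "sidecar_path",
    "save_trials",
    "load_trials",
]


def save_trials(trials: TrialSet, path) -> Path:
    """Persist an epoched trial set as a compressed ``.npz`` archive."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=trials.data,
        rate=np.array([trials.rate]),
        channel_names=np.array(trials.channel_names, dtype=str),
        condition=trials.condition.astype(str),
        limb=trials.limb.astype(str),
        subject_id=np.array([trials.subject_id]),
        group=np.array([trials.group]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_trials(path) -> TrialSet:
    with np.load(path, allow_pickle=False) as z:
        return TrialSet(
            data=z["data"],
            rate=float(z["rate"][0]),
            channel_names=tuple(z["channel_names"]),
            condition=z["condition"].astype(object),
            limb=z["limb"].astype(object),
            subject_id=str(z["subject_id"][0]),
            group=str(z["group"][0]),
        )


def sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".edf":
        return "edf"
    return "delimited"


def read_recording(path, fmt: str | None = None, montage: Montage | None = None) -> Recording:
    """Read a recording from ``path`` (format inferred from the suffix).

    Channels are returned in montage order when a montage is given.
    EDF amplitudes are interpreted in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "delimited":
        rec = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if montage is not None:
        rec = _reorder_to_montage(rec, montage)
    return rec


def write_recording(rec: Recording, path, fmt: str | None = None) -> Path:
    """Write ``rec`` to ``path``; returns the path written."""
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with zero channels")
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _reorder_to_montage(rec: Recording, montage: Montage) -> Recording:
    for ch in rec.channel_names:
        if ch not in montage.channel_names:
            raise MontageError(f"channel {ch!r} not in montage {montage.name!r}")
    order = [rec.channel_names.index(ch) for ch in montage.channel_names
             if ch in rec.channel_names]
    return Recording(
        samples=rec.samples[order],
        rate=rec.rate,
        channel_names=tuple(rec.channel_names[i] for i in order),
        annotations=list(rec.annotations),
    )


# -- delimited + JSON sidecar -------------------------------------------


def _write_delimited(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.samples, fmt="%.10g", delimiter="\t")
    meta = {
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "annotations": [[float(t), str(lab)] for t, lab in rec.annotations],
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_delimited(path: Path) -> Recording:
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    samples = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Recording(
        samples=samples,
        rate=float(meta["rate"]),
        channel_names=tuple(meta["channel_names"]),
        annotations=[(float(t), str(lab)) for t, lab in meta.get("annotations", [])],
    )


# -- EDF ----------------------------------------------------------------

#: Step size of the 16-bit EDF quantizer for a given physical range.
def edf_quantization_step(samples: np.ndarray) -> float:
    lo, hi = _phys_bounds(float(np.min(samples)), float(np.max(samples)))
    return (hi - lo) / 65535.0


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {float(raw.info["sfreq"])}
    if len(rates) != 1:
        raise ValueError("inconsistent sampling rates across channels")
    samples = raw.get_data() * 1e6  # mne loads volts; recordings are in uV
    annotations = [
        (float(onset), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return Recording(
        samples=samples,
        rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        annotations=annotations,
    )


def _phys_bounds(lo: float, hi: float) -> tuple[float, float]:
    """Bracket [lo, hi] with values that print exactly in 8 EDF chars.

    The header's physical min/max fields are 8 ASCII bytes; the digitizer
    must use the very values the header will carry, or the reader's
    rescaling would not invert the writer's. Bounds are widened outward
    to the coarsest decimal precision that fits.
    """
    if hi == lo:
        hi = lo + 1.0
    for decimals in range(6, -1, -1):
        f = 10.0 ** decimals
        lo_r = math.floor(lo * f) / f
        hi_r = math.ceil(hi * f) / f
        if len(f"{lo_r:.10g}") <= 8 and len(f"{hi_r:.10g}") <= 8:
            return lo_r, hi_r
    raise ValueError(f"physical range [{lo}, {hi}] does not fit an EDF header")


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} EDF header bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+C writer: one-second records, int16 samples.

    The recording length must be a whole number of seconds and the rate a
    whole number of samples per second; annotations are written as EDF+
    TALs in a dedicated annotations signal.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per record per signal
    n_records = rec.n_samples / spr
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError(
            "EDF writer requires a whole number of one-second records; "
            f"got {rec.n_samples} samples at {spr} Hz"
        )
    n_records = int(round(n_records))
    if n_records == 0:
        raise ValueError("cannot write an empty recording")

    n_sig = rec.n_channels + 1  # + annotations channel
    ann_spr = 32  # 64 bytes per record for annotation TALs

    phys_min, phys_max = [], []
    dig = np.empty((rec.n_channels, rec.n_samples), dtype="<i2")
    for i in range(rec.n_channels):
        lo, hi = _phys_bounds(
            float(np.min(rec.samples[i])), float(np.max(rec.samples[i]))
        )
        scale = (hi - lo) / 65535.0
        dig[i] = np.clip(
            np.round((rec.samples[i] - lo) / scale) - 32768, -32768, 32767
        ).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)

    # annotation TALs: record k starts with its timestamp TAL, then any
    # annotations whose onset falls in [k, k+1).
    ann_blocks = []
    for k in range(n_records):
        tal = f"+{k}\x14\x14\x00".encode("ascii")
        for onset, label in rec.annotations:
            if k <= onset < k + 1 or (onset == n_records and k == n_records - 1):
                tal += f"+{onset:g}\x14{label}\x14\x00".encode("utf-8")
        if len(tal) > 2 * ann_spr:
            raise ValueError(f"too many annotations near t={k}s for EDF record")
        ann_blocks.append(tal.ljust(2 * ann_spr, b"\x00"))

    def fmt_phys(v: float) -> str:
        s = f"{v:.10g}"
        if len(s) > 8:
            raise ValueError(f"physical bound {v} does not fit EDF header")
        return s

    header = b"".join([
        _ascii(0, 8),  # version
        _ascii("X X X X", 80),  # patient id (anonymous)
        _ascii("Startdate X X X X", 80),  # recording id
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_sig + 1), 8),  # header bytes
        _ascii("EDF+C", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),  # record duration, seconds
        _ascii(n_sig, 4),
    ])
    labels = [ch[:16] for ch in rec.channel_names] + ["EDF Annotations"]
    transducer = [""] * n_sig
    dim = ["uV"] * rec.n_channels + [""]
    pmin = [fmt_phys(v) for v in phys_min] + ["-1"]
    pmax = [fmt_phys(v) for v in phys_max] + ["1"]
    dmin = ["-32768"] * n_sig
    dmax = ["32767"] * n_sig
    prefilter = [""] * n_sig
    nsamp = [str(spr)] * rec.n_channels + [str(ann_spr)]
    for fields, width in [
        (labels, 16), (transducer, 80), (dim, 8), (pmin, 8), (pmax, 8),
        (dmin, 8), (dmax, 8), (prefilter, 80), (nsamp, 8),
    ]:
        header += b"".join(_ascii(f, width) for f in fields)
    header += b" " * (32 * n_sig)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for k in range(n_records):
            sl = slice(k * spr, (k + 1) * spr)
            for i in range(rec.n_channels):
                fh.write(dig[i, sl].tobytes())
            fh.write(ann_blocks[k])
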