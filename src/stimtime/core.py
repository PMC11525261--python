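"""Core domain types and file I/O for stimulus-timing validation.

The toolkit works on multi-channel oscilloscope-style recordings of a
smartphone's stimulus channels (auditory, visual, tactile).  A recording is a
:class:`Trace`: a uniformly sampled window (nominally 10 kHz over ±125 ms)
around the commanded stimulus onset, one sample sequence per modality.  Device
behaviour (per-modality command-to-physical latency, display frame
quantization, vibrator pathologies, ...) is described by a
:class:`DeviceProfile`, loadable from YAML/JSON; two measured phone profiles
ship with the package (``xiaomi_mi_a2``, ``samsung_a40``).

Times are milliseconds everywhere in memory; only the trace file's time
column is in seconds (oscilloscope-export idiom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

MODALITIES = ("auditory", "visual", "tactile")

__all__ = [
    "MODALITIES",
    "Trace",
    "Pulse",
    "StimulusSpec",
    "ModalityProfile",
    "DeviceProfile",
    "DetectionParams",
    "Event",
    "DelayTable",
    "ProfileError",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "load_profile",
    "save_profile",
    "load_stimulus_spec",
    "save_stimulus_spec",
    "packaged_profile_path",
    "load_packaged_profile",
]


class TraceFormatError(ValueError):
    """Raised for malformed trace files."""


class ProfileError(ValueError):
    """Raised for device-profile files violating the schema."""


# ---------------------------------------------------------------------------
# Trace


@dataclass
class Trace:
    """Uniformly sampled multi-channel recording.

    Parameters
    ----------
    sampling_rate_hz
        Sampling frequency; nominally 10 000 Hz.
    t0_ms
        Time of the commanded stimulus onset on the trace's time axis
        (conventionally 0: the time axis is centred on the command).
    start_ms
        Time of the first sample (nominally −125 ms).
    channels
        Mapping modality name → 1-D sample array; all equal length ≥ 2.
    meta
        Free-form provenance (profile name, commanded spec, seed, injected
        ground-truth intervals when simulated).
    """

    sampling_rate_hz: float
    t0_ms: float
    start_ms: float
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channels:
            raise ValueError("Trace requires at least one channel")
        lengths = set()
        for name, samples in list(self.channels.items()):
            if name not in MODALITIES:
                raise ValueError(
                    f"unknown modality {name!r}; expected one of {MODALITIES}"
                )
            arr = np.asarray(samples, dtype=float)
            self.channels[name] = arr
            lengths.add(arr.shape[0] if arr.ndim == 1 else -1)
        if len(lengths) != 1 or -1 in lengths:
            raise ValueError("all channels must be 1-D and of identical length")
        if lengths.pop() < 2:
            raise ValueError("channels must hold at least two samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def dt_ms(self) -> float:
        """Sample period in milliseconds."""
        return 1000.0 / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample times in ms, on the axis where ``t0_ms`` is the command."""
        return self.start_ms + np.arange(self.n_samples) * self.dt_ms


# ---------------------------------------------------------------------------
# Stimulus specification


@dataclass(frozen=True)
class Pulse:
    """One commanded pulse: software command time and requested duration."""

    command_time_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


@dataclass
class StimulusSpec:
    """Commanded stimulation: per-modality pulse trains.

    Pulses within a modality must be sorted by command time and must not
    overlap once their durations are added.
    """

    pulses: dict[str, list[Pulse]]
    label: str = ""

    def __post_init__(self) -> None:
        for name, train in self.pulses.items():
            if name not in MODALITIES:
                raise ValueError(f"unknown modality {name!r}")
            for a, b in zip(train, train[1:]):
                if b.command_time_ms < a.command_time_ms:
                    raise ValueError(f"{name} pulses not sorted by command time")
                if b.command_time_ms < a.command_time_ms + a.duration_ms:
                    raise ValueError(f"{name} pulses overlap")

    @property
    def modalities(self) -> list[str]:
        return sorted(self.pulses)


# ---------------------------------------------------------------------------
# Device profile


@dataclass
class ModalityProfile:
    """Latency/fidelity parameters of one stimulus channel.

    ``onset_delay_ms`` is the command-to-physical-onset latency relative to
    the device's fastest channel.  Visual channels additionally carry the
    display frame period and per-duration one-frame miss probabilities;
    tactile channels the minimum producible duration, additive duration
    inflation and the merge pathology (commanded gaps below
    ``merge_below_isi_ms`` fuse the pair into a single wave of
    ``merged_wave_duration_ms``); auditory channels the carrier frequency and
    the shortest-interval overshoot.
    """

    onset_delay_ms: float = 0.0
    min_duration_ms: float = 0.0
    transition_ms: float = 0.0
    duration_inflation_ms: float = 0.0
    merge_below_isi_ms: float = 0.0
    merged_wave_duration_ms: float | None = None
    frame_period_ms: float | None = None
    frame_phase_ms: float = 0.0
    frame_miss_prob: dict[float, float] = field(default_factory=dict)
    shortest_isi_ms: float | None = None
    shortest_isi_overshoot_ms: float = 0.0
    noise_sd: float = 0.01
    carrier_hz: float | None = None

    def __post_init__(self) -> None:
        if self.onset_delay_ms < 0:
            raise ProfileError("onset_delay_ms must be >= 0")
        if self.min_duration_ms < 0:
            raise ProfileError("min_duration_ms must be >= 0")
        if self.noise_sd < 0:
            raise ProfileError("noise_sd must be >= 0")
        if self.frame_period_ms is not None and self.frame_period_ms <= 0:
            raise ProfileError("frame_period_ms must be > 0")
        self.frame_miss_prob = {
            float(k): float(v) for k, v in self.frame_miss_prob.items()
        }
        for dur, p in self.frame_miss_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ProfileError(
                    f"frame_miss_prob[{dur}] = {p} outside [0, 1]"
                )


@dataclass
class DeviceProfile:
    """Per-modality latency/fidelity parameters for one device."""

    name: str
    modalities: dict[str, ModalityProfile]

    def __post_init__(self) -> None:
        for name in self.modalities:
            if name not in MODALITIES:
                raise ProfileError(f"unknown modality {name!r}")
        delays = {m: p.onset_delay_ms for m, p in self.modalities.items()}
        if len(delays) > 1:
            zeros = [m for m, d in delays.items() if d == 0.0]
            if len(zeros) != 1:
                raise ProfileError(
                    "exactly one modality must have onset_delay_ms = 0 "
                    f"(the fastest); got zero delay for {zeros!r}"
                )
        for m, p in self.modalities.items():
            if m == "visual" and p.frame_period_ms is None:
                raise ProfileError("visual modality requires frame_period_ms")

    def __getitem__(self, modality: str) -> ModalityProfile:
        return self.modalities[modality]

    def delay_table(self, modalities: Sequence[str] | None = None) -> "DelayTable":
        """Onset delays of the requested modalities, re-referenced so the
        fastest of them is 0."""
        names = list(modalities) if modalities is not None else sorted(self.modalities)
        missing = [m for m in names if m not in self.modalities]
        if missing:
            raise KeyError(f"profile {self.name!r} lacks modalities {missing}")
        raw = {m: self.modalities[m].onset_delay_ms for m in names}
        fastest = min(raw.values())
        return DelayTable({m: d - fastest for m, d in raw.items()})


# ---------------------------------------------------------------------------
# Detection parameters


@dataclass
class DetectionParams:
    """Settings of the onset/offset extraction pipeline.

    ``cutoff_k`` standard deviations of the pre-stimulus baseline define the
    noise band; ``sg_window_samples``/``sg_polyorder`` configure the
    Savitzky–Golay smoother used for auditory/tactile channels;
    ``lowpass_passband`` (rad/sample, default 0.1·π) the zero-phase low-pass
    used for visual channels.  ``amplitude_floor_frac`` sets the
    half-amplitude event criterion used when the baseline band alone is
    degenerate or far below the signal (see docs/methods.md); ``baseline_center``
    selects median (default) or mean as the baseline estimate.
    """

    baseline_window_ms: float = 50.0
    cutoff_k: float = 2.0
    sg_window_samples: int = 11
    sg_polyorder: int = 3
    lowpass_passband: float = 0.1 * np.pi
    lowpass_order: int = 4
    min_event_separation_ms: float = 2.0
    rectify_audio: bool = True
    smooth_audio: bool = False
    baseline_center: str = "median"
    amplitude_floor_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff_k <= 0:
            raise ValueError("cutoff_k must be > 0")
        if self.sg_window_samples % 2 == 0 or self.sg_window_samples <= self.sg_polyorder:
            raise ValueError("sg_window_samples must be odd and > sg_polyorder")
        if not 0.0 < self.lowpass_passband < np.pi:
            raise ValueError("lowpass_passband must lie in (0, pi) rad/sample")
        if self.baseline_center not in ("median", "mean"):
            raise ValueError("baseline_center must be 'median' or 'mean'")
        if not 0.0 <= self.amplitude_floor_frac < 1.0:
            raise ValueError("amplitude_floor_frac must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Events and delay tables


@dataclass(frozen=True)
class Event:
    """Detected stimulus: onset, offset, duration = offset − onset."""

    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset_ms must exceed onset_ms")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


class DelayTable(dict):
    """Modality → onset delay (ms) relative to the fastest modality.

    The fastest modality has delay 0 by definition; all entries are
    non-negative.
    """

    def __init__(self, delays: Mapping[str, float]):
        if not delays:
            raise ValueError("DelayTable requires at least one modality")
        vals = list(delays.values())
        if min(vals) != 0.0:
            raise ValueError("the fastest modality must have delay 0")
        if any(v < 0 for v in vals):
            raise ValueError("delays must be non-negative")
        super().__init__({str(k): float(v) for k, v in delays.items()})


# ---------------------------------------------------------------------------
# Trace file I/O (CSV: header ``time_s,<modality>,...``; time in seconds)

_TIME_COL = "time_s"


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV readable by :func:`read_trace`.

    Columns: ``time_s`` then one column per modality (sorted), samples in
    arbitrary volt-equivalent units with ≥ 6 significant digits.
    """
    path = Path(path)
    names = sorted(trace.channels)
    header = ",".join([_TIME_COL] + names)
    cols = [trace.times_ms / 1000.0] + [trace.channels[m] for m in names]
    data = np.column_stack(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.8g")


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (or an equivalent
    oscilloscope export).

    The time column must be strictly increasing and uniform to within 1 % of
    the median step; the sampling rate is inferred from it.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if not cols or cols[0] != _TIME_COL:
        raise TraceFormatError(f"first column must be {_TIME_COL!r}, got {cols[:1]}")
    modal_cols = cols[1:]
    if not modal_cols:
        raise TraceFormatError("trace file declares no modality columns")
    unknown = [c for c in modal_cols if c not in MODALITIES]
    if unknown:
        raise TraceFormatError(f"unknown modality columns {unknown}")
    if len(set(modal_cols)) != len(modal_cols):
        raise TraceFormatError(f"duplicate modality columns in {modal_cols}")

    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != len(cols):
        raise TraceFormatError("row width does not match header")
    if data.shape[0] < 2:
        raise TraceFormatError("trace needs at least two rows")
    t_ms = data[:, 0] * 1000.0
    steps = np.diff(t_ms)
    if np.any(steps <= 0):
        raise TraceFormatError("time column must be strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 0.01 * dt:
        raise TraceFormatError("non-uniform time base (> 1 % step deviation)")
    channels = {m: data[:, i + 1].copy() for i, m in enumerate(modal_cols)}
    return Trace(
        sampling_rate_hz=1000.0 / dt,
        t0_ms=0.0,
        start_ms=float(t_ms[0]),
        channels=channels,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Device-profile I/O

_MODALITY_FIELDS = {f for f in ModalityProfile.__dataclass_fields__}


def _profile_from_mapping(doc: object, origin: str) -> DeviceProfile:
    if not isinstance(doc, dict):
        raise ProfileError(f"{origin}: profile document must be a mapping")
    if "name" not in doc or not isinstance(doc["name"], str):
        raise ProfileError(f"{origin}: missing or non-string field 'name'")
    mods = doc.get("modalities")
    if not isinstance(mods, dict) or not mods:
        raise ProfileError(f"{origin}: 'modalities' must be a non-empty mapping")
    parsed: dict[str, ModalityProfile] = {}
    for mname, fields_ in mods.items():
        if not isinstance(fields_, dict):
            raise ProfileError(f"{origin}: modalities.{mname} must be a mapping")
        bad = set(fields_) - _MODALITY_FIELDS
        if bad:
            raise ProfileError(
                f"{origin}: modalities.{mname} has unknown fields {sorted(bad)}"
            )
        try:
            parsed[mname] = ModalityProfile(**fields_)
        except (ProfileError, TypeError, ValueError) as exc:
            raise ProfileError(f"{origin}: modalities.{mname}: {exc}") from exc
    try:
        return DeviceProfile(name=doc["name"], modalities=parsed)
    except ProfileError as exc:
        raise ProfileError(f"{origin}: {exc}") from exc


def load_profile(path: str | Path) -> DeviceProfile:
    """Load a device profile from YAML (JSON is valid YAML and accepted)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _profile_from_mapping(doc, origin=str(path))


def save_profile(profile: DeviceProfile, path: str | Path) -> None:
    """Serialize a profile to YAML; the result round-trips via load_profile."""
    doc = {
        "name": profile.name,
        "modalities": {
            m: {
                k: v
                for k, v in vars(p).items()
                if v not in (None,) and not (isinstance(v, dict) and not v)
            }
            for m, p in profile.modalities.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_stimulus_spec(path: str | Path) -> StimulusSpec:
    """Load a commanded-stimulus spec from YAML.

    Schema: ``label`` (optional) and ``pulses``: modality → list of
    ``[command_time_ms, duration_ms]`` pairs.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pulses" not in doc:
        raise ValueError(f"{path}: stimulus spec must be a mapping with 'pulses'")
    pulses = {
        m: [Pulse(float(t), float(d)) for t, d in train]
        for m, train in doc["pulses"].items()
    }
    return StimulusSpec(pulses=pulses, label=str(doc.get("label", "")))


def save_stimulus_spec(spec: StimulusSpec, path: str | Path) -> None:
    doc = {
        "label": spec.label,
        "pulses": {
            m: [[p.command_time_ms, p.duration_ms] for p in train]
            for m, train in spec.pulses.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def packaged_profile_path(name: str) -> Path:
    """Filesystem path of a packaged profile (``xiaomi_mi_a2``, ``samsung_a40``)."""
    res = resources.files("stimtime") / "profiles" / f"{name}.yaml"
    with resources.as_file(res) as p:
        return Path(p)


def load_packaged_profile(name: str) -> DeviceProfile:
    """Load one of the profiles shipped with the package."""
    res = resources.files("stimtime") / "profiles" / f"{name}.yaml"
    try:
        text = res.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise ProfileError(f"no packaged profile named {name!r}") from exc
    return _profile_from_mapping(yaml.safe_load(text), origin=f"packaged:{name}")
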