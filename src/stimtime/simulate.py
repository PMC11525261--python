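"""Synthetic stimulus-channel traces reproducing measured phone behaviour.

The simulator turns a commanded :class:`~stimtime.core.StimulusSpec` into the
multi-channel trace an oscilloscope would record from the device described by
a :class:`~stimtime.core.DeviceProfile`:

* auditory — a carrier burst (1-kHz tone by default) starting at
  ``command + onset_delay`` and lasting exactly the commanded duration;
  a commanded pair at the channel's shortest producible interval comes out
  with the gap overshot by ``shortest_isi_overshoot_ms`` (+2 ms measured).
* visual — onsets snap to the 60-Hz frame grid, durations to whole frames,
  with a per-duration probability of a ±1-frame error (never below one
  frame); pixel transitions are ramps of ``transition_ms``.
* tactile — onset lag, minimum producible duration, additive duration
  inflation, and (on pathological devices) fusion of closely commanded pulse
  pairs into a single ~125-ms wave.

Edges are raised-cosine ramps *centred* on the nominal on/off time, and a
pulse is active on the closed interval [onset, offset], so the half-amplitude
crossing of the rendered waveform — and, for instantaneous edges, the first
and last active sample — sits exactly at the nominal edge time.  Detection
then recovers injected timing without a systematic half-transition or
one-sample bias (see docs/methods.md).

Ground-truth physical intervals are stored in ``Trace.meta["injected"]`` so
closed-loop tests can compare detected events against what was rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DeviceProfile, ModalityProfile, Pulse, StimulusSpec, Trace

__all__ = ["SessionSpec", "simulate_trial", "simulate_session", "physical_intervals"]

DEFAULT_SAMPLING_RATE_HZ = 10_000.0
DEFAULT_WINDOW_MS = (-125.0, 125.0)


@dataclass
class SessionSpec:
    """A recording session: one stimulus spec repeated ``n_trials`` times."""

    spec: StimulusSpec
    profile: DeviceProfile
    n_trials: int = 100
    seed: int = 0
    compensated: bool = False
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _quantize_visual(
    pulses: list[Pulse], mp: ModalityProfile, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Frame-snap visual pulses; returns (physical_onset, physical_duration)."""
    fp = mp.frame_period_ms
    assert fp is not None
    # The frame grid is anchored so that a boundary falls at the first
    # commanded onset (+ optional phase): the device's vsync phase relative
    # to the command is unobservable, and this choice reproduces the measured
    # onset-delay table exactly.
    anchor = pulses[0].command_time_ms + mp.onset_delay_ms + mp.frame_phase_ms
    out = []
    for p in pulses:
        raw = p.command_time_ms + mp.onset_delay_ms
        n_up = math.ceil((raw - anchor) / fp - 1e-9)
        onset = anchor + n_up * fp
        n_frames = max(1, round(p.duration_ms / fp))
        miss_p = 0.0
        for nominal, prob in mp.frame_miss_prob.items():
            if abs(nominal - p.duration_ms) < 0.5:
                miss_p = prob
                break
        if miss_p > 0 and rng.random() < miss_p:
            sign = 1 if rng.random() < 0.5 else -1
            if n_frames + sign < 1:
                sign = 1
            n_frames += sign
        out.append((onset, n_frames * fp))
    return out


def _audio_intervals(
    pulses: list[Pulse], mp: ModalityProfile
) -> list[tuple[float, float]]:
    out = []
    shift = 0.0
    for prev, p in zip([None] + pulses[:-1], pulses):
        if prev is not None and mp.shortest_isi_ms is not None:
            gap = p.command_time_ms - (prev.command_time_ms + prev.duration_ms)
            if gap <= mp.shortest_isi_ms + 1e-9:
                shift += mp.shortest_isi_overshoot_ms
        out.append((p.command_time_ms + mp.onset_delay_ms + shift, p.duration_ms))
    return out


def _tactile_intervals(
    pulses: list[Pulse], mp: ModalityProfile
) -> list[tuple[float, float]]:
    # Group pulses whose commanded gap is below the merge threshold.
    groups: list[list[Pulse]] = []
    for p in pulses:
        if groups:
            prev = groups[-1][-1]
            gap = p.command_time_ms - (prev.command_time_ms + prev.duration_ms)
            if gap < mp.merge_below_isi_ms:
                groups[-1].append(p)
                continue
        groups.append([p])
    out = []
    for g in groups:
        onset = g[0].command_time_ms + mp.onset_delay_ms
        if len(g) > 1:
            if mp.merged_wave_duration_ms is None:
                raise ValueError(
                    "profile merges tactile pulses but merged_wave_duration_ms unset"
                )
            out.append((onset, mp.merged_wave_duration_ms))
        else:
            dur = max(g[0].duration_ms, mp.min_duration_ms) + mp.duration_inflation_ms
            out.append((onset, dur))
    return out


def physical_intervals(
    spec: StimulusSpec, profile: DeviceProfile, rng: np.random.Generator
) -> dict[str, list[tuple[float, float]]]:
    """Physical (onset, duration) per modality after all device distortions.

    Stochastic only through the visual frame-miss draw.
    """
    out: dict[str, list[tuple[float, float]]] = {}
    for modality in sorted(spec.pulses):
        if modality not in profile.modalities:
            raise KeyError(f"profile {profile.name!r} lacks modality {modality!r}")
        mp = profile.modalities[modality]
        pulses = spec.pulses[modality]
        if not pulses:
            out[modality] = []
        elif modality == "visual":
            out[modality] = _quantize_visual(pulses, mp, rng)
        elif modality == "auditory":
            out[modality] = _audio_intervals(pulses, mp)
        else:
            out[modality] = _tactile_intervals(pulses, mp)
    return out


def _render_channel(
    t: np.ndarray,
    intervals: list[tuple[float, float]],
    mp: ModalityProfile,
) -> np.ndarray:
    dt = t[1] - t[0]
    x = np.zeros_like(t)
    tiny = dt * 1e-6
    for onset, dur in intervals:
        offset = onset + dur
        T = mp.transition_ms
        if T <= 0:
            env = ((t >= onset - tiny) & (t <= offset + tiny)).astype(float)
        else:
            rise = np.clip((t - onset) / T + 0.5, 0.0, 1.0)
            fall = np.clip((offset - t) / T + 0.5, 0.0, 1.0)
            env = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
        if mp.carrier_hz:
            x += env * np.cos(2 * np.pi * mp.carrier_hz * (t - onset) / 1000.0)
        else:
            x += env
    return x


def simulate_trial(
    spec: StimulusSpec,
    profile: DeviceProfile,
    seed: int,
    *,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    noise_sd: float | None = None,
) -> Trace:
    """Simulate the oscilloscope trace of one commanded trial.

    Parameters
    ----------
    seed
        Seeds both the visual frame-miss draw and the additive baseline
        noise; identical (spec, profile, seed) gives an identical trace.
    window_ms
        Recording window relative to the commanded onset (default ±125 ms).
        A pulse (including its transition ramp) falling outside it is an
        error: widen the window for long sequential stimuli.
    noise_sd
        Override of the per-modality baseline noise SD (e.g. 0 for
        noise-free closed-loop tests); ``None`` uses the profile's value.
    """
    rng = np.random.default_rng(seed)
    intervals = physical_intervals(spec, profile, rng)

    start, end = window_ms
    if end <= start:
        raise ValueError("window_ms end must exceed start")
    dt = 1000.0 / sampling_rate_hz
    n = int(round((end - start) / dt)) + 1
    t = start + np.arange(n) * dt

    channels: dict[str, np.ndarray] = {}
    for modality in sorted(intervals):
        mp = profile.modalities[modality]
        for onset, dur in intervals[modality]:
            if onset - mp.transition_ms / 2 < start or onset + dur + mp.transition_ms / 2 > end:
                raise ValueError(
                    f"{modality} pulse [{onset:.1f}, {onset + dur:.1f}] ms "
                    f"extends beyond the trace window {window_ms}"
                )
        x = _render_channel(t, intervals[modality], mp)
        sd = mp.noise_sd if noise_sd is None else noise_sd
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=n)
        channels[modality] = x

    return Trace(
        sampling_rate_hz=sampling_rate_hz,
        t0_ms=0.0,
        start_ms=start,
        channels=channels,
        meta={
            "profile": profile.name,
            "label": spec.label,
            "seed": int(seed),
            "injected": {
                m: [
                    {"onset_ms": on, "duration_ms": du, "offset_ms": on + du}
                    for on, du in ivs
                ]
                for m, ivs in intervals.items()
            },
        },
    )


def simulate_session(session: SessionSpec, *, noise_sd: float | None = None) -> list[Trace]:
    """Simulate ``n_trials`` traces with per-trial seeds ``seed + index``."""
    return [
        simulate_trial(
            session.spec,
            session.profile,
            session.seed + i,
            window_ms=session.window_ms,
            noise_sd=noise_sd,
        )
        for i in range(session.n_trials)
    ]
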