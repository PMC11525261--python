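"""Stimulus scheduling: ISI rule, delay compensation, DFI trial design.

Multimodal channels have unequal command-to-physical latencies, so physical
simultaneity requires commanding the slow channels early.  Given a measured
delay table, :func:`compensate` issues each modality's command at
``max_delay − delay``: the largest-latency channel is commanded first (time
0) and every physical onset then lands at ``max_delay``.

The sequential-stimulation spacing rule sets the commanded gap to twice the
stimulus duration; :func:`build_dfi_schedule` lays out the double-flash
illusion session (four conditions × N repetitions, shuffled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DelayTable, Pulse, StimulusSpec

__all__ = [
    "isi_rule",
    "Schedule",
    "compensate",
    "DFI_CONDITIONS",
    "DFITrial",
    "build_dfi_schedule",
    "dfi_stimulus_spec",
]

#: Flash and beep parameters of the double-flash-illusion task (ms).
DFI_FLASH_MS = 17.0
DFI_BEEP_MS = 7.0
DFI_ONSET_DELAY_MS = 30.0

#: condition name -> (number of flashes, number of beeps)
DFI_CONDITIONS: dict[str, tuple[int, int]] = {
    "single_unimodal": (1, 0),
    "double_unimodal": (2, 0),
    "single_bimodal": (1, 1),
    "double_bimodal": (1, 2),
}


def isi_rule(duration_ms: float) -> float:
    """Commanded inter-stimulus interval for a given duration: 2 × duration."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    return 2.0 * duration_ms


@dataclass
class Schedule:
    """Per-modality command times achieving physical simultaneity."""

    command_times_ms: dict[str, float]
    delays: DelayTable

    def __post_init__(self) -> None:
        if not self.command_times_ms:
            raise ValueError("empty schedule")
        vals = self.command_times_ms.values()
        if min(vals) != 0.0 or any(v < 0 for v in vals):
            raise ValueError("command times must be >= 0 with minimum 0")


def compensate(delays: DelayTable, modalities: set[str] | None = None) -> Schedule:
    """Command times that cancel the measured onset delays.

    ``command(m) = max_delay − delay(m)`` over the requested modalities, so
    every physical onset (command + delay) coincides at ``max_delay``; the
    slowest channel is commanded at time 0.  (The perceptually "faster"
    channel is thus commanded *last* — alignment of physical onsets requires
    the largest-latency channel to lead the command queue.)
    """
    names = sorted(modalities) if modalities is not None else sorted(delays)
    unknown = [m for m in names if m not in delays]
    if unknown:
        raise KeyError(f"modalities {unknown} missing from the delay table")
    if not names:
        raise ValueError("no modalities requested")
    dmax = max(delays[m] for m in names)
    return Schedule(
        command_times_ms={m: dmax - delays[m] for m in names},
        delays=delays,
    )


@dataclass(frozen=True)
class DFITrial:
    """One double-flash-illusion trial.

    ``flash_count_true`` is what a veridical observer should report;
    the illusion (two beeps + one flash) makes ``double_bimodal`` trials feel
    like two flashes even though only one is shown.
    """

    condition: str
    onset_delay_ms: float = DFI_ONSET_DELAY_MS
    flash_count_true: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.condition not in DFI_CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                f"expected one of {sorted(DFI_CONDITIONS)}"
            )
        n_flash, _ = DFI_CONDITIONS[self.condition]
        object.__setattr__(self, "flash_count_true", n_flash)


def build_dfi_schedule(reps_per_condition: int, seed: int) -> list[DFITrial]:
    """The DFI session: ``reps`` trials per condition, uniformly shuffled.

    20 repetitions give the standard 80-trial session.  Determinstic given
    (reps, seed); per-condition counts are exact for every seed.
    """
    if reps_per_condition < 0:
        raise ValueError("reps_per_condition must be >= 0")
    trials = [
        DFITrial(condition=c)
        for c in sorted(DFI_CONDITIONS)
        for _ in range(reps_per_condition)
    ]
    rng = np.random.default_rng(seed)
    rng.shuffle(trials)
    return trials


def dfi_stimulus_spec(trial: DFITrial) -> StimulusSpec:
    """Commanded pulses of one DFI trial (17-ms flashes, 7-ms beeps,
    successive onsets spaced by the trial's onset delay)."""
    n_flash, n_beep = DFI_CONDITIONS[trial.condition]
    pulses: dict[str, list[Pulse]] = {
        "visual": [
            Pulse(i * trial.onset_delay_ms, DFI_FLASH_MS) for i in range(n_flash)
        ]
    }
    if n_beep:
        pulses["auditory"] = [
            Pulse(i * trial.onset_delay_ms, DFI_BEEP_MS) for i in range(n_beep)
        ]
    return StimulusSpec(pulses=pulses, label=trial.condition)
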