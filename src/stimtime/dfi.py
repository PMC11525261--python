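"""Double-flash-illusion behavioural analysis.

Participants report how many flashes they saw.  Pairing one 17-ms flash with
two 7-ms beeps (onsets 30 ms apart) induces an illusory second flash, so the
proportion of *correct* (veridical) reports collapses in the double-bimodal
condition.  The analysis is fully non-parametric: per-participant proportions
correct feed a Kruskal–Wallis omnibus test over conditions, followed by
paired Dunn post-hoc comparisons with Bonferroni correction over the family
of three.

A simple Bernoulli observer (per-condition probability of reporting "two")
closes the loop for end-to-end tests without human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scheduling import DFI_CONDITIONS, DFITrial

__all__ = [
    "RESPONSE_COLUMNS",
    "validate_responses",
    "load_response_csv",
    "proportions",
    "group_summary",
    "kruskal_wallis",
    "dunn_posthoc",
    "PosthocComparison",
    "StatsResult",
    "analyze_dfi",
    "ObserverModel",
    "simulate_observer",
    "DFI_ANALYSIS_GROUPS",
]

RESPONSE_COLUMNS = [
    "participant_id",
    "setup",
    "condition",
    "trial_index",
    "reported_flashes",
]

#: The omnibus factor levels: (setup, condition), in reporting order.
DFI_ANALYSIS_GROUPS: list[tuple[str, str]] = [
    ("app", "single_unimodal"),
    ("app", "double_bimodal"),
    ("pc", "double_bimodal"),
]


def validate_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Check a response table and add the ``correct`` column.

    Expected columns: participant_id, setup ∈ {app, pc}, condition,
    trial_index (unique within participant × setup), reported_flashes ≥ 0,
    and flash_count_true (inferred from the condition when absent).
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table lacks columns {missing}")
    table = table.copy()
    bad_setup = set(table["setup"]) - {"app", "pc"}
    if bad_setup:
        raise ValueError(f"unknown setup values {sorted(bad_setup)}")
    bad_cond = set(table["condition"]) - set(DFI_CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    if (table["reported_flashes"] < 0).any():
        raise ValueError("reported_flashes must be >= 0")
    dup = table.duplicated(subset=["participant_id", "setup", "trial_index"])
    if dup.any():
        raise ValueError("trial_index not unique within participant × setup")
    if "flash_count_true" not in table.columns:
        table["flash_count_true"] = table["condition"].map(
            {c: nf for c, (nf, _) in DFI_CONDITIONS.items()}
        )
    table["correct"] = table["reported_flashes"] == table["flash_count_true"]
    return table


def load_response_csv(path: str | Path) -> pd.DataFrame:
    """Load a behavioural response CSV (schema of :data:`RESPONSE_COLUMNS`).

    This is the adapter for externally deposited response tables: map the
    source's columns onto the canonical names, one row per trial, then this
    loader validates and derives correctness.
    """
    return validate_responses(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Proportions


def proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per participant × setup × condition proportion of correct reports."""
    if table.empty:
        raise ValueError("empty response table")
    if "correct" not in table.columns:
        table = validate_responses(table)
    out = (
        table.groupby(["participant_id", "setup", "condition"], sort=True)["correct"]
        .agg(prop_correct="mean", n_trials="size")
        .reset_index()
    )
    return out


def group_summary(props: pd.DataFrame) -> pd.DataFrame:
    """Group mean, SD and SEM of proportion correct per setup × condition."""
    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    return (
        props.groupby(["setup", "condition"], sort=True)["prop_correct"]
        .agg(mean="mean", sd=lambda x: float(x.std(ddof=1)), sem=sem, n="size")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Rank statistics


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected), degrees of freedom, chi-square p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, df, 1.0  # identical data carry no rank information
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple[int, int]
    z: float
    p: float
    p_adjusted: float


def dunn_posthoc(
    groups: list[np.ndarray],
    comparisons: list[tuple[int, int]],
    family_size: int | None = None,
    *,
    tie_correction: bool = True,
) -> list[PosthocComparison]:
    """Dunn's pairwise z tests on pooled ranks, Bonferroni-adjusted.

    For pair (i, j): ``z = (mean rank of group j − mean rank of group i) /
    SE`` with the tie-corrected pooled-rank standard error

        SE² = (N(N+1)/12 − ΣT/(12(N−1))) · (1/n_i + 1/n_j),

    ΣT = Σ(t³ − t) over tied value groups.  A group that outperforms its
    comparison partner therefore yields a negative z when listed first.
    Two-sided p values are multiplied by ``family_size`` (default: the
    number of comparisons) and capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    k = len(arrays)
    for i, j in comparisons:
        if not (0 <= i < k and 0 <= j < k and i != j):
            raise ValueError(f"invalid comparison pair {(i, j)}")
    if family_size is None:
        family_size = len(comparisons)
    if family_size < len(comparisons):
        raise ValueError("family_size must be >= number of comparisons")

    pooled = np.concatenate(arrays)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(ranks[bounds[i] : bounds[i + 1]].mean()) for i in range(k)
    ]

    tie_term = 0.0
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))

    var_base = n_tot * (n_tot + 1) / 12.0
    if tie_correction and n_tot > 1:
        var_base -= tie_term / (12.0 * (n_tot - 1))

    out = []
    for i, j in comparisons:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[j] - mean_ranks[i]) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            PosthocComparison(
                pair=(i, j), z=float(z), p=p, p_adjusted=min(1.0, family_size * p)
            )
        )
    return out


# ---------------------------------------------------------------------------
# The full analysis


@dataclass
class StatsResult:
    """Omnibus + post-hoc results of the DFI condition comparison."""

    H: float
    df: int
    p_omnibus: float
    group_labels: list[str]
    posthoc: list[PosthocComparison]

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "df": self.df,
            "p_omnibus": self.p_omnibus,
            "groups": self.group_labels,
            "posthoc": [
                {
                    "pair": [
                        self.group_labels[c.pair[0]],
                        self.group_labels[c.pair[1]],
                    ],
                    "z": c.z,
                    "p": c.p,
                    "p_adjusted": c.p_adjusted,
                }
                for c in self.posthoc
            ],
        }


def analyze_dfi(table: pd.DataFrame, *, tie_correction: bool = True) -> StatsResult:
    """Kruskal–Wallis over the three conditions of interest + paired Dunn.

    Groups (per-participant proportions correct): single-unimodal on the
    app, double-bimodal on the app, double-bimodal on the PC setup.  The
    post-hoc family is the three pairwise comparisons, Bonferroni-corrected
    with family size 3.
    """
    props = proportions(table)
    groups = []
    labels = []
    for setup, condition in DFI_ANALYSIS_GROUPS:
        sel = props[(props["setup"] == setup) & (props["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no responses for {setup}/{condition}")
        groups.append(sel["prop_correct"].to_numpy())
        labels.append(f"{condition}[{setup}]")
    h, df, p = kruskal_wallis(groups)
    posthoc = dunn_posthoc(
        groups,
        comparisons=[(0, 1), (0, 2), (1, 2)],
        family_size=3,
        tie_correction=tie_correction,
    )
    return StatsResult(H=h, df=df, p_omnibus=p, group_labels=labels, posthoc=posthoc)


# ---------------------------------------------------------------------------
# Synthetic observer


@dataclass
class ObserverModel:
    """Bernoulli observer: per-condition probability of reporting "two".

    For ``double_bimodal`` that probability is the fission (illusion) rate;
    for the other conditions it models lapses (for ``double_unimodal``,
    where "two" is correct, use 1 − lapse).
    """

    p_report_two: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        for c, p in self.p_report_two.items():
            if c not in DFI_CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_report_two[{c}] = {p} outside [0, 1]")


def simulate_observer(
    model: ObserverModel,
    schedule: list[DFITrial],
    participant_id: str = "synthetic",
    setup: str = "app",
) -> pd.DataFrame:
    """Simulate reports for one scheduled session; deterministic given seed."""
    rng = np.random.default_rng(model.seed)
    rows = []
    for i, trial in enumerate(schedule):
        p_two = model.p_report_two.get(trial.condition, 0.0)
        reported = 2 if rng.random() < p_two else 1
        rows.append(
            {
                "participant_id": participant_id,
                "setup": setup,
                "condition": trial.condition,
                "trial_index": i,
                "reported_flashes": reported,
            }
        )
    return validate_responses(pd.DataFrame(rows, columns=RESPONSE_COLUMNS))
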