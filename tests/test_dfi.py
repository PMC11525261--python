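"""Behavioural statistics: proportions, Kruskal–Wallis, Dunn, observer loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stimtime.dfi import (
    ObserverModel,
    analyze_dfi,
    dunn_posthoc,
    group_summary,
    kruskal_wallis,
    proportions,
    simulate_observer,
    validate_responses,
)
from stimtime.scheduling import build_dfi_schedule


# ---------------------------------------------------------------------------
# Independent brute-force rank oracles


def brute_ranks(pooled):
    """Midranks from first principles (count-based, no sorting library)."""
    return [
        sum(1 for y in pooled if y < x) + (1 + sum(1 for y in pooled if y == x)) / 2
        for x in pooled
    ]


def brute_kruskal_h(groups):
    pooled = [x for g in groups for x in g]
    n_tot = len(pooled)
    ranks = brute_ranks(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        i += len(g)
        h += (sum(r) ** 2) / len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    ties = sum(
        c**3 - c for c in (pooled.count(v) for v in set(pooled))
    )
    denom = 1 - ties / (n_tot**3 - n_tot)
    return h / denom if denom > 0 else 0.0


def brute_dunn_z(groups, i, j):
    pooled = [x for g in groups for x in g]
    n_tot = len(pooled)
    ranks = brute_ranks(pooled)
    means, k = [], 0
    for g in groups:
        means.append(sum(ranks[k : k + len(g)]) / len(g))
        k += len(g)
    ties = sum(c**3 - c for c in (pooled.count(v) for v in set(pooled)))
    var = n_tot * (n_tot + 1) / 12 - ties / (12 * (n_tot - 1))
    se = (var * (1 / len(groups[i]) + 1 / len(groups[j]))) ** 0.5
    return 0.0 if se == 0 else (means[j] - means[i]) / se


small_group = st.lists(st.integers(0, 5), min_size=1, max_size=8)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, df, p = kruskal_wallis([np.ones(4), np.ones(4), np.ones(4)])
        assert h == 0.0 and df == 2 and p == 1.0

    def test_hand_ranked_h(self):
        h, df, _ = kruskal_wallis([np.array([1, 2]), np.array([3, 4]), np.array([5, 6])])
        assert h == pytest.approx(12 / (6 * 7) * (3**2 / 2 + 7**2 / 2 + 11**2 / 2) - 21)
        assert h == pytest.approx(4.571, abs=1e-3)
        assert df == 2

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(groups=st.lists(small_group, min_size=2, max_size=4))
    def test_matches_brute_force(self, groups):
        arrays = [np.array(g, dtype=float) for g in groups]
        h, _, _ = kruskal_wallis(arrays)
        assert h == pytest.approx(brute_kruskal_h(groups), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        groups=st.lists(
            # 0.1-granular values: keeps exp() injective in float arithmetic
            st.lists(
                st.integers(-50, 50).map(lambda v: v / 10.0),
                min_size=2,
                max_size=8,
            ),
            min_size=2,
            max_size=3,
        )
    )
    def test_invariant_under_monotone_transform(self, groups):
        arrays = [np.array(g) for g in groups]
        h1, _, _ = kruskal_wallis(arrays)
        h2, _, _ = kruskal_wallis([np.exp(a) for a in arrays])  # strictly monotone
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestDunn:
    def test_identical_groups_z_zero(self):
        (res,) = dunn_posthoc([np.ones(5), np.ones(5)], [(0, 1)], family_size=3)
        assert res.z == 0.0
        assert res.p_adjusted == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(groups=st.lists(small_group, min_size=2, max_size=4))
    def test_matches_brute_force(self, groups):
        arrays = [np.array(g, dtype=float) for g in groups]
        pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
        for res in dunn_posthoc(arrays, pairs, family_size=len(pairs)):
            i, j = res.pair
            assert res.z == pytest.approx(brute_dunn_z(groups, i, j), abs=1e-9)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(groups=st.lists(small_group, min_size=2, max_size=3))
    def test_adjusted_p_bounds(self, groups):
        arrays = [np.array(g, dtype=float) for g in groups]
        for res in dunn_posthoc(arrays, [(0, 1)], family_size=3):
            assert res.p <= res.p_adjusted <= 1.0

    def test_family_size_must_cover_comparisons(self):
        with pytest.raises(ValueError):
            dunn_posthoc([np.ones(3), np.zeros(3)], [(0, 1)], family_size=0)

    def test_sign_convention(self):
        """A better-performing first group yields negative z."""
        (res,) = dunn_posthoc(
            [np.array([10.0, 11, 12]), np.array([1.0, 2, 3])], [(0, 1)]
        )
        assert res.z < 0


class TestResponsesAndProportions:
    def make_table(self, reported):
        rows = []
        for i, r in enumerate(reported):
            rows.append(
                {
                    "participant_id": "p1",
                    "setup": "app",
                    "condition": "double_bimodal",
                    "trial_index": i,
                    "reported_flashes": r,
                }
            )
        return pd.DataFrame(rows)

    def test_all_correct(self):
        table = self.make_table([1] * 10)
        props = proportions(validate_responses(table))
        assert (props["prop_correct"] == 1.0).all()

    def test_correctness_against_true_flash_count(self):
        table = validate_responses(self.make_table([1, 2, 2, 2]))
        assert table["correct"].tolist() == [True, False, False, False]

    def test_duplicate_trial_index_rejected(self):
        table = self.make_table([1, 1])
        table.loc[1, "trial_index"] = 0
        with pytest.raises(ValueError, match="unique"):
            validate_responses(table)

    def test_unknown_condition_rejected(self):
        table = self.make_table([1])
        table["condition"] = "quintuple_bimodal"
        with pytest.raises(ValueError, match="condition"):
            validate_responses(table)


class TestObserverLoop:
    def test_veridical_observer_all_correct(self):
        sched = build_dfi_schedule(10, seed=0)
        model = ObserverModel(
            p_report_two={
                "single_unimodal": 0.0,
                "double_unimodal": 1.0,  # correctly reports two flashes
                "single_bimodal": 0.0,
                "double_bimodal": 0.0,
            },
            seed=1,
        )
        table = simulate_observer(model, sched)
        assert table["correct"].all()

    def test_full_fission_zero_correct(self):
        sched = build_dfi_schedule(10, seed=0)
        model = ObserverModel(p_report_two={"double_bimodal": 1.0}, seed=1)
        table = simulate_observer(model, sched)
        db = table[table["condition"] == "double_bimodal"]
        assert (~db["correct"]).all()

    def test_proportion_recovers_fission_probability(self):
        """proportions ∘ simulate_observer recovers the injected rate."""
        p_fission = 0.8
        n_participants, reps = 12, 20
        props = []
        for k in range(n_participants):
            sched = build_dfi_schedule(reps, seed=k)
            model = ObserverModel(
                p_report_two={"double_bimodal": p_fission}, seed=100 + k
            )
            table = simulate_observer(model, sched, participant_id=f"p{k}")
            pr = proportions(table)
            props.append(
                float(
                    pr[pr["condition"] == "double_bimodal"]["prop_correct"].iloc[0]
                )
            )
        n_tot = n_participants * reps
        expect = 1 - p_fission
        se = np.sqrt(p_fission * expect / n_tot)
        assert abs(np.mean(props) - expect) < 3 * se

    def test_end_to_end_stats_detect_the_illusion(self):
        """Synthetic cohort: strong fission on both setups, ceiling on
        single flashes -> significant omnibus, matched setups."""
        rows = []
        for k in range(10):
            for setup in ("app", "pc"):
                sched = build_dfi_schedule(20, seed=k)
                model = ObserverModel(
                    p_report_two={
                        "single_unimodal": 0.03,
                        "double_bimodal": 0.82,
                    },
                    seed=500 + 2 * k + (setup == "pc"),
                )
                rows.append(
                    simulate_observer(model, sched, participant_id=f"p{k}", setup=setup)
                )
        table = pd.concat(rows, ignore_index=True)
        result = analyze_dfi(table)
        assert result.df == 2
        assert result.H > 10
        assert result.p_omnibus < 0.001
        by_pair = {c.pair: c for c in result.posthoc}
        assert by_pair[(0, 1)].z < 0  # single beats double-bimodal (app)
        assert by_pair[(0, 1)].p_adjusted < 0.01
        assert by_pair[(0, 2)].z < 0
        assert by_pair[(1, 2)].p_adjusted > 0.05  # setups equivalent
        summary = group_summary(proportions(table))
        single = summary[
            (summary["setup"] == "app") & (summary["condition"] == "single_unimodal")
        ]
        assert float(single["mean"].iloc[0]) > 0.9
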