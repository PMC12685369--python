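"""Frailty-index scoring, state cutoffs, and panel assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailmsm.index import (
    MAX_MISSING,
    N_ITEMS,
    assemble_panel,
    build_assessments,
    categorize_state,
    compute_fi,
    compute_fi_frame,
    default_item_template,
    load_item_specs,
    save_item_specs,
)
from frailmsm.panel import PanelValidationError


def _items(overrides):
    v = np.zeros(N_ITEMS)
    for idx, val in overrides.items():
        v[idx] = val
    return v


class TestComputeFI:
    def test_renormalises_to_valid_items(self):
        # 2 missing, 6 deficits among the 30 valid items -> 6/30
        v = np.zeros(N_ITEMS)
        v[:6] = 1.0
        v[30:] = np.nan
        assert compute_fi(v) == pytest.approx(6 / 30)

    def test_zero_deficits(self):
        assert compute_fi(np.zeros(N_ITEMS)) == 0.0

    def test_more_than_three_missing_is_missing(self):
        v = np.zeros(N_ITEMS)
        v[: MAX_MISSING + 1] = np.nan
        assert np.isnan(compute_fi(v))

    def test_exactly_three_missing_is_scored(self):
        v = np.zeros(N_ITEMS)
        v[:MAX_MISSING] = np.nan
        assert compute_fi(v) == 0.0

    @pytest.mark.parametrize("bad", [np.full(31, 0.0), np.full(33, 0.0)])
    def test_wrong_length_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_fi(bad)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_fi(_items({0: 1.2}))

    @given(st.lists(st.floats(0, 1), min_size=N_ITEMS, max_size=N_ITEMS),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, values, rnd):
        v = list(values)
        fi1 = compute_fi(v)
        rnd.shuffle(v)
        assert compute_fi(v) == pytest.approx(fi1)

    @given(st.floats(0, 1), st.integers(0, MAX_MISSING))
    @settings(max_examples=50, deadline=None)
    def test_renormalization_identity(self, c, k):
        # k missing items, everything else equal to c -> FI == c
        v = np.full(N_ITEMS, c)
        v[:k] = np.nan
        assert compute_fi(v) == pytest.approx(c)

    def test_filling_missing_with_one_never_decreases(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            v = rng.uniform(0, 1, N_ITEMS)
            miss = rng.choice(N_ITEMS, size=rng.integers(1, MAX_MISSING + 1),
                              replace=False)
            v[miss] = np.nan
            base = compute_fi(v)
            hi = v.copy(); hi[miss] = 1.0
            lo = v.copy(); lo[miss] = 0.0
            assert compute_fi(hi) >= base - 1e-12
            assert compute_fi(lo) <= base + 1e-12

    def test_frame_scoring_matches_scalar(self):
        rng = np.random.default_rng(1)
        rows = rng.uniform(0, 1, size=(20, N_ITEMS))
        rows[rng.random(rows.shape) < 0.1] = np.nan
        frame = pd.DataFrame(rows)
        scored = compute_fi_frame(frame)
        for k in range(len(rows)):
            expected = compute_fi(rows[k])
            got = scored["fi_value"].iloc[k]
            assert (np.isnan(expected) and np.isnan(got)) or \
                got == pytest.approx(expected)


class TestCategorizeState:
    @pytest.mark.parametrize("fi,state", [
        (0.0, 1), (0.10, 1),          # boundary 0.10 is robust
        (0.1000001, 2), (0.17, 2), (0.2499999, 2),
        (0.25, 3), (1.0, 3),          # boundary 0.25 is frail
    ])
    def test_cutoffs(self, fi, state):
        assert categorize_state(fi) == state

    def test_missing_propagates(self):
        assert np.isnan(categorize_state(np.nan))

    @given(st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, fi):
        assert categorize_state(fi) in (1, 2, 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_state(1.5)


class TestItemTemplate:
    def test_default_template_has_32_items_one_continuous(self):
        items = default_item_template()
        assert len(items) == N_ITEMS
        kinds = [i.kind for i in items]
        assert kinds.count("continuous_unit_interval") == 1
        assert kinds[-1] == "continuous_unit_interval"

    def test_roundtrip_json_and_yaml(self, tmp_path):
        items = default_item_template()
        for name in ("items.json", "items.yaml"):
            p = tmp_path / name
            save_item_specs(items, p)
            assert load_item_specs(p) == items


class TestAssemblePanel:
    @staticmethod
    def _assessments(rows):
        return pd.DataFrame(rows, columns=["subject_id", "wave", "time",
                                           "fi_value", "state"])

    def test_two_wave_subject_retained(self):
        a = self._assessments([(1, 1, 0.0, 0.05, 1), (1, 3, 4.0, 0.3, 3)])
        ds = assemble_panel(a)
        assert ds.n_subjects == 1
        assert len(ds.observations) == 2

    def test_single_observation_excluded_and_counted(self):
        a = self._assessments([(1, 1, 0.0, 0.05, 1),
                               (2, 1, 0.0, 0.05, 1), (2, 2, 2.0, 0.2, 2)])
        ds = assemble_panel(a)
        assert ds.n_subjects == 1
        assert len(ds.exclusions) == 1
        assert ds.exclusions["subject_id"].iloc[0] == 1

    def test_death_completes_a_pair(self):
        a = self._assessments([(1, 1, 0.0, 0.05, 1)])
        deaths = pd.DataFrame({"subject_id": [1], "death_time": [3.0]})
        ds = assemble_panel(a, deaths)
        assert ds.n_subjects == 1
        assert ds.observations["state"].iloc[-1] == 4
        assert ds.observations["time"].iloc[-1] == 3.0

    def test_missing_fi_wave_dropped(self):
        a = self._assessments([(1, 1, 0.0, 0.05, 1),
                               (1, 2, 2.0, np.nan, np.nan),
                               (1, 3, 4.0, 0.3, 3)])
        ds = assemble_panel(a)
        assert len(ds.observations) == 2
        assert list(ds.observations["time"]) == [0.0, 4.0]

    def test_nonmonotone_times_rejected(self):
        a = self._assessments([(1, 1, 2.0, 0.05, 1), (1, 2, 1.0, 0.2, 2)])
        with pytest.raises(PanelValidationError) as err:
            assemble_panel(a)
        assert 1 in err.value.subjects

    def test_observation_after_death_rejected(self):
        a = self._assessments([(1, 1, 0.0, 0.05, 1), (1, 2, 5.0, 0.2, 2)])
        deaths = pd.DataFrame({"subject_id": [1], "death_time": [3.0]})
        with pytest.raises(PanelValidationError):
            assemble_panel(a, deaths)


def test_build_assessments_end_to_end():
    rng = np.random.default_rng(5)
    vals = rng.integers(0, 2, size=(4, N_ITEMS)).astype(float)
    vals[:, -1] = rng.uniform(0, 1, 4)
    df = pd.DataFrame(vals, columns=[f"item_{i+1}" for i in range(N_ITEMS)])
    df.insert(0, "subject_id", [1, 1, 2, 2])
    df.insert(1, "wave", [1, 2, 1, 2])
    df.insert(2, "time", [0.0, 2.0, 0.0, 2.0])
    out = build_assessments(df)
    assert set(out.columns) >= {"subject_id", "wave", "time", "fi_value",
                                "state", "n_valid_items"}
    for k in range(4):
        assert out["fi_value"].iloc[k] == pytest.approx(vals[k].sum() / N_ITEMS)
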