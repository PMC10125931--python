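"""Aggregation and the BIS/LISAS measure family.

Frozen expected values were computed by hand or with an independent
brute-force z-standardization (statistics.stdev) before the implementation
was written; the hypothesis property re-derives every measure from scratch
with plain Python loops on random cell sets.
"""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from speedacc import (
    AggregationError,
    DegenerateVarianceError,
    MeasureContext,
    UndefinedMeasureError,
    aggregate,
    bis,
    bis_rt_scaled,
    compute_measures,
    ies,
    lisas,
    lisas_bis,
    lisas_cond,
    rcs,
)


def make_cells(mean_rt, pc, participants=None, conditions=None, **extra):
    """Cell table from per-cell vectors (2 participants x 2 conditions default)."""
    k = len(mean_rt)
    participants = participants or [1, 1, 2, 2][:k]
    conditions = conditions or [1, 2, 1, 2][:k]
    pc = np.asarray(pc, dtype=float)
    base = {
        "participant": participants,
        "condition": conditions,
        "n": extra.pop("n", [100] * k),
        "n_correct": extra.pop("n_correct", (pc * 100).round().astype(int)),
        "mean_rt": np.asarray(mean_rt, dtype=float),
        "pc": pc,
        "pe": 1.0 - pc,
        "sum_rt_all": extra.pop("sum_rt_all", np.asarray(mean_rt, dtype=float) * 100),
        "sd_rt_participant": extra.pop("sd_rt_participant", [100.0] * k),
        "sd_e_participant": extra.pop("sd_e_participant", [0.5] * k),
        "sd_rt_cell": extra.pop("sd_rt_cell", [90.0] * k),
        "sd_e_cell": extra.pop("sd_e_cell", [0.4] * k),
    }
    return pd.DataFrame(base)


class TestAggregate:
    def test_hand_checked_cell(self, toy_trials):
        cells = aggregate(toy_trials)
        c = cells.set_index(["participant", "condition"])
        # participant 1, condition 1: correct RTs 400, 500; one error
        assert c.loc[(1, 1), "mean_rt"] == pytest.approx(450.0)
        assert c.loc[(1, 1), "pc"] == pytest.approx(2 / 3)
        assert c.loc[(1, 1), "pe"] == pytest.approx(1 / 3)
        assert c.loc[(1, 2), "pc"] == pytest.approx(1.0)
        # participant-pooled correct RTs of p1: 400, 500, 450, 550, 650
        assert c.loc[(1, 1), "sd_rt_participant"] == pytest.approx(
            statistics.stdev([400, 500, 450, 550, 650])
        )
        assert c.loc[(1, 1), "sd_rt_participant"] == c.loc[(1, 2), "sd_rt_participant"]
        # error indicator of p1 over all 6 trials: one error
        assert c.loc[(1, 1), "sd_e_participant"] == pytest.approx(
            statistics.stdev([1, 0, 0, 0, 0, 0])
        )

    def test_cell_error_sd_matches_bernoulli_form(self, toy_trials):
        # with the population convention the cell error SD is sqrt(PE*(1-PE))
        cells = aggregate(toy_trials, ddof=0)
        for _, row in cells.iterrows():
            assert row["sd_e_cell"] == pytest.approx(math.sqrt(row["pe"] * (1 - row["pe"])))

    def test_row_order_irrelevant(self, toy_trials):
        shuffled = toy_trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(aggregate(toy_trials), aggregate(shuffled))

    def test_cell_without_correct_trials_raises(self):
        bad = pd.DataFrame(
            {"participant": [1, 1], "condition": [1, 2], "rt": [500.0, 600.0], "correct": [0, 1]}
        )
        with pytest.raises(AggregationError, match="condition=1"):
            aggregate(bad)


class TestBis:
    def test_frozen_oracle_values(self):
        # brute-force z-standardization (sample SD) computed independently
        cells = make_cells([500.0, 520.0, 480.0, 540.0], [0.90, 0.85, 0.95, 0.80])
        got = bis(cells)
        expected = [0.774596669241484, -0.774596669241484, 2.32379000772445, -2.32379000772445]
        assert np.allclose(got, expected)

    def test_sums_to_zero_over_scope(self):
        rng = np.random.default_rng(0)
        cells = make_cells(rng.uniform(400, 700, 6), rng.uniform(0.6, 0.99, 6),
                           participants=[1, 1, 2, 2, 3, 3], conditions=[1, 2] * 3)
        assert bis(cells).sum() == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_positive_affine_rt_transform(self):
        cells = make_cells([500.0, 520.0, 480.0, 540.0], [0.90, 0.85, 0.95, 0.80])
        transformed = cells.copy()
        transformed["mean_rt"] = 2.0 * cells["mean_rt"] + 100.0
        assert np.allclose(bis(cells), bis(transformed))

    def test_zero_variance_raises(self):
        cells = make_cells([500.0] * 4, [0.9, 0.8, 0.85, 0.95])
        with pytest.raises(DegenerateVarianceError):
            bis(cells)


class TestBisRtScaled:
    def test_mean_is_grand_mean_rt_and_anticorrelated_with_bis(self):
        cells = make_cells([500.0, 520.0, 480.0, 540.0], [0.90, 0.85, 0.95, 0.80])
        scaled = bis_rt_scaled(cells)
        assert scaled.mean() == pytest.approx(cells["mean_rt"].mean())
        assert np.corrcoef(scaled, bis(cells))[0, 1] == pytest.approx(-1.0)


class TestLisas:
    def test_hand_value(self):
        # RTbar=450, PE=1/3, S^RT=100, S^E=0.5 -> 450 + 200/3
        cells = make_cells([450.0], [2 / 3], participants=[1], conditions=[1],
                          sd_rt_participant=[100.0], sd_e_participant=[0.5])
        assert lisas(cells).iloc[0] == pytest.approx(450.0 + 200.0 / 3.0)

    def test_error_free_participant_degenerates_to_mean_rt(self):
        cells = make_cells([450.0, 470.0], [1.0, 1.0], participants=[1, 1], conditions=[1, 2],
                          sd_e_participant=[0.0, 0.0], sd_e_cell=[0.0, 0.0])
        assert np.allclose(lisas(cells), cells["mean_rt"])
        assert np.allclose(lisas_cond(cells), cells["mean_rt"])

    def test_lisas_cond_coincides_when_cell_sds_equal_pooled(self):
        cells = make_cells([500.0, 520.0], [0.9, 0.8], participants=[1, 1], conditions=[1, 2],
                          sd_rt_participant=[80.0, 80.0], sd_e_participant=[0.3, 0.3],
                          sd_rt_cell=[80.0, 80.0], sd_e_cell=[0.3, 0.3])
        assert np.allclose(lisas(cells), lisas_cond(cells))

    def test_not_invariant_to_affine_rt_transform(self):
        # the deliberate contrast with BIS: trial-SD scaling breaks affine invariance
        cells = make_cells([500.0, 520.0, 480.0, 540.0], [0.90, 0.85, 0.95, 0.80])
        t = cells.copy()
        t["mean_rt"] = 2.0 * cells["mean_rt"] + 100.0
        d_orig = lisas(cells).iloc[0] - lisas(cells).iloc[1]
        d_trans = lisas(t).iloc[0] - lisas(t).iloc[1]
        assert d_trans != pytest.approx(2.0 * d_orig)


class TestLisasBis:
    def test_differs_from_bis_rt_scaled_by_cellwise_constant(self):
        rng = np.random.default_rng(4)
        cells = make_cells(rng.uniform(400, 700, 8), rng.uniform(0.6, 0.99, 8),
                           participants=[1, 1, 2, 2, 3, 3, 4, 4], conditions=[1, 2] * 4)
        diff = lisas_bis(cells) - bis_rt_scaled(cells)
        assert np.ptp(diff.to_numpy()) == pytest.approx(0.0, abs=1e-9)

    def test_equal_pe_everywhere_reduces_to_rt_differences(self):
        cells = make_cells([500.0, 520.0, 480.0, 540.0], [0.9] * 4)
        with pytest.raises(DegenerateVarianceError):
            lisas_bis(cells)  # S^PE = 0 in that case: degenerate by definition


class TestBaselines:
    def test_ies_reduces_to_mean_rt_at_perfect_accuracy(self):
        cells = make_cells([480.0], [1.0], participants=[1], conditions=[1])
        assert ies(cells).iloc[0] == pytest.approx(480.0)

    def test_ies_monotone_decreasing_in_pc(self):
        cells = make_cells([500.0] * 3, [0.7, 0.8, 0.9],
                           participants=[1, 2, 3], conditions=[1, 1, 1])
        vals = ies(cells).to_numpy()
        assert vals[0] > vals[1] > vals[2]

    def test_ies_undefined_at_zero_pc(self):
        cells = make_cells([500.0], [0.0], participants=[1], conditions=[1])
        with pytest.raises(UndefinedMeasureError):
            ies(cells)

    def test_rcs_hand_value(self):
        # 2 correct trials with RTs 400 and 600 -> 2 / 1000 responses per ms
        trials = pd.DataFrame(
            {"participant": [1, 1], "condition": [1, 1], "rt": [400.0, 600.0], "correct": [1, 1]}
        )
        cells = aggregate(trials)
        assert rcs(cells).iloc[0] == pytest.approx(0.002)


@st.composite
def random_cells(draw):
    n_participants = draw(st.integers(2, 4))
    k = 2 * n_participants
    rts = draw(st.lists(st.floats(300, 900), min_size=k, max_size=k))
    pcs = draw(st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k))
    return make_cells(
        rts, pcs,
        participants=[p for p in range(1, n_participants + 1) for _ in (0, 1)],
        conditions=[1, 2] * n_participants,
        sd_rt_participant=draw(st.lists(st.floats(10, 200), min_size=k, max_size=k)),
        sd_e_participant=draw(st.lists(st.floats(0.05, 0.5), min_size=k, max_size=k)),
    )


@settings(max_examples=40, derandomize=True)
@given(cells=random_cells())
def test_measures_match_brute_force_oracle(cells):
    """Every measure equals an independently coded plain-Python computation."""
    rt = list(cells["mean_rt"])
    pc = list(cells["pc"])
    m_rt, s_rt = statistics.mean(rt), statistics.stdev(rt)
    m_pc, s_pc = statistics.mean(pc), statistics.stdev(pc)
    if s_rt == 0 or s_pc == 0:
        return
    exp_bis = [(p - m_pc) / s_pc - (r - m_rt) / s_rt for r, p in zip(rt, pc)]
    exp_scaled = [m_rt - s_rt * b for b in exp_bis]
    exp_lisas = [
        r + (srt / se) * (1 - p)
        for r, p, srt, se in zip(rt, pc, cells["sd_rt_participant"], cells["sd_e_participant"])
    ]
    exp_lisas_bis = [r + (s_rt / s_pc) * (1 - p) for r, p in zip(rt, pc)]
    assert np.allclose(bis(cells), exp_bis)
    assert np.allclose(bis_rt_scaled(cells), exp_scaled)
    assert np.allclose(lisas(cells), exp_lisas)
    assert np.allclose(lisas_bis(cells), exp_lisas_bis)
    assert np.allclose(ies(cells), [r / p for r, p in zip(rt, pc)])


def test_compute_measures_schema():
    rng = np.random.default_rng(9)
    cells = make_cells(rng.uniform(400, 700, 4), rng.uniform(0.6, 0.95, 4))
    out = compute_measures(cells)
    assert list(out.columns) == [
        "participant", "condition", "mean_rt", "pc",
        "bis", "bis_rt_scaled", "lisas", "lisas_cond", "lisas_bis", "ies", "rcs",
    ]
    with pytest.raises(KeyError):
        compute_measures(cells, measures=["nope"])


def test_z_of_pc_equals_negated_z_of_pe():
    """PE = 1 - PC is a reflection: z(PC) = -z(PE) exactly (same SD)."""
    rng = np.random.default_rng(11)
    pc = rng.uniform(0.5, 1.0, 6)
    ctx_pc = (pc - pc.mean()) / np.std(pc, ddof=1)
    pe = 1 - pc
    ctx_pe = (pe - pe.mean()) / np.std(pe, ddof=1)
    assert np.allclose(ctx_pc, -ctx_pe)
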