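"""Monte Carlo grid harness: cells, grids, resume, and the decision map."""

import numpy as np
import pandas as pd
import pytest

from hurstkit.contaminate import ContaminantSpec
from hurstkit.experiment import (
    RESULT_COLUMNS,
    RunConfig,
    decision_map,
    load_config,
    parse_kind_token,
    run_cell,
    run_grid,
    substream_seed,
)


def make_decision_table(errors_by_cell):
    """Tiny synthetic results table: {(H, N, A): {est: abs_error}}."""
    rows = []
    for (H, N, A), errs in errors_by_cell.items():
        for est, err in errs.items():
            rows.append(
                dict(
                    estimator=est, contaminant="awgn", H_true=H, N=N, A=A,
                    tau=0.0, sign=0, n_reps=10, n_failures=0,
                    mean_hhat=H + err, sd_hhat=0.1, ci_low=H, ci_high=H + 2 * err,
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


class TestSeeding:
    def test_substream_seed_is_stable_and_bounded(self):
        s = substream_seed("x", 42, 0.8, 64, 3)
        assert s == substream_seed("x", 42, 0.8, 64, 3)
        assert 0 <= s < 2**31
        assert s != substream_seed("x", 42, 0.8, 64, 4)
        assert s != substream_seed("c", 42, 0.8, 64, 3)


class TestRunCell:
    def test_deterministic(self):
        spec = ContaminantSpec(kind="awgn", A=0.5)
        a = run_cell("DFA1", 0.6, 64, spec, 5, master_seed=1)
        b = run_cell("DFA1", 0.6, 64, spec, 5, master_seed=1)
        assert a == b

    def test_zero_amplitude_equals_uncontaminated_across_kinds(self):
        """At A = 0 every contaminant kind reproduces the same cell exactly."""
        cells = [
            run_cell("DFA1", 0.7, 64, ContaminantSpec(kind=kind, A=0.0), 5, master_seed=3)
            for kind in ("awgn", "fgn", "linear", "cyclical")
        ]
        means = {c.mean_hhat for c in cells}
        assert len(means) == 1

    def test_ci_brackets_mean(self):
        cell = run_cell("DFA2", 0.5, 64, ContaminantSpec(kind="awgn", A=0.3), 10, master_seed=5)
        assert cell.ci_low <= cell.mean_hhat <= cell.ci_high
        assert cell.abs_error >= 0
        assert cell.n_failures == 0 and not cell.failed

    def test_hk_parameter_recovery(self):
        """HK cell at H = 0.8, n = 256, A = 0 recovers H within 0.05 (100 reps)."""
        cell = run_cell("HK", 0.8, 256, ContaminantSpec(kind="awgn", A=0.0), 100, master_seed=7)
        assert abs(cell.mean_hhat - 0.8) < 0.05

    def test_failures_counted_and_cell_marked(self):
        """DFA needs n >= 16, so every replicate fails at n = 8."""
        cell = run_cell("DFA1", 0.5, 8, ContaminantSpec(kind="awgn", A=0.0), 4, master_seed=1)
        assert cell.n_failures == 4 and cell.failed
        assert np.isnan(cell.mean_hhat)

    def test_invalid_args(self):
        spec = ContaminantSpec(kind="awgn", A=0.0)
        with pytest.raises(ValueError):
            run_cell("XYZ", 0.5, 64, spec, 5, 0)
        with pytest.raises(ValueError):
            run_cell("HK", 0.5, 64, spec, 1, 0)


class TestConfig:
    def test_axes_accept_lists_and_comma_strings(self):
        cfg = load_config(
            dict(H="0.2, 0.8", N=[32, 64], A="0,1", kinds="awgn,linear:-", estimators="hk, dfa1")
        )
        assert cfg.H == (0.2, 0.8) and cfg.N == (32, 64) and cfg.A == (0.0, 1.0)
        assert cfg.estimators == ("HK", "DFA1")
        assert parse_kind_token(cfg.kinds[1]).sign == -1

    def test_unknown_and_missing_keys_error_before_compute(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(dict(H=[0.5], N=[32], A=[0], kinds=["awgn"], estimators=["HK"], reps=9))
        with pytest.raises(ValueError, match="missing config keys"):
            load_config(dict(H=[0.5]))

    def test_paper_scale_cell_count(self):
        cfg = RunConfig(
            H=tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
            N=(32, 64, 128, 256, 512, 1024),
            A=tuple(np.round(np.arange(0.0, 1.05, 0.1), 1)),
            kinds=("awgn",),
            estimators=("HK", "DFA1", "DFA2"),
            n_reps=1000,
        )
        assert cfg.n_cells() == 1782

    def test_bad_axis_values(self):
        with pytest.raises(ValueError):
            RunConfig(H=(1.2,), N=(64,), A=(0.0,), kinds=("awgn",), estimators=("HK",))
        with pytest.raises(ValueError):
            RunConfig(H=(0.5,), N=(8,), A=(0.0,), kinds=("awgn",), estimators=("HK",))


class TestRunGrid:
    DEMO = dict(
        H=[0.3, 0.8], N=[32, 64], A=[0.0, 1.0], kinds=["awgn"],
        estimators=["HK", "DFA1", "DFA2"], n_reps=4, master_seed=11,
    )

    def test_single_cell_grid(self):
        cfg = dict(H=[0.5], N=[64], A=[0.0], kinds=["awgn"], estimators=["DFA1"], n_reps=3, master_seed=0)
        table = run_grid(cfg)
        assert len(table) == 1 and list(table.columns) == RESULT_COLUMNS

    def test_round_trip_and_resume(self, tmp_path):
        out = tmp_path / "results.csv"
        table = run_grid(self.DEMO, out_path=out)
        assert len(table) == 24
        first_bytes = out.read_bytes()
        # rerun resumes: every row already present, file untouched, same table
        table2 = run_grid(self.DEMO, out_path=out)
        assert out.read_bytes() == first_bytes
        pd.testing.assert_frame_equal(
            table.reset_index(drop=True),
            pd.read_csv(out)[RESULT_COLUMNS],
            check_dtype=False,
        )
        assert np.allclose(table["mean_hhat"], table2["mean_hhat"])

    def test_pure_function_of_config(self):
        a = run_grid(dict(self.DEMO, N=[32]))
        b = run_grid(dict(self.DEMO, N=[32]))
        pd.testing.assert_frame_equal(a, b)


class TestDecisionMap:
    def test_unique_argmin_under_threshold(self):
        table = make_decision_table({(0.5, 64, 0.1): {"HK": 0.05, "DFA1": 0.2, "DFA2": 0.3}})
        out = decision_map(table)
        assert list(out["best"]) == ["HK"]
        assert out["min_abs_error"][0] == pytest.approx(0.05)

    def test_all_above_threshold_gives_none(self):
        table = make_decision_table({(0.5, 64, 0.1): {"HK": 0.2, "DFA1": 0.15, "DFA2": 0.3}})
        assert list(decision_map(table)["best"]) == ["none"]

    def test_tie_break_prefers_hk_then_dfa1(self):
        table = make_decision_table(
            {
                (0.5, 64, 0.1): {"HK": 0.08, "DFA1": 0.08, "DFA2": 0.2},
                (0.3, 64, 0.1): {"HK": 0.2, "DFA1": 0.06, "DFA2": 0.06},
            }
        )
        out = decision_map(table)
        assert list(out["best"]) == ["HK", "DFA1"]

    def test_missing_estimator_errors_with_cell_name(self):
        table = make_decision_table({(0.5, 64, 0.1): {"HK": 0.05, "DFA1": 0.2, "DFA2": 0.3}})
        with pytest.raises(ValueError, match="DFA2"):
            decision_map(table[table.estimator != "DFA2"])

    def test_custom_threshold(self):
        table = make_decision_table({(0.5, 64, 0.1): {"HK": 0.15, "DFA1": 0.3, "DFA2": 0.3}})
        assert list(decision_map(table, threshold=0.2)["best"]) == ["HK"]
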