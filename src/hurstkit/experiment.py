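"""Monte Carlo benchmarking of Hurst estimators under contamination.

The harness sweeps a grid of true Hurst exponents H, series lengths N,
contaminant families, and contamination amplitudes A.  Each grid cell
simulates ``n_reps`` fGn series, contaminates them, estimates H with one of
{HK, DFA1, DFA2}, and summarizes the replicate estimates (mean, SD, 95% CI).
The decision map then reports, per cell, which estimator attains
``|mean estimate - H| <= threshold`` (default 0.1) with the smallest error,
or ``none`` when no estimator does.

Every replicate draws its randomness from substreams derived by a stable
hash of (master seed, cell identity, replicate index), so the whole grid is
a pure function of its config and individual cells are independently
reproducible.  The fGn substream and the estimator substream deliberately
exclude the contaminant kind and amplitude: cells at A = 0 coincide exactly
with the uncontaminated cell, and contaminant families share common random
numbers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contaminate import KINDS, LONG_TAU, SHORT_TAU, ContaminantSpec, contaminate
from .dfa import estimate_h_dfa
from .fgn import simulate_fgn
from .hk import estimate_h_hk

__all__ = [
    "CellSummary",
    "RunConfig",
    "ESTIMATORS",
    "RESULT_COLUMNS",
    "DECISION_COLUMNS",
    "substream_seed",
    "parse_kind_token",
    "run_cell",
    "run_grid",
    "decision_map",
    "load_config",
]

ESTIMATORS = ("HK", "DFA1", "DFA2")

RESULT_COLUMNS = [
    "estimator",
    "contaminant",
    "H_true",
    "N",
    "A",
    "tau",
    "sign",
    "n_reps",
    "n_failures",
    "mean_hhat",
    "sd_hhat",
    "ci_low",
    "ci_high",
]

DECISION_COLUMNS = ["contaminant", "tau", "sign", "H_true", "N", "A", "best", "min_abs_error"]

#: a cell with more than this fraction of failed replicates is marked failed
FAILURE_FRACTION = 0.1


def _canon(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def substream_seed(*parts) -> int:
    """Stable substream seed: blake2b of the canonical key, reduced mod 2^31."""
    key = "|".join(_canon(p) for p in parts)
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class CellSummary:
    """Replicate summary for one (estimator, H, N, contaminant) grid cell."""

    estimator: str
    H_true: float
    n: int
    contaminant: ContaminantSpec
    n_reps: int
    n_failures: int
    mean_hhat: float
    sd_hhat: float
    ci_low: float
    ci_high: float
    failed: bool = False

    @property
    def abs_error(self) -> float:
        return abs(self.mean_hhat - self.H_true)

    def to_row(self) -> dict:
        spec = self.contaminant
        return {
            "estimator": self.estimator,
            "contaminant": spec.kind,
            "H_true": self.H_true,
            "N": self.n,
            "A": spec.A,
            "tau": spec.tau if spec.kind == "cyclical" else 0.0,
            "sign": spec.sign if spec.kind in ("linear", "quadratic") else 0,
            "n_reps": self.n_reps,
            "n_failures": self.n_failures,
            "mean_hhat": self.mean_hhat,
            "sd_hhat": self.sd_hhat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _estimate(estimator: str, y: np.ndarray, seed: int) -> float:
    if estimator == "HK":
        return estimate_h_hk(y, 100, seed)
    if estimator == "DFA1":
        return estimate_h_dfa(y, order=1).h_hat
    if estimator == "DFA2":
        return estimate_h_dfa(y, order=2).h_hat
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def run_cell(
    estimator: str,
    H_true: float,
    n: int,
    spec: ContaminantSpec,
    n_reps: int,
    master_seed: int,
    ci: str = "normal",
) -> CellSummary:
    """Monte Carlo summary of one grid cell.

    Each replicate r simulates fGn(H_true, n) from its own substream,
    contaminates it (stochastic contaminants use a second, independent
    substream), and estimates H.  Replicates whose estimator raises are
    counted in ``n_failures`` and excluded; a cell with more than 10%
    failures is marked failed.

    The 95% CI of the mean is ``mean +/- 1.96*sd/sqrt(n_ok)`` (``ci="normal"``)
    or the 2.5/97.5 percentiles of the replicate estimates (``ci="percentile"``).
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if ci not in ("normal", "percentile"):
        raise ValueError(f"ci must be 'normal' or 'percentile'; got {ci!r}")
    estimates = []
    n_failures = 0
    for r in range(n_reps):
        x_seed = substream_seed("x", master_seed, H_true, n, r)
        c_seed = substream_seed(
            "c", master_seed, spec.kind, spec.A, spec.tau, spec.sign,
            spec.Hc, spec.d, spec.a1, H_true, n, r,
        )
        e_seed = substream_seed("e", master_seed, estimator, H_true, n, r)
        x = simulate_fgn(H_true, n, x_seed)
        y = contaminate(x, spec, c_seed)
        try:
            estimates.append(_estimate(estimator, y, e_seed))
        except Exception:
            n_failures += 1
    failed = n_failures > FAILURE_FRACTION * n_reps
    if len(estimates) >= 2 and not failed:
        est = np.asarray(estimates)
        mean = float(est.mean())
        sd = float(est.std(ddof=1))
        if ci == "normal":
            half = 1.96 * sd / np.sqrt(len(est))
            lo, hi = mean - half, mean + half
        else:
            lo, hi = (float(q) for q in np.percentile(est, [2.5, 97.5]))
            lo, hi = min(lo, mean), max(hi, mean)
    else:
        failed = True
        mean = sd = lo = hi = float("nan")
    return CellSummary(
        estimator=estimator,
        H_true=float(H_true),
        n=int(n),
        contaminant=spec,
        n_reps=int(n_reps),
        n_failures=n_failures,
        mean_hhat=mean,
        sd_hhat=sd,
        ci_low=lo,
        ci_high=hi,
        failed=failed,
    )


def parse_kind_token(token: str) -> ContaminantSpec:
    """Parse a contaminant token into a template spec (amplitude filled later).

    Tokens are the kind name with an optional ``:parameter`` suffix —
    ``cyclical:365``, ``cyclical:36500``, ``linear:+``, ``quadratic:-``.
    Bare ``cyclical`` defaults to tau=365; bare trends default to sign +1.
    """
    kind, _, param = token.partition(":")
    kind = kind.strip()
    kwargs = {}
    if param:
        if kind == "cyclical":
            kwargs["tau"] = float(param)
        elif kind in ("linear", "quadratic"):
            if param not in ("+", "-", "+1", "-1"):
                raise ValueError(f"trend sign must be '+' or '-'; got {param!r} in {token!r}")
            kwargs["sign"] = 1 if param.startswith("+") else -1
        else:
            raise ValueError(f"kind {kind!r} takes no parameter (token {token!r})")
    return ContaminantSpec(kind=kind, A=0.0, **kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Validated experiment grid configuration."""

    H: tuple[float, ...]
    N: tuple[int, ...]
    A: tuple[float, ...]
    kinds: tuple[str, ...]
    estimators: tuple[str, ...]
    n_reps: int = 200
    master_seed: int = 0
    ci: str = "normal"
    threshold: float = 0.1
    out: str | None = None

    def __post_init__(self):
        if not self.H or not all(0.0 < h < 1.0 for h in self.H):
            raise ValueError("H axis must be nonempty with every value in (0, 1)")
        if not self.N or not all(n >= 16 for n in self.N):
            raise ValueError("N axis must be nonempty with every length >= 16")
        if not self.A or not all(0.0 <= a <= 1.0 for a in self.A):
            raise ValueError("A axis must be nonempty with every amplitude in [0, 1]")
        for token in self.kinds:
            parse_kind_token(token)  # raises on malformed tokens
        if not self.estimators or any(e not in ESTIMATORS for e in self.estimators):
            raise ValueError(f"estimators must be drawn from {ESTIMATORS}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.ci not in ("normal", "percentile"):
            raise ValueError("ci must be 'normal' or 'percentile'")
        if self.threshold <= 0.0:
            raise ValueError("threshold must be positive")

    def n_cells(self) -> int:
        return len(self.H) * len(self.N) * len(self.A) * len(self.kinds) * len(self.estimators)


def _as_list(v):
    if isinstance(v, str):
        return [s.strip() for s in v.split(",") if s.strip()]
    if isinstance(v, (list, tuple)):
        return list(v)
    return [v]


_CONFIG_KEYS = {"H", "N", "A", "kinds", "estimators", "n_reps", "master_seed", "ci", "threshold", "out"}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a flat mapping or a YAML file path.

    Axes (H, N, A, kinds, estimators) accept YAML lists or comma-separated
    strings.  Unknown keys raise before any computation.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(source) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"H", "N", "A", "kinds", "estimators"} - set(source)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    kwargs = dict(
        H=tuple(float(v) for v in _as_list(source["H"])),
        N=tuple(int(v) for v in _as_list(source["N"])),
        A=tuple(float(v) for v in _as_list(source["A"])),
        kinds=tuple(str(v) for v in _as_list(source["kinds"])),
        estimators=tuple(str(v).upper() for v in _as_list(source["estimators"])),
    )
    for key in ("n_reps", "master_seed"):
        if key in source:
            kwargs[key] = int(source[key])
    if "ci" in source:
        kwargs["ci"] = str(source["ci"])
    if "threshold" in source:
        kwargs["threshold"] = float(source["threshold"])
    if "out" in source and source["out"] is not None:
        kwargs["out"] = str(source["out"])
    return RunConfig(**kwargs)


def _row_key(row: dict) -> tuple:
    return (
        str(row["estimator"]),
        str(row["contaminant"]),
        f"{float(row['H_true']):.10g}",
        int(row["N"]),
        f"{float(row['A']):.10g}",
        f"{float(row['tau']):.10g}",
        int(row["sign"]),
    )


def run_grid(config: RunConfig | dict, out_path=None, progress=None) -> pd.DataFrame:
    """Run the full grid and return one summary row per cell.

    Cell order is kinds x H x N x A x estimators.  If ``out_path`` (or
    ``config.out``) is given, rows are appended to that CSV as they complete
    and cells already present in the file are skipped, so an interrupted run
    resumes where it stopped.  ``progress`` may be a callable taking
    ``(i, total, row)``.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    out_path = out_path or config.out
    done: dict[tuple, dict] = {}
    if out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path)
        for row in existing.to_dict("records"):
            done[_row_key(row)] = row

    rows = []
    total = config.n_cells()
    i = 0
    for token in config.kinds:
        template = parse_kind_token(token)
        for H in config.H:
            for n in config.N:
                for A in config.A:
                    spec = replace(template, A=A)
                    for estimator in config.estimators:
                        i += 1
                        key = (
                            estimator, spec.kind, f"{H:.10g}", int(n), f"{A:.10g}",
                            f"{(spec.tau if spec.kind == 'cyclical' else 0.0):.10g}",
                            int(spec.sign if spec.kind in ('linear', 'quadratic') else 0),
                        )
                        if key in done:
                            rows.append(done[key])
                            continue
                        cell = run_cell(
                            estimator, H, n, spec, config.n_reps, config.master_seed, config.ci
                        )
                        row = cell.to_row()
                        rows.append(row)
                        if out_path is not None:
                            header = not Path(out_path).exists()
                            pd.DataFrame([row], columns=RESULT_COLUMNS).to_csv(
                                out_path, mode="a", header=header, index=False
                            )
                        if progress is not None:
                            progress(i, total, row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def decision_map(table: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Per-cell verdict: which estimator is accurate enough, if any.

    For every (contaminant, tau, sign, H, N, A) cell the best estimator is
    the one minimizing ``|mean_hhat - H_true|``; ties break in the preference
    order HK > DFA1 > DFA2.  If the minimum exceeds ``threshold`` (or every
    estimator failed) the verdict is ``none``.  All three estimators must be
    present for every cell.
    """
    required = {"estimator", "contaminant", "H_true", "N", "A", "tau", "sign", "mean_hhat"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"results table lacks columns: {sorted(missing_cols)}")
    out_rows = []
    group_cols = ["contaminant", "tau", "sign", "H_true", "N", "A"]
    for cell_id, group in table.groupby(group_cols, sort=False):
        present = set(group["estimator"])
        missing = set(ESTIMATORS) - present
        if missing:
            raise ValueError(
                f"incomplete cell {dict(zip(group_cols, cell_id))}: missing estimators {sorted(missing)}"
            )
        errors = {}
        for _, row in group.iterrows():
            err = abs(row["mean_hhat"] - row["H_true"])
            errors[row["estimator"]] = err if np.isfinite(err) else np.inf
        best = "none"
        best_err = np.inf
        for est in ESTIMATORS:  # preference order; strict < keeps earlier on ties
            if errors[est] < best_err:
                best_err = errors[est]
                best = est
        if best_err > threshold:
            best = "none"
        out_rows.append(
            dict(zip(group_cols, cell_id))
            | {"best": best, "min_abs_error": best_err if np.isfinite(best_err) else np.nan}
        )
    return pd.DataFrame(out_rows, columns=DECISION_COLUMNS)
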