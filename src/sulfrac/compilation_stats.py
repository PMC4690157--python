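"""Meta-analysis utilities for compiled fractionation observations.

Two jobs:

* class-wise distribution summaries (box-whisker style quantiles) of
  compiled reactant-product 34-epsilon observations from whole-cell and
  cell-free sulfate/sulfite reduction experiments, and
* the one-phase exponential decay regression of fractionation against
  sulfate-reduction rate::

      Y(X) = (Y0 - Plateau) * exp(-K * X) + Plateau

  which captures the empirical pattern that fractionation falls from a
  low-rate ceiling (Y0) to a high-rate floor (Plateau) as volumetric
  reduction rate X grows.

Quantiles use linear interpolation (type-7) for reproducibility.  The
decay fit is plain nonlinear least squares with multi-start initialisation
of K over a log-spaced grid, since realistic decay constants span orders
of magnitude; 95% confidence intervals come from the covariance of the
fit via the t distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("sulfrac")

__all__ = [
    "EXPERIMENT_TYPES",
    "SUBSTRATES",
    "DecayFit",
    "one_phase_decay",
    "summarize",
    "fit_decay",
    "rescale_rates",
]

EXPERIMENT_TYPES = ("batch", "chemostat", "resting", "cell-free")
SUBSTRATES = ("sulfate->sulfide", "sulfite->sulfide", "sulfate->sulfite")

_QUANTILE_COLS = ["min", "q25", "median", "q75", "max", "mean", "n"]


def summarize(records: pd.DataFrame, by=("experiment_type",),
              value_col: str = "eps34_r_p") -> pd.DataFrame:
    """Quantile table (min, 25%, median, 75%, max, mean, n) per group plus
    a grand 'all' row; empty groups are omitted with a log entry."""
    if value_col not in records.columns:
        raise ValueError(f"records lack value column {value_col!r}")
    by = list(by)
    rows = []

    def stats_of(vals: np.ndarray) -> dict:
        return {
            "min": float(np.min(vals)),
            "q25": float(np.quantile(vals, 0.25)),
            "median": float(np.quantile(vals, 0.5)),
            "q75": float(np.quantile(vals, 0.75)),
            "max": float(np.max(vals)),
            "mean": float(np.mean(vals)),
            "n": int(len(vals)),
        }

    for key, grp in records.groupby(by, sort=True, dropna=False):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            logger.info("summarize: empty group %s omitted", key)
            continue
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(stats_of(vals))
        rows.append(row)
    allvals = records[value_col].dropna().to_numpy(dtype=float)
    if len(allvals):
        grand = {k: "all" for k in by}
        grand.update(stats_of(allvals))
        rows.append(grand)
    return pd.DataFrame(rows, columns=by + _QUANTILE_COLS)


def one_phase_decay(x, y0: float, plateau: float, k: float):
    """Y = (Y0 - Plateau) * exp(-K X) + Plateau."""
    return (y0 - plateau) * np.exp(-k * np.asarray(x, dtype=float)) + plateau


@dataclass
class DecayFit:
    """Fitted one-phase decay parameters with 95% CIs and diagnostics."""

    y0: float
    plateau: float
    k: float
    ci95: dict
    rss: float
    n: int
    k_identifiable: bool = True

    def predict(self, x):
        return one_phase_decay(x, self.y0, self.plateau, self.k)


def fit_decay(x, y, n_starts: int = 13) -> DecayFit:
    """Nonlinear least squares of the one-phase decay with multi-start K.

    K starts are log-spaced over [1e-3, 1e3] scaled by the span of x, so
    both slow and fast decays are found without a user guess.  Constant y
    degenerates to Y0 = Plateau = mean with K flagged unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 points to fit a 3-parameter decay")
    if np.any(x < 0):
        raise ValueError("rates must be >= 0")

    if np.ptp(y) == 0.0:
        c = float(y[0])
        return DecayFit(y0=c, plateau=c, k=0.0,
                        ci95={"y0": (c, c), "plateau": (c, c), "k": (0.0, math.inf)},
                        rss=0.0, n=len(x), k_identifiable=False)

    x_span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    order = np.argsort(x)
    y0_init = float(y[order[0]])
    plateau_init = float(y[order[-1]])
    best = None
    failures = []
    for k_init in np.geomspace(1e-3, 1e3, n_starts) / x_span:
        try:
            popt, pcov = optimize.curve_fit(
                one_phase_decay, x, y,
                p0=[y0_init, plateau_init, k_init],
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            failures.append(str(exc))
            continue
        rss = float(np.sum((y - one_phase_decay(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError(
            "one-phase decay fit failed from every start; messages: "
            + "; ".join(sorted(set(failures)))
        )
    popt, pcov, rss = best
    dof = max(1, len(x) - 3)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    names = ("y0", "plateau", "k")
    ci = {nm: (float(p - tval * s), float(p + tval * s))
          for nm, p, s in zip(names, popt, se)}
    return DecayFit(y0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
                    ci95=ci, rss=rss, n=len(x))


def rescale_rates(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Deterministic rate-unit transformations with a provenance column.

    mode="linearize_log10"
        rows whose ``rate_unit`` starts with ``log10_`` are mapped through
        10**value; already-linear rows pass through unchanged (idempotent).
    mode="volumetric_from_cell_specific"
        rows with a cell-specific unit (containing ``/cell``) are
        multiplied by ``n_cells_per_mL``; rows lacking a cell count are
        skipped with a log entry.
    """
    out = records.copy()
    if "rate_rescaled_from" not in out.columns:
        out["rate_rescaled_from"] = ""
    if mode == "linearize_log10":
        for idx, row in out.iterrows():
            unit = str(row["rate_unit"])
            if unit.startswith("log10_"):
                out.at[idx, "rate_value"] = 10.0 ** float(row["rate_value"])
                out.at[idx, "rate_unit"] = unit[len("log10_"):]
                out.at[idx, "rate_rescaled_from"] = unit
    elif mode == "volumetric_from_cell_specific":
        drop = []
        for idx, row in out.iterrows():
            unit = str(row["rate_unit"])
            if "/cell" not in unit:
                continue
            n_cells = row.get("n_cells_per_mL", np.nan)
            if pd.isna(n_cells):
                logger.info("rescale_rates: record %s lacks n_cells_per_mL; skipped",
                            row.get("study", idx))
                drop.append(idx)
                continue
            out.at[idx, "rate_value"] = float(row["rate_value"]) * float(n_cells)
            out.at[idx, "rate_unit"] = unit.replace("/cell", "/mL")
            out.at[idx, "rate_rescaled_from"] = unit
        out = out.drop(index=drop)
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    return out
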