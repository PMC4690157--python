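"""Per-point inversion of branched closed-system distillation data.

Given measured concentrations (which fix the reaction progress ``f`` and
the product split ``j``) and the deltas of residual sulfite, pooled
sulfonate and pooled reduced S, each time point is inverted for the net and
branch-specific fractionation factors, per isotope::

    R_p       = w_red * R_red + w_ox * R_ox          (atom-weighted product ratio)
    a_total   = ln((R_p / R_a0) * (f - 1) + 1) / ln(f)
    a_z       = (R_z / R_a0) * a_total * (f - 1) / (f**a_total - 1),  z in {red, ox}
    lam3x_z   = ln(a3x_z) / ln(a34_z)

The branch equation is the unique algebra consistent with the net mass
balance and with cumulative-product Rayleigh theory; applied to output of
:mod:`sulfrac.forward_model` it recovers the generating parameters to
machine precision, which is the module's central test.

Because the branch fractionations drift once the reaction has consumed a
substantial fraction of the sulfite (secondary reduction of sulfonate
becomes plausible), summary estimates are computed on an early-reaction
window, by default f >= 0.85, while the full-f per-point table is always
reported so the drift diagnostic stays visible.

Error model per point (1-sigma), assembled from :mod:`sulfrac.uncertainty`
and split into an *independent* part (per-point measurements) and a
*shared* part (the t0 sulfite measurement common to every point of a
series).  Window summaries are inverse-variance-weighted means whose
variance counts the independent parts as averaging down and the shared
part as fully correlated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cli_io import ExperimentSeries, TimePoint, series_to_timepoints
from .isotope_core import (
    VCDT,
    DeltaTriple,
    FractionationTriple,
    ReferenceScale,
    delta_to_ratio,
)
from .uncertainty import ErrorInputs, lambda_partials, sigma_lambda

logger = logging.getLogger("sulfrac")

__all__ = [
    "PointInversion",
    "WindowSummary",
    "InversionResult",
    "SecondaryReactionScan",
    "NumericallyInvalidPoint",
    "EmptyWindowError",
    "invert_point",
    "invert_series",
    "invert_experiment_frame",
    "pool_windows",
    "scan_secondary",
]

_BRANCH_FIELDS = ("eps34_red", "eps34_ox", "lam33_red", "lam33_ox", "lam36_red", "lam36_ox")


class NumericallyInvalidPoint(ValueError):
    """The measured ratios/concentrations admit no real fractionation factor."""


class EmptyWindowError(ValueError):
    """No valid points at or above the window threshold."""


@dataclass
class PointInversion:
    """Inversion output of a single time point."""

    f: float
    j: float
    w_red: float
    w_ox: float
    time_h: float
    r_p: dict
    alpha_total: FractionationTriple
    alpha_red: FractionationTriple
    alpha_ox: FractionationTriple
    eps34_red: float
    eps34_ox: float
    lam33_red: float | None = None
    lam33_ox: float | None = None
    lam36_red: float | None = None
    lam36_ox: float | None = None
    # 1-sigma decomposition: {field: (sigma_independent, sigma_shared)}
    sigmas: dict = field(default_factory=dict)

    def sigma_total(self, name: str) -> float | None:
        pair = self.sigmas.get(name)
        if pair is None:
            return None
        return math.hypot(*pair)


@dataclass
class WindowSummary:
    """Weighted early-window summary of one or more inverted series."""

    f_threshold: float
    n_points: int
    f_used: tuple
    eps34_red: float = math.nan
    eps34_ox: float = math.nan
    lam33_red: float | None = None
    lam33_ox: float | None = None
    lam36_red: float | None = None
    lam36_ox: float | None = None
    sigma_eps34_red: float = math.nan
    sigma_eps34_ox: float = math.nan
    sigma_lam33_red: float | None = None
    sigma_lam33_ox: float | None = None
    sigma_lam36_red: float | None = None
    sigma_lam36_ox: float | None = None

    def report(self) -> dict:
        """Public 2-sigma report."""
        out = {"f_threshold": self.f_threshold, "n_points": self.n_points}
        for name in _BRANCH_FIELDS:
            v = getattr(self, name)
            s = getattr(self, f"sigma_{name}")
            if v is None:
                continue
            out[name] = v
            out[f"{name}_2sigma"] = None if s is None else 2.0 * s
        return out


@dataclass
class InversionResult:
    """Per-point table plus windowed summary for one experiment series."""

    points: list
    window: WindowSummary
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {
                "f": p.f, "j": p.j, "time_h": p.time_h,
                "eps34_red": p.eps34_red, "eps34_ox": p.eps34_ox,
                "lam33_red": p.lam33_red, "lam33_ox": p.lam33_ox,
                "lam36_red": p.lam36_red, "lam36_ox": p.lam36_ox,
            }
            for name in _BRANCH_FIELDS:
                row[f"sigma_{name}"] = p.sigma_total(name)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class MultiSeriesResult:
    """Inversions of every (experiment, replicate) series plus the pooled
    window summary (per-experiment inversion first, pooling second)."""

    per_series: dict
    pooled: WindowSummary


def _branch_alpha(r_z: float, r_a0: float, f: float, a_total: float) -> float:
    num = math.expm1(a_total * math.log(f))  # f**a_total - 1
    return (r_z / r_a0) * a_total * (f - 1.0) / num


def invert_point(tp: TimePoint, initial: DeltaTriple,
                 initial_sulfite_mM: float, f: float | None = None,
                 err: ErrorInputs = ErrorInputs(),
                 scale: ReferenceScale = VCDT) -> PointInversion:
    """Invert one time point for net and branch fractionation factors.

    ``f`` defaults to measured sulfite over the t0 value; pass it
    explicitly to use a product-accumulation estimate instead.
    """
    if initial is None:
        raise NumericallyInvalidPoint("initial sulfite delta missing")
    if tp.delta_reduced is None or tp.delta_sulfonate is None:
        raise NumericallyInvalidPoint("product pool deltas missing")
    if f is None:
        f = tp.conc_sulfite_mM / initial_sulfite_mM
    prod_s = 2.0 * tp.conc_thiosulfate_mM + 3.0 * tp.conc_trithionate_mM
    if f >= 1.0 or prod_s <= 0.0:
        raise NumericallyInvalidPoint(f"no product accumulated (f={f:.4f})")
    if f <= 0.0:
        raise NumericallyInvalidPoint(f"non-positive f={f:.4f}")

    j = 2.0 * tp.conc_thiosulfate_mM / prod_s
    w_red = j / 2.0 + (1.0 - j) / 3.0
    w_ox = 1.0 - w_red

    r_a0 = delta_to_ratio(initial, scale)
    r_red = delta_to_ratio(tp.delta_reduced, scale)
    r_ox = delta_to_ratio(tp.delta_sulfonate, scale)

    lnf = math.log(f)
    a_tot: dict[str, float | None] = {}
    a_red: dict[str, float | None] = {}
    a_ox: dict[str, float | None] = {}
    r_p: dict[str, float | None] = {}
    for iso in ("33", "34", "36"):
        r0x = getattr(r_a0, f"r{iso}")
        rrx = getattr(r_red, f"r{iso}")
        rox = getattr(r_ox, f"r{iso}")
        if r0x is None or rrx is None or rox is None:
            a_tot[iso] = a_red[iso] = a_ox[iso] = r_p[iso] = None
            continue
        rp = w_red * rrx + w_ox * rox
        arg = (rp / r0x) * (f - 1.0)
        if arg <= -1.0:
            raise NumericallyInvalidPoint(
                f"isotope {iso}: R_p(f-1)/R_a0 + 1 = {arg + 1.0:.3e} <= 0"
            )
        at = math.log1p(arg) / lnf
        r_p[iso] = rp
        a_tot[iso] = at
        a_red[iso] = _branch_alpha(rrx, r0x, f, at)
        a_ox[iso] = _branch_alpha(rox, r0x, f, at)

    def lam(a3x: float | None, a34: float) -> float | None:
        if a3x is None or a34 == 1.0:
            return None
        la = math.log(a34)
        return math.log(a3x) / la if la != 0.0 else None

    eps_red = 1000.0 * (1.0 / a_red["34"] - 1.0)
    eps_ox = 1000.0 * (1.0 / a_ox["34"] - 1.0)

    pi = PointInversion(
        f=f, j=j, w_red=w_red, w_ox=w_ox, time_h=tp.time_h,
        r_p=r_p,
        alpha_total=FractionationTriple(a34=a_tot["34"], a33=a_tot["33"], a36=a_tot["36"]),
        alpha_red=FractionationTriple(a34=a_red["34"], a33=a_red["33"], a36=a_red["36"]),
        alpha_ox=FractionationTriple(a34=a_ox["34"], a33=a_ox["33"], a36=a_ox["36"]),
        eps34_red=eps_red,
        eps34_ox=eps_ox,
        lam33_red=lam(a_red["33"], a_red["34"]),
        lam33_ox=lam(a_ox["33"], a_ox["34"]),
        lam36_red=lam(a_red["36"], a_red["34"]),
        lam36_ox=lam(a_ox["36"], a_ox["34"]),
    )
    pi.sigmas = _point_sigmas(pi, f, err, scale)
    return pi


def _point_sigmas(pi: PointInversion, f: float, err: ErrorInputs,
                  scale: ReferenceScale) -> dict:
    """1-sigma (independent, shared) decomposition per reported quantity.

    epsilon: the Rayleigh power-law propagation of (sigma_f, sigma_R),
    once with the per-point measurement errors (independent) and once with
    the t0 measurement errors (shared).

    lambda: the (delta34, Delta33) error formula evaluated at the branch's
    own separation; the capital-delta scatter of the pool is independent,
    that of the t0 reference is shared across the series (it enters every
    point with the same sign and magnitude).
    """
    sig: dict[str, tuple[float, float]] = {}
    for branch, a in (("red", pi.alpha_red), ("ox", pi.alpha_ox)):
        x = abs(a.a34 - 1.0)
        s_f = 1000.0 * x * err.sigma_f_rel
        s_r = 1000.0 * err.sigma_R_rel
        s_eps = math.hypot(s_f, s_r)
        sig[f"eps34_{branch}"] = (s_eps, s_eps)

        for iso, lam_name, lam_rfl, s_D in (
            ("33", f"lam33_{branch}", scale.lambda33_rfl, err.sigma_D33),
            ("36", f"lam36_{branch}", scale.lambda36_rfl, err.sigma_D36),
        ):
            lam_v = getattr(pi, lam_name)
            a3x = getattr(a, f"a{iso}")
            if lam_v is None or a3x is None:
                continue
            d34_sep = 1000.0 * (a.a34 - 1.0)
            if d34_sep == 0.0:
                continue
            cap_sep = 1000.0 * (a3x - a.a34 ** lam_rfl)
            le = sigma_lambda(d34_sep, cap_sep, sigma_d34=s_eps, sigma_D33=s_D,
                              lambda_rfl=lam_rfl)
            dD33, _ = lambda_partials(d34_sep, cap_sep, lam_rfl)
            sig[lam_name] = (le.sigma, abs(dD33) * s_D)
    return sig


def invert_series(series, f_threshold: float = 0.85, weighting: str = "ivw",
                  err: ErrorInputs = ErrorInputs(),
                  scale: ReferenceScale = VCDT,
                  f_from: str = "sulfite") -> InversionResult:
    """Invert every valid point of one series and summarise the early
    window (f >= threshold).

    ``series`` is an :class:`ExperimentSeries` or a schema DataFrame whose
    first row is t0.  Invalid points are skipped with a logged reason, and
    an :class:`EmptyWindowError` is raised when nothing survives above the
    threshold.
    """
    if isinstance(series, pd.DataFrame):
        series = ExperimentSeries(experiment_id="anon", replicate=1,
                                  frame=series.reset_index(drop=True))
    c0 = series.initial_sulfite_mM
    initial = series.initial_delta
    points: list[PointInversion] = []
    skipped: list[tuple[float, str]] = []
    for tp in series_to_timepoints(series):
        f = None
        if f_from == "products":
            f = 1.0 - (2.0 * tp.conc_thiosulfate_mM + 3.0 * tp.conc_trithionate_mM) / c0
        try:
            points.append(invert_point(tp, initial, c0, f=f, err=err, scale=scale))
        except NumericallyInvalidPoint as exc:
            skipped.append((tp.time_h, str(exc)))
            logger.info("series (%s, %s): point at t=%s h skipped: %s",
                        series.experiment_id, series.replicate, tp.time_h, exc)
    window = summarize_window(points, f_threshold, weighting)
    return InversionResult(points=points, window=window, skipped=skipped)


def _combine(values, sig_pairs, weighting):
    """Weighted mean with independent/shared variance bookkeeping."""
    v = np.asarray(values, dtype=float)
    si = np.asarray([s[0] for s in sig_pairs], dtype=float)
    ss = np.asarray([s[1] for s in sig_pairs], dtype=float)
    if weighting == "ivw" and np.all((si**2 + ss**2) > 0):
        w = 1.0 / (si**2 + ss**2)
    else:
        w = np.ones_like(v)
    w = w / w.sum()
    mean = float(np.sum(w * v))
    var = float(np.sum(w**2 * si**2) + np.sum(w * ss) ** 2)
    return mean, math.sqrt(var)


def summarize_window(points: list, f_threshold: float,
                     weighting: str = "ivw") -> WindowSummary:
    """Inverse-variance-weighted summary of points with f >= threshold."""
    used = [p for p in points if p.f >= f_threshold]
    if not used:
        raise EmptyWindowError(
            f"no valid points with f >= {f_threshold} (had {len(points)} inverted points)"
        )
    ws = WindowSummary(f_threshold=f_threshold, n_points=len(used),
                       f_used=tuple(p.f for p in used))
    for name in _BRANCH_FIELDS:
        vals, sigs = [], []
        for p in used:
            v = getattr(p, name)
            s = p.sigmas.get(name)
            if v is None or s is None:
                continue
            vals.append(v)
            sigs.append(s)
        if not vals:
            continue
        mean, sigma = _combine(vals, sigs, weighting)
        setattr(ws, name, mean)
        setattr(ws, f"sigma_{name}", sigma)
    return ws


def pool_windows(windows: list[WindowSummary]) -> WindowSummary:
    """Pool the window summaries of replicate experiments.

    Replicates carry independent t0 measurements, so their window sigmas
    are treated as independent and combined by inverse variance.
    """
    if not windows:
        raise EmptyWindowError("no windows to pool")
    if len(windows) == 1:
        return replace(windows[0])
    out = WindowSummary(
        f_threshold=windows[0].f_threshold,
        n_points=sum(w.n_points for w in windows),
        f_used=tuple(f for w in windows for f in w.f_used),
    )
    for name in _BRANCH_FIELDS:
        vals = [getattr(w, name) for w in windows]
        sigs = [getattr(w, f"sigma_{name}") for w in windows]
        pairs = [(v, s) for v, s in zip(vals, sigs) if v is not None and s is not None
                 and not (isinstance(v, float) and math.isnan(v))]
        if not pairs:
            continue
        v = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        if np.all(s > 0):
            w_ = 1.0 / s**2
        else:
            w_ = np.ones_like(v)
        w_ = w_ / w_.sum()
        setattr(out, name, float(np.sum(w_ * v)))
        setattr(out, f"sigma_{name}", float(math.sqrt(np.sum(w_**2 * s**2))))
    return out


def invert_experiment_frame(frame: pd.DataFrame, f_threshold: float = 0.85,
                            weighting: str = "ivw",
                            err: ErrorInputs = ErrorInputs(),
                            scale: ReferenceScale = VCDT) -> MultiSeriesResult:
    """Invert every (experiment_id, replicate) series in a schema frame and
    pool the resulting windows (per-experiment inversion, then pooling)."""
    per: dict[tuple[str, int], InversionResult] = {}
    for (exp, rep), grp in frame.groupby(["experiment_id", "replicate"], sort=False):
        series = ExperimentSeries(experiment_id=str(exp), replicate=int(rep),
                                  frame=grp.sort_values("time_h").reset_index(drop=True))
        per[(str(exp), int(rep))] = invert_series(
            series, f_threshold=f_threshold, weighting=weighting, err=err, scale=scale
        )
    pooled = pool_windows([r.window for r in per.values()])
    return MultiSeriesResult(per_series=per, pooled=pooled)


@dataclass
class SecondaryReactionScan:
    """Constraint curve alpha_unk(X_SO3) for a possible sulfonate -> reduced
    secondary reaction; not a unique solution."""

    x_grid: np.ndarray
    alpha_unk: np.ndarray
    unphysical: np.ndarray
    alpha_red_ref: float


def scan_secondary(alpha_red_ref: float, r_red: float, r_so3: float, r_ox: float,
                   x_grid=None) -> SecondaryReactionScan:
    """Solve ``R_red = X*a_red_ref*R_SO3 + (1-X)*a_unk*R_ox`` for a_unk over
    a grid of X (the fraction of reduced S formed directly from sulfite).

    The relation degenerates at X = 1, so the grid must exclude it; points
    where the implied a_unk is non-positive are flagged unphysical.
    """
    if x_grid is None:
        x_grid = np.linspace(0.01, 0.99, 99)
    x = np.asarray(x_grid, dtype=float)
    if np.any(x >= 1.0) or np.any(x <= 0.0):
        raise ValueError("X_SO3 grid must lie strictly inside (0, 1)")
    denom = (1.0 - x) * r_ox
    a_unk = (r_red - x * alpha_red_ref * r_so3) / denom
    return SecondaryReactionScan(
        x_grid=x, alpha_unk=a_unk, unphysical=a_unk <= 0.0,
        alpha_red_ref=alpha_red_ref,
    )
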