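"""Synthetic experiment tables with the statistical structure of the in
vitro sulfite-reduction measurements.

The generator wraps the deterministic forward model with the measured
noise structure of the real experiments:

* 3% relative (truncated) Gaussian noise on every concentration,
* 0.2 permil Gaussian noise on each delta-34 measurement,
* delta-33 tied mass-dependently to the *perturbed* delta-34 plus a small
  independent scatter on Delta33 (0.008 permil) — the correlated-error
  mode, reflecting that delta-33 and delta-34 measurement errors of an
  SF6 analysis are highly correlated; an uncorrelated mode (0.1 permil raw
  delta-33 noise) exists for sensitivity studies,
* duplicate experiments sharing the truth but not the noise,
* 10 or 15 mM initial sulfite and a constant product split j = 0.19.

The default truth is the reduced-branch/sulfonate-branch parameter set
inferred for the D. vulgaris enzyme (reactant-product epsilons of +15.3
and -3.2 permil, mass-law exponents 0.5150 and 0.495), so a default
generate -> invert round trip exercises the pipeline at realistic values.

Everything is driven by one integer seed; the same seed yields
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forward_model import BranchFractionation, ReactionScheme, simulate
from .isotope_core import VCDT, DeltaTriple, ReferenceScale, epsilon_to_alpha
from .cli_io import COMPILATION_COLUMNS, EXPERIMENT_COLUMNS

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "DEFAULT_TRUTH",
    "DEFAULT_SCHEME",
    "generate",
    "generate_compilation",
]

# Reference truth for the default design: the reduced branch depletes the
# product by 15.3 permil (reactant-product convention) with mass-law
# exponent 0.5150; the sulfonate branch enriches by 3.2 permil with an
# early-window exponent of 0.495.
DEFAULT_TRUTH = BranchFractionation(
    a34_red=epsilon_to_alpha(15.3, "reactant-product"),
    a34_ox=epsilon_to_alpha(-3.2, "reactant-product"),
    lam33_red=0.5150,
    lam33_ox=0.495,
    lam36_red=1.90,
    lam36_ox=1.90,
)
DEFAULT_SCHEME = ReactionScheme(j=0.19)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise structure of the experiment tables (all 1-sigma)."""

    cv_conc: float = 0.03
    sd_d34: float = 0.2
    sd_D33: float = 0.008
    sd_D36: float = 0.15
    sd_d33_raw: float = 0.1
    correlated: bool = True

    def __post_init__(self) -> None:
        for name in ("cv_conc", "sd_d34", "sd_D33", "sd_D36", "sd_d33_raw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(cv_conc=0.0, sd_d34=0.0, sd_D33=0.0, sd_D36=0.0, sd_d33_raw=0.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic experiment set."""

    initial_sulfite_mM: float = 15.0
    n_replicates: int = 2
    f_grid: tuple = tuple(np.round(np.arange(0.99, 0.599, -0.03), 10))
    truth: BranchFractionation = DEFAULT_TRUTH
    scheme: ReactionScheme = DEFAULT_SCHEME
    delta0: DeltaTriple = field(default_factory=lambda: DeltaTriple(d34=0.0, d33=0.0, d36=0.0))
    temperature_C: float = 20.0
    enzyme: str = "DsrAB"
    experiment_id: str = "synthetic"
    j_drift_per_f: float = 0.0  # robustness hook; 0 = constant j, as observed

    def __post_init__(self) -> None:
        f = np.asarray(self.f_grid, dtype=float)
        if len(f) == 0 or np.any(f <= 0.0) or np.any(f > 1.0):
            raise ValueError("f_grid must lie in (0, 1]")
        if np.any(np.diff(f) >= 0):
            raise ValueError("f_grid must be strictly descending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _mult_noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative 1 + N(0, cv) truncated at +/-3 sigma (keeps
    concentrations positive for any cv <= 0.33)."""
    if cv == 0.0:
        return np.ones(n)
    draws = stats.truncnorm.rvs(-3.0, 3.0, size=n, random_state=rng)
    return 1.0 + cv * draws


def _mass_dependent_d3x(d34: np.ndarray, cap: np.ndarray, lam_rfl: float) -> np.ndarray:
    return 1000.0 * ((1.0 + d34 / 1000.0) ** lam_rfl - 1.0) + cap


def _cap_of(d3x: np.ndarray, d34: np.ndarray, lam_rfl: float) -> np.ndarray:
    return d3x - 1000.0 * ((1.0 + d34 / 1000.0) ** lam_rfl - 1.0)


def generate(design: ExperimentDesign, noise: NoiseModel,
             seed: int, scale: ReferenceScale = VCDT) -> pd.DataFrame:
    """Emit a schema-conformant experiment table for ``design`` under
    ``noise``; replicates share the truth and differ only in noise."""
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, design.n_replicates + 1):
        scheme = design.scheme
        traj = simulate(design.truth, scheme, design.initial_sulfite_mM,
                        design.delta0, np.asarray(design.f_grid), scale)
        frame = traj.to_frame(experiment_id=design.experiment_id, replicate=rep,
                              enzyme=design.enzyme, temperature_C=design.temperature_C)
        if design.j_drift_per_f != 0.0:
            frame = _apply_j_drift(frame, design)
        frame = _apply_noise(frame, noise, rng, scale)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[EXPERIMENT_COLUMNS]


def _apply_j_drift(frame: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Robustness hook: let the apparent product split drift linearly in
    (1 - f) by re-splitting the consumed S between thiosulfate and
    trithionate.  The isotope pools keep the constant-j truth, so this
    deliberately mis-specifies the model for stress tests."""
    frame = frame.copy()
    c0 = float(frame.iloc[0]["conc_sulfite_mM"])
    consumed = c0 - frame["conc_sulfite_mM"].to_numpy(dtype=float)
    f = frame["conc_sulfite_mM"].to_numpy(dtype=float) / c0
    j_eff = np.clip(design.scheme.j + design.j_drift_per_f * (1.0 - f), 0.0, 1.0)
    frame["conc_thiosulfate_mM"] = j_eff * consumed / 2.0
    frame["conc_trithionate_mM"] = (1.0 - j_eff) * consumed / 3.0
    return frame


def _apply_noise(frame: pd.DataFrame, noise: NoiseModel,
                 rng: np.random.Generator, scale: ReferenceScale) -> pd.DataFrame:
    frame = frame.copy()
    n = len(frame)
    for col in ("conc_sulfite_mM", "conc_thiosulfate_mM", "conc_trithionate_mM"):
        frame[col] = frame[col].to_numpy(dtype=float) * _mult_noise(rng, n, noise.cv_conc)
    for pool in ("sulfite", "sulfonate", "reduced"):
        d34 = frame[f"d34_{pool}"].to_numpy(dtype=float)
        d33 = frame[f"d33_{pool}"].to_numpy(dtype=float)
        d36 = frame[f"d36_{pool}"].to_numpy(dtype=float)
        present = ~np.isnan(d34)
        d34_noisy = d34 + noise.sd_d34 * rng.standard_normal(n)
        if noise.correlated:
            cap33 = _cap_of(d33, d34, scale.lambda33_rfl)
            cap36 = _cap_of(d36, d34, scale.lambda36_rfl)
            d33_noisy = _mass_dependent_d3x(
                d34_noisy, cap33 + noise.sd_D33 * rng.standard_normal(n),
                scale.lambda33_rfl)
            d36_noisy = _mass_dependent_d3x(
                d34_noisy, cap36 + noise.sd_D36 * rng.standard_normal(n),
                scale.lambda36_rfl)
        else:
            d33_noisy = d33 + noise.sd_d33_raw * rng.standard_normal(n)
            d36_noisy = d36 + noise.sd_d33_raw * rng.standard_normal(n)
        frame[f"d34_{pool}"] = np.where(present, d34_noisy, np.nan)
        frame[f"d33_{pool}"] = np.where(~np.isnan(d33), d33_noisy, np.nan)
        frame[f"d36_{pool}"] = np.where(~np.isnan(d36), d36_noisy, np.nan)
    return frame


def generate_compilation(class_params: dict, seed: int) -> pd.DataFrame:
    """Synthetic literature-compilation table.

    ``class_params`` maps experiment class to a spec dict with keys
    ``n``, ``mean``, ``sd`` and optionally ``substrate``, ``rate_mean``,
    ``rate_sd``, ``rate_unit``, ``n_cells_per_mL``.  Epsilons are drawn
    normally per class; classes model the spread of whole-cell and
    cell-free fractionation observations, not any single dataset.
    """
    if not class_params:
        raise ValueError("class_params must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for cls in sorted(class_params):
        spec = class_params[cls]
        n = int(spec["n"])
        eps = spec["mean"] + spec.get("sd", 0.0) * rng.standard_normal(n)
        if spec.get("rate_mean") is not None:
            rate = np.abs(spec["rate_mean"] + spec.get("rate_sd", 0.0)
                          * rng.standard_normal(n))
        else:
            rate = np.full(n, np.nan)
        for i in range(n):
            rows.append({
                "study": f"{cls}-{i+1:03d}",
                "experiment_type": cls,
                "substrate": spec.get("substrate", "sulfate->sulfide"),
                "eps34_r_p": float(eps[i]),
                "rate_value": float(rate[i]),
                "rate_unit": spec.get("rate_unit", ""),
                "n_cells_per_mL": spec.get("n_cells_per_mL", np.nan),
            })
    return pd.DataFrame(rows, columns=COMPILATION_COLUMNS)
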