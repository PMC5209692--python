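"""Weighted least-squares parameter estimation.

The cost is built from weighted residuals

    res_i = (Mod_i - Obs_i) / error_i

with unit weights by default.  Minimization uses a Levenberg-Marquardt
iteration on log-transformed parameters, which enforces the (0, inf)
bounds of all rate/partition parameters without explicit constraints.
Standard errors come from the Jacobian-based covariance
``SSR/(n-p) * inv(J'J)`` evaluated at the optimum on the original
parameter scale, and p-values from a two-sided t-test with n-p degrees
of freedom.

The two-stage protocol mirrors the reference workflow: stage 1 fits the
absorption rate ``k_a`` and the rest-of-body partition coefficient
``Kp_re`` to a plasma series; stage 2 fixes those estimates and fits the
pericardial perfusion ``Q_pf`` and the pericardial-epicardial diffusion
clearance ``P`` to a heart-tissue series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .config import ConfigError, ModelConfig, build_model
from .physiology import PhysiologyError
from .simulate import SimulationError, run

__all__ = ["ObservedSeries", "FitResult", "FittingError",
           "weighted_residuals", "weighted_least_squares", "fit",
           "two_stage_protocol", "apply_parameters", "FITTABLE_PARAMETERS"]

VALID_VARIABLES = ("venous_plasma", "total_heart")


class FittingError(ValueError):
    """Raised for invalid observations or fitting setups."""


@dataclass(frozen=True)
class ObservedSeries:
    """Concentration observations: (time [h], value [mg/L], variable, error).

    ``variable`` identifies the model output the record belongs to
    (``venous_plasma`` or ``total_heart``); ``error`` is the residual
    weighting factor (default 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_h", "value", "variable"}
        missing = required - set(self.data.columns)
        if missing:
            raise FittingError(f"observed series missing columns: {missing}")
        if "error" not in self.data.columns:
            df = self.data.copy()
            df["error"] = 1.0
            object.__setattr__(self, "data", df)
        if len(self.data) == 0:
            raise FittingError("observed series is empty")
        if (self.data["time_h"] < 0).any():
            raise FittingError("observation times must be nonnegative")
        if (self.data["error"] <= 0).any():
            raise FittingError("error weights must be positive")
        unknown = set(self.data["variable"]) - set(VALID_VARIABLES)
        if unknown:
            raise FittingError(f"unknown observed variables: {unknown}")

    @classmethod
    def from_records(cls, records: Sequence[tuple], variable: str | None = None
                     ) -> "ObservedSeries":
        """Build from (time, value[, variable[, error]]) tuples."""
        rows = []
        for rec in records:
            t, v = rec[0], rec[1]
            var = rec[2] if len(rec) > 2 else variable
            err = rec[3] if len(rec) > 3 else 1.0
            rows.append({"time_h": t, "value": v, "variable": var,
                         "error": err})
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ObservedSeries":
        df = pd.read_csv(path, comment="#")
        return cls(df)

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, index=False)

    def subset(self, variable: str) -> "ObservedSeries":
        sub = self.data[self.data["variable"] == variable]
        if len(sub) == 0:
            raise FittingError(f"no observations for variable '{variable}'")
        return ObservedSeries(sub.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class FitResult:
    """Estimates and uncertainty for one least-squares stage."""

    names: tuple
    estimates: dict
    standard_errors: dict
    p_values: dict
    residuals: np.ndarray
    ssr: float
    converged: bool
    n_evaluations: int
    message: str = ""

    def __post_init__(self) -> None:
        if any(se < 0 for se in self.standard_errors.values()):
            raise FittingError("standard errors must be nonnegative")


def weighted_residuals(model_values: np.ndarray, observed: ObservedSeries
                       ) -> np.ndarray:
    """(Mod - Obs) / error, aligned record by record."""
    model_values = np.asarray(model_values, dtype=float)
    if model_values.shape[0] != len(observed):
        raise FittingError(
            f"model vector length {model_values.shape[0]} does not match "
            f"{len(observed)} observations")
    obs = observed.data["value"].to_numpy(dtype=float)
    err = observed.data["error"].to_numpy(dtype=float)
    return (model_values - obs) / err


# -- parameter plumbing ----------------------------------------------------

def _set_ka(c: ModelConfig, v: float) -> ModelConfig:
    return replace(c, drug=replace(c.drug, k_a=v))


def _set_kp_re(c: ModelConfig, v: float) -> ModelConfig:
    kp = dict(c.drug.kp)
    kp["rest"] = v
    return replace(c, drug=replace(c.drug, kp=kp))


def _set_q_pf(c: ModelConfig, v: float) -> ModelConfig:
    return replace(c, heart=replace(c.heart, Q_pf=v))


def _set_p(c: ModelConfig, v: float) -> ModelConfig:
    return replace(c, heart=replace(c.heart, P=v))


FITTABLE_PARAMETERS = {
    "k_a": _set_ka,
    "Kp_re": _set_kp_re,
    "Q_pf": _set_q_pf,
    "P": _set_p,
}


def apply_parameters(config: ModelConfig, values: Mapping[str, float]
                     ) -> ModelConfig:
    """Return a config with the named fittable parameters replaced."""
    for name, value in values.items():
        try:
            setter = FITTABLE_PARAMETERS[name]
        except KeyError:
            raise FittingError(
                f"unknown fittable parameter '{name}'; expected one of "
                f"{sorted(FITTABLE_PARAMETERS)}") from None
        config = setter(config, value)
    return config


def _model_at_observations(config: ModelConfig, observed: ObservedSeries,
                           rtol: float, atol: float) -> np.ndarray:
    """Simulate and linearly interpolate the dense grid at the
    observation times, per observed variable."""
    t_obs_max = float(observed.data["time_h"].max())
    if t_obs_max > config.run.t_end:
        raise FittingError(
            f"observation at t={t_obs_max} h is outside the simulated "
            f"span 0-{config.run.t_end} h")
    params = build_model(config)
    result = run(params, config.dose_mg, t_end=config.run.t_end,
                 dt=config.run.dt, rtol=rtol, atol=atol)
    out = np.empty(len(observed))
    for variable in observed.data["variable"].unique():
        mask = (observed.data["variable"] == variable).to_numpy()
        t_obs = observed.data.loc[mask, "time_h"].to_numpy(dtype=float)
        out[mask] = np.interp(t_obs, result.time, result.series(variable))
    return out


@dataclass(frozen=True)
class _FitSettings:
    """Inner-loop numerical settings.

    ``diff_step`` (relative, on the log-parameter scale) is kept well
    above the integrator error so finite-difference Jacobians stay
    accurate; ``rtol``/``atol`` are the integration tolerances of the
    model evaluations inside the loop.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    xtol: float = 1e-8
    diff_step: float = 1e-4
    max_nfev: int = 200


def weighted_least_squares(predict, free: Mapping[str, float],
                           observed: ObservedSeries,
                           settings: _FitSettings = _FitSettings()
                           ) -> FitResult:
    """Minimize the weighted SSR of ``predict`` over positive parameters.

    ``predict`` maps a ``{name: value}`` dict to the model-value vector
    aligned with ``observed``.  Parameters are estimated on the log
    scale (an exact reparameterization of the (0, inf) box), and the
    reported covariance is transformed back to the original scale.
    """
    if len(free) == 0:
        raise FittingError("at least one free parameter is required")
    for name, start in free.items():
        if start <= 0:
            raise FittingError(f"start for {name} must be positive")

    names = tuple(free)
    theta0 = np.log([free[n] for n in names])

    def residuals_theta(theta: np.ndarray) -> np.ndarray:
        model = predict(dict(zip(names, np.exp(theta))))
        return weighted_residuals(model, observed)

    sol = least_squares(residuals_theta, theta0, method="lm",
                        xtol=settings.xtol, diff_step=settings.diff_step,
                        max_nfev=settings.max_nfev)
    estimates = dict(zip(names, np.exp(sol.x)))
    res = sol.fun
    ssr = float(np.sum(res ** 2))
    n, p = len(res), len(names)

    # covariance on the original scale: d res/d param = d res/d theta / param
    J = sol.jac / np.exp(sol.x)[np.newaxis, :]
    dof = max(n - p, 1)
    s2 = ssr / dof
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        warnings.warn("singular Jacobian: standard errors from the "
                      "pseudo-inverse are inflated", RuntimeWarning)
        cov = s2 * np.linalg.pinv(JtJ)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore"):
        t_stat = np.array([estimates[nm] for nm in names]) / np.where(
            se > 0, se, np.inf)
    p_values = 2.0 * stats.t.sf(np.abs(t_stat), dof)

    converged = bool(sol.status > 0)
    if not converged:
        warnings.warn(f"fit did not converge: {sol.message}", RuntimeWarning)
    return FitResult(
        names=names, estimates=estimates,
        standard_errors=dict(zip(names, se)),
        p_values=dict(zip(names, p_values)),
        residuals=res, ssr=ssr, converged=converged,
        n_evaluations=int(sol.nfev), message=str(sol.message),
    )


def fit(free: Mapping[str, float], config: ModelConfig,
        observed: ObservedSeries, fixed: Mapping[str, float] | None = None,
        settings: _FitSettings = _FitSettings()) -> FitResult:
    """Least-squares fit of named model parameters to observations.

    Parameters
    ----------
    free : mapping name -> starting value
        Parameters to estimate (all positive, bounds (0, inf)).
    config : ModelConfig
        Base configuration supplying everything not being fitted.
    observed : ObservedSeries
        Observations with weights.
    fixed : mapping, optional
        Named parameters to pin at given values before fitting.
    """
    for name in free:
        if name not in FITTABLE_PARAMETERS:
            raise FittingError(f"unknown fittable parameter '{name}'")
    if fixed:
        config = apply_parameters(config, fixed)

    def predict(values: Mapping[str, float]) -> np.ndarray:
        # infeasible probes (e.g. Q_pf above the heart blood flow) get a
        # large finite cost so the optimizer backs away instead of dying
        try:
            return _model_at_observations(apply_parameters(config, values),
                                          observed, settings.rtol,
                                          settings.atol)
        except (PhysiologyError, ConfigError, SimulationError):
            return np.full(len(observed), 1e6)

    return weighted_least_squares(predict, free, observed, settings)


def two_stage_protocol(plasma_obs: ObservedSeries, heart_obs: ObservedSeries,
                       config: ModelConfig,
                       stage1_starts: Mapping[str, float] | None = None,
                       stage2_starts: Mapping[str, float] | None = None,
                       settings: _FitSettings = _FitSettings(),
                       ) -> tuple[FitResult, FitResult]:
    """Sequential estimation of (k_a, Kp_re) then (Q_pf, P).

    Stage 1 fits absorption and rest-of-body partitioning to the plasma
    series with the pericardial parameters held at their stage-2 starting
    values (0.01 L/h and 0.40 L/h by default).  Stage 2 pins the stage-1
    estimates and fits the two pericardial parameters to the heart
    series.
    """
    plasma_obs = plasma_obs.subset("venous_plasma")
    heart_obs = heart_obs.subset("total_heart")
    if stage1_starts is None:
        stage1_starts = {"k_a": 1.0, "Kp_re": 30.0}
    if stage2_starts is None:
        stage2_starts = {"Q_pf": 0.01, "P": 0.40}

    stage1 = fit(stage1_starts, config, plasma_obs,
                 fixed=dict(stage2_starts), settings=settings)
    stage2 = fit(stage2_starts, config, heart_obs,
                 fixed=dict(stage1.estimates), settings=settings)
    return stage1, stage2
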