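"""Post-processing: surface warming, exponential fits, slices and studies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import Mesh
from .solver import T_AMBIENT


@dataclass
class TimeSeries:
    """Surface-warming trajectory: time (s), mean and max dT (K) over tissue."""

    t: np.ndarray
    dT_mean: np.ndarray
    dT_max: np.ndarray
    state: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if not (np.isfinite(self.dT_mean).all() and np.isfinite(self.dT_max).all()):
            raise ValueError("non-finite warming values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "dT_mean_K": self.dT_mean, "dT_max_K": self.dT_max})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary least-squares line dT = slope*I + intercept."""

    slope: float  # K per (W/m^2)
    intercept: float  # K
    r_squared: float  # may be nan when dT has zero variance


def surface_warming(state, mesh: Mesh, T_ref: float = T_AMBIENT) -> tuple[float, float]:
    """Area-weighted mean and max warming over the exposed coral surface (K).

    The surface is the set of coral cells with at least one fluid-facing
    face; weights are the exposed face areas.  A mesh without coral cells is
    rejected.
    """
    mask, wts = mesh.surface_cells()
    dT = state.T - T_ref
    mean = float((dT[mask] * wts[mask]).sum() / wts[mask].sum())
    return mean, float(dT[mask].max())


def fit_time_constant(series: TimeSeries, t_on: float, use: str = "mean") -> tuple[float, float, float]:
    """Exponential time constant of a dark-light warm-up.

    Fits dT(t) = dT_ss * (1 - exp(-(t - t_on)/tau)) for t >= t_on by
    nonlinear least squares with t_on fixed; returns (tau, dT_ss, rms
    residual).  Requires the series to span at least ~3 tau beyond t_on and
    to actually rise; flat or decreasing series are rejected.
    """
    y_all = series.dT_mean if use == "mean" else series.dT_max
    sel = series.t >= t_on - 1e-9
    t = series.t[sel] - t_on
    y = y_all[sel]
    if len(t) < 4 or y[-1] <= 0 or y.max() <= 1e-12:
        raise ValueError("series does not rise after t_on; cannot fit a time constant")

    def model(tt, dT_ss, tau):
        return dT_ss * -np.expm1(-tt / tau)

    # crude initial guesses from the 63% crossing
    dT0 = y[-1]
    i63 = int(np.searchsorted(y, 0.632 * dT0))
    tau0 = max(t[min(i63, len(t) - 1)], t[-1] / 10.0)
    (dT_ss, tau), _ = curve_fit(model, t, y, p0=[dT0, tau0], maxfev=20000)
    if tau <= 0:
        raise ValueError("fit produced a non-positive time constant")
    resid = float(np.sqrt(np.mean((model(t, dT_ss, tau) - y) ** 2)))
    if t[-1] < 3.0 * tau:
        raise ValueError(f"series spans only {t[-1]:.0f} s < 3*tau = {3 * tau:.0f} s")
    return float(tau), float(dT_ss), resid


def irradiance_response(points) -> LinearFitResult:
    """OLS line through (irradiance, warming) points with R^2.

    At least 3 points are required.  R^2 is reported as nan when the warming
    has zero variance (a perfectly flat response).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (I, dT) points")
    I, y = pts[:, 0], pts[:, 1]
    slope, intercept = np.polyfit(I, y, 1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return LinearFitResult(float(slope), float(intercept), float("nan"))
    ss_res = float(((y - (slope * I + intercept)) ** 2).sum())
    return LinearFitResult(float(slope), float(intercept), 1.0 - ss_res / ss_tot)


def extract_slices(state, mesh: Mesh, planes) -> list[dict]:
    """Axial-velocity and temperature slices on x-normal planes.

    ``planes`` are x-coordinates (m, chamber frame).  Values are the
    nearest-cell field values — no interpolation — so slices conserve the
    discrete field exactly.  Each dict holds the plane position, the (y, z)
    cell centres, the u and T arrays and the in-plane coral outline mask.
    """
    out = []
    for xpos in planes:
        if not mesh.xf[0] <= xpos <= mesh.xf[-1]:
            raise ValueError(f"plane x={xpos} outside the domain")
        i = int(np.clip(np.searchsorted(mesh.xf, xpos) - 1, 0, mesh.shape[0] - 1))
        out.append(
            {
                "x": float(mesh.xc[i]),
                "y": mesh.yc.copy(),
                "z": mesh.zc.copy(),
                "u": state.u[i].copy(),
                "T": state.T[i].copy(),
                "coral": mesh.coral_mask()[i].copy(),
            }
        )
    return out


def grid_independence_study(run_case, resolutions) -> pd.DataFrame:
    """Surface warming vs grid resolution.

    ``run_case`` maps a resolution triple to (n_cells, mean warming).  At
    least 3 resolutions are required.  The returned table carries the
    successive relative change and an ``asymptotic`` flag marking changes
    below 2%.
    """
    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions for a grid study")
    rows = []
    for res in resolutions:
        n, dT = run_case(res)
        rows.append({"resolution": str(tuple(res)), "n_cells": n, "dT_mean_K": dT})
    df = pd.DataFrame(rows).sort_values("n_cells").reset_index(drop=True)
    prev = df["dT_mean_K"].shift(1)
    df["rel_change"] = ((df["dT_mean_K"] - prev).abs() / df["dT_mean_K"].abs()).fillna(np.nan)
    df["asymptotic"] = df["rel_change"] < 0.02
    return df


def sensitivity_study(run_perturbed, volume_perturbation: float = 0.10) -> pd.DataFrame:
    """Skeletal warming trajectories under +-X% bulk-volume perturbation.

    A +X% bulk-volume perturbation at constant skeletal mass lowers the bulk
    density by the factor 1/(1+X) and raises the porosity accordingly; the
    external geometry is unchanged.  ``run_perturbed`` maps a volume
    perturbation fraction to a TimeSeries.  Returns a long-format table of
    trajectories at -X%, 0 and +X%.
    """
    if not -0.2 <= volume_perturbation <= 0.2:
        raise ValueError("perturbation must lie within +-20%")
    frames = []
    for pert in (-abs(volume_perturbation), 0.0, abs(volume_perturbation)):
        series = run_perturbed(pert)
        f = series.to_frame()
        f["volume_perturbation"] = pert
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
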