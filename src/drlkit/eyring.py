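"""Eyring analysis: temperature-resolved rate constants -> activation parameters.

A plot of ln(k/T) against 1/T is linear under transition-state theory
(transmission coefficient 1):

    ln(k/T) = ln(k_B/h) + dS/R - dH/(R*T)

so the slope gives the activation enthalpy dH (kcal/mol) and the intercept
the activation entropy dS (cal/mol/K) — the mixed kcal/cal convention of the
coordination-chemistry literature is kept in all reports, while the
computation itself runs in cal. dG(T) = dH - T*dS, with its variance taken
from the full 2x2 parameter covariance, is smallest near the mean
experimental temperature (a standard regression property).

Replicate spreads, when available, enter as inverse-variance weights after a
delta-method transform to the ln(k/T) scale; with no (or incomplete) spreads
the fit falls back to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import (
    BOLTZMANN_J_PER_K,
    GAS_CONSTANT_CAL,
    PLANCK_J_S,
    STANDARD_TEMPERATURE_K,
)
from .exceptions import ValidationError

__all__ = [
    "RateAtTemperature",
    "ActivationParameters",
    "EyringRegression",
    "eyring_fit",
    "eyring_rate",
    "gibbs_at",
]

_LN_KB_OVER_H = np.log(BOLTZMANN_J_PER_K / PLANCK_J_S)


@dataclass(frozen=True)
class RateAtTemperature:
    """One temperature point: rate constant with replicate spread."""

    temperature: float  # K
    k: float  # s^-1
    sd: float = 0.0  # s^-1, across replicates
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.k <= 0 or not np.isfinite(self.k):
            raise ValidationError("k must be finite and > 0")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass
class ActivationParameters:
    """Activation enthalpy/entropy with their joint covariance.

    dH in kcal/mol, dS in cal/mol/K; covariance is 2x2 over (dH, dS) in those
    units.
    """

    dH: float
    dS: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValidationError("covariance must be 2x2")
        if abs(cov[0, 1] - cov[1, 0]) > 1e-12 * (1 + abs(cov[0, 1])):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValidationError("covariance must be positive semi-definite")
        self.covariance = cov

    def gibbs(self, temperature: float = STANDARD_TEMPERATURE_K) -> tuple[float, float]:
        """dG(T) in kcal/mol with its propagated standard deviation."""
        return gibbs_at(self, temperature)

    def to_dict(self) -> dict:
        dg, dg_sd = self.gibbs()
        return {
            "dH_kcal_per_mol": self.dH,
            "dS_cal_per_mol_K": self.dS,
            "dG_298K_kcal_per_mol": dg,
            "dG_298K_sd": dg_sd,
            "covariance": self.covariance.tolist(),
        }


class EyringRegression(RegressorMixin, BaseEstimator):
    """Scikit-learn style linear Eyring fit.

    fit(X, y): X = temperatures (K), y = rate constants (s^-1); optional
    ``sd`` gives replicate spreads of k for inverse-variance weighting.

    Attributes (after fit): dH_ (kcal/mol), dS_ (cal/mol/K), covariance_,
    params_ (ActivationParameters).
    """

    def __init__(self, weighting: str = "inverse_variance"):
        self.weighting = weighting

    def fit(self, X, y, sd=None):
        T = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if T.size != k.size:
            raise ValidationError("temperatures and rates must have equal length")
        if np.unique(T).size < 2:
            raise ValidationError("Eyring fit needs >= 2 distinct temperatures")
        if np.any(T <= 0):
            raise ValidationError("temperatures must be > 0 K")
        if np.any(k <= 0) or not np.all(np.isfinite(k)):
            raise ValidationError("rate constants must be finite and > 0")

        x = 1.0 / T
        yv = np.log(k / T)
        # delta method: var[ln(k/T)] = (sd_k / k)^2
        w = None
        if self.weighting == "inverse_variance" and sd is not None:
            sd = np.asarray(sd, dtype=float).reshape(-1)
            if np.all(sd > 0):
                w = (k / sd) ** 2

        A = np.column_stack([x, np.ones_like(x)])
        if w is None:
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            resid = yv - A @ coef
            dof = max(T.size - 2, 0)
            s2 = float(resid @ resid) / dof if dof else 0.0
            cov_line = s2 * np.linalg.inv(A.T @ A)
        else:
            Aw = A * np.sqrt(w)[:, None]
            yw = yv * np.sqrt(w)
            coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
            # known variances: covariance is (A^T W A)^-1, unscaled
            cov_line = np.linalg.inv(Aw.T @ Aw)
        slope, intercept = coef

        R_kcal = GAS_CONSTANT_CAL / 1000.0
        self.dH_ = float(-slope * R_kcal)
        self.dS_ = float(GAS_CONSTANT_CAL * (intercept - _LN_KB_OVER_H))
        # linear map (slope, intercept) -> (dH, dS)
        J = np.array([[-R_kcal, 0.0], [0.0, GAS_CONSTANT_CAL]])
        cov = J @ cov_line @ J.T
        self.covariance_ = 0.5 * (cov + cov.T)
        self.params_ = ActivationParameters(
            dH=self.dH_,
            dS=self.dS_,
            covariance=self.covariance_,
            reference={
                "n_points": int(T.size),
                "T_range_K": [float(T.min()), float(T.max())],
                "weighted": w is not None,
            },
        )
        return self

    def predict(self, X):
        """Rate constants (s^-1) at temperatures X."""
        T = np.asarray(X, dtype=float)
        return eyring_rate(self.params_, T)


def eyring_fit(points, weighting: str = "inverse_variance") -> ActivationParameters:
    """Fit activation parameters from (temperature, rate) points.

    ``points`` is an iterable of :class:`RateAtTemperature` (or (T, k[, sd])
    tuples). Weighted by replicate spread when every point carries one.
    """
    pts = [
        p if isinstance(p, RateAtTemperature) else RateAtTemperature(*p)
        for p in points
    ]
    if len(pts) < 2:
        raise ValidationError("Eyring fit needs >= 2 points")
    T = np.array([p.temperature for p in pts])
    k = np.array([p.k for p in pts])
    sd = np.array([p.sd for p in pts])
    est = EyringRegression(weighting=weighting)
    est.fit(T, k, sd=sd if np.all(sd > 0) else None)
    return est.params_


def gibbs_at(params: ActivationParameters, temperature: float) -> tuple[float, float]:
    """Activation free energy dG(T) = dH - T*dS in kcal/mol, with 1-sigma sd.

    var[dG] = var[dH] + T^2 var[dS] - 2 T cov[dH, dS], with dS terms converted
    from cal to kcal.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be > 0 K")
    T = float(temperature)
    dg = params.dH - T * params.dS / 1000.0
    cov = params.covariance
    var = cov[0, 0] + (T / 1000.0) ** 2 * cov[1, 1] - 2.0 * (T / 1000.0) * cov[0, 1]
    return float(dg), float(np.sqrt(max(var, 0.0)))


def eyring_rate(params: ActivationParameters, temperature) -> float | np.ndarray:
    """Rate constant k(T) = (k_B T / h) exp(-dG(T) / (R T)).

    The exponent is clipped to +-600 so extreme parameters degrade
    gracefully instead of overflowing.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperature must be > 0 K")
    dg_cal = params.dH * 1000.0 - T * params.dS
    exponent = np.clip(-dg_cal / (GAS_CONSTANT_CAL * T), -600.0, 600.0)
    k = (BOLTZMANN_J_PER_K * T / PLANCK_J_S) * np.exp(exponent)
    return float(k) if np.isscalar(temperature) else k
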