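"""Pseudo-first-order fitting of DRL relative-intensity curves.

The observable is the pair of complementary bound-species fractions; both are
fitted globally with shared parameters (rate, addition time, equilibrium
plateau), which is symmetric in the two isotopologues:

    p_unlabelled(t) = f_eq_u + (1 - f_eq_u) * exp(-k * (t - t_L))
    p_labelled(t)   = 1 - p_unlabelled(t)

with f_eq_u = 1 - f_label fixed to the known pool composition by default.
Because the fit consumes fractions only, any common-mode intensity drift
(spray fluctuation) cancels and leaves the estimate unchanged.

``FirstOrderExchange`` is a scikit-learn style estimator; the module-level
functions are thin wrappers matching the rest of the library's functional
surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import RelativeTraces
from .exceptions import DegenerateDataError, FitConvergenceError, ValidationError

__all__ = [
    "FitOptions",
    "ObservedRate",
    "QualifiedRate",
    "FirstOrderExchange",
    "fit_first_order",
    "fit_competitive",
    "CompetitiveFitResult",
    "check_quantitation_limit",
]

#: data are declared rate-free (degenerate) below this peak-to-peak amplitude
_FLAT_TOL = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Options for the first-order DRL fit.

    quantitation_limit is the instrument-protocol ceiling: processes faster
    than ~0.5 s^-1 complete during labelled-ligand addition and source
    transfer, so their fitted rates are qualitative only.
    """

    float_t_L: bool = False
    float_f_eq: bool = False
    weighting: str = "none"  # "none" | "inverse_variance"
    quantitation_limit: float = 0.5  # s^-1

    def __post_init__(self) -> None:
        if self.quantitation_limit <= 0:
            raise ValidationError("quantitation_limit must be > 0")
        if self.weighting not in ("none", "inverse_variance"):
            raise ValidationError("weighting must be 'none' or 'inverse_variance'")


@dataclass
class ObservedRate:
    """Fitted MS-observed rate constant with uncertainty and diagnostics."""

    k_ms: float  # s^-1
    stderr: float  # s^-1, 1*SE from the scaled Gauss-Newton covariance
    t_L_fitted: float  # s (equals the fixed value unless floated)
    f_eq_fitted: float  # labelled-fraction plateau
    residual_rms: float
    n_points: int  # post-addition time points used

    def __post_init__(self) -> None:
        if self.k_ms < 0 or self.stderr < 0:
            raise ValidationError("k_ms and stderr must be >= 0")
        if self.n_points < 3:
            raise ValidationError("a rate fit needs at least 3 time points")

    def to_dict(self) -> dict:
        return {
            "k_ms_per_s": self.k_ms,
            "stderr_per_s": self.stderr,
            "t_L_s": self.t_L_fitted,
            "f_eq": self.f_eq_fitted,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
        }


@dataclass
class QualifiedRate:
    """An ObservedRate plus quantitation-limit flags ('too_fast', 'undersampled')."""

    rate: ObservedRate
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def _model_unlabelled(t, k, t_l, f_eq_label):
    dt = np.clip(t - t_l, 0.0, None)
    plateau = 1.0 - f_eq_label
    return plateau + (1.0 - plateau) * np.exp(-k * dt)


class FirstOrderExchange(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the pseudo-first-order DRL model.

    Parameters
    ----------
    f_label : float
        Labelled fraction of the ligand pool; sets the plateau when
        ``float_f_eq`` is False (the default, matching the standard protocol
        of known stock ratios).
    t_L : float
        Labelled-ligand addition time (seconds); fitted only if ``float_t_L``.
    float_t_L, float_f_eq : bool
        Free the addition time / plateau during the fit.
    weighting : "none" or "inverse_variance"
        Inverse-variance weighting needs per-point standard deviations passed
        to :meth:`fit` as ``sample_sd``.

    Attributes (after fit)
    ----------------------
    k_ms_, stderr_, t_L_, f_eq_, residual_rms_, n_points_, report_
    """

    def __init__(
        self,
        f_label: float = 0.5,
        t_L: float = 0.0,
        float_t_L: bool = False,
        float_f_eq: bool = False,
        weighting: str = "none",
    ):
        self.f_label = f_label
        self.t_L = t_L
        self.float_t_L = float_t_L
        self.float_f_eq = float_f_eq
        self.weighting = weighting

    # -- helpers ---------------------------------------------------------
    def _validate(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValidationError("X must be a 1-D array of times (or column vector)")
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != t.size or y.shape[1] not in (1, 2):
            raise ValidationError("y must be (n,) or (n, 2): unlabelled [, labelled] fractions")
        if not 0.0 <= self.f_label <= 1.0:
            raise ValidationError("f_label must be in [0, 1]")
        keep = np.all(np.isfinite(y), axis=1) & np.isfinite(t)
        return t[keep], y[keep]

    def fit(self, X, y, sample_sd=None):
        """Fit times X against unlabelled (and optionally labelled) fractions y."""
        t, y = self._validate(X, y)
        post = t >= self.t_L if not self.float_t_L else np.ones_like(t, bool)
        n_post = int(post.sum())
        if n_post < 3:
            raise ValidationError("need >= 3 post-addition time points")

        p_obs = y[:, 0]
        amplitude = float(np.ptp(p_obs[post]))
        if amplitude < _FLAT_TOL:
            raise DegenerateDataError(
                "fractions are constant over the fit window: rate unidentifiable "
                f"(peak-to-peak {amplitude:.2e} < {_FLAT_TOL:.0e})"
            )

        params = lmfit.Parameters()
        params.add("k", value=self._initial_rate(t[post], p_obs[post]), min=0.0)
        params.add("t_l", value=self.t_L, vary=self.float_t_L)
        params.add(
            "f_eq", value=self.f_label, min=0.0, max=1.0, vary=self.float_f_eq
        )

        weights = None
        if self.weighting == "inverse_variance" and sample_sd is not None:
            sd = np.asarray(sample_sd, dtype=float)
            weights = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 0.0)

        t_fit, y_fit = t[post], y[post]
        w_fit = weights[post] if weights is not None else None

        def residual(pars):
            p = _model_unlabelled(t_fit, pars["k"].value, pars["t_l"].value, pars["f_eq"].value)
            res = [p - y_fit[:, 0]]
            if y_fit.shape[1] == 2:
                res.append((1.0 - p) - y_fit[:, 1])
            res = np.concatenate(res)
            if w_fit is not None:
                res *= np.tile(w_fit, y_fit.shape[1])
            return res

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = lmfit.minimize(residual, params, method="leastsq")
        if not result.success:
            raise FitConvergenceError(f"first-order fit did not converge: {result.message}")

        k = result.params["k"]
        stderr = k.stderr if k.stderr is not None else 0.0
        # a two-species group's fractions are exact complements, so the second
        # trace duplicates every residual with opposite sign: it symmetrizes
        # the fit but carries no new information, and the naive least-squares
        # covariance is deflated by exactly 2. Undo that so stderr reflects
        # the number of independent observations.
        if y_fit.shape[1] == 2 and np.max(np.abs(y_fit.sum(axis=1) - 1.0)) < 1e-9:
            stderr *= np.sqrt(2.0)
        self.k_ms_ = float(k.value)
        self.stderr_ = float(stderr)
        self.t_L_ = float(result.params["t_l"].value)
        self.f_eq_ = float(result.params["f_eq"].value)
        self.residual_rms_ = float(np.sqrt(np.mean(result.residual**2)))
        self.n_points_ = n_post
        self.report_ = ObservedRate(
            k_ms=self.k_ms_,
            stderr=self.stderr_,
            t_L_fitted=self.t_L_,
            f_eq_fitted=self.f_eq_,
            residual_rms=self.residual_rms_,
            n_points=self.n_points_,
        )
        self._n_traces = y.shape[1]
        return self

    def predict(self, X):
        """Model fractions at times X; shape matches the fitted y."""
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        p = _model_unlabelled(t, self.k_ms_, self.t_L_, self.f_eq_)
        if getattr(self, "_n_traces", 1) == 2:
            return np.column_stack([p, 1.0 - p])
        return p

    @staticmethod
    def _initial_rate(t, p) -> float:
        """Half-decay heuristic for the rate starting value."""
        p0, p_inf = p[0], p[-1]
        target = p_inf + 0.5 * (p0 - p_inf)
        crossing = np.nonzero((p - target) * (p0 - target) <= 0)[0]
        if crossing.size and t[crossing[0]] > t[0]:
            return float(np.log(2.0) / (t[crossing[0]] - t[0]))
        span = t[-1] - t[0]
        return 5.0 / span if span > 0 else 1.0


def _pair_columns(rel: RelativeTraces, unlabelled: str | None, labelled: str | None):
    names = rel.species
    if unlabelled is None or labelled is None:
        if len(names) != 2:
            raise ValidationError(
                "group must contain exactly the unlabelled/labelled pair, "
                f"got {names}; pass unlabelled=/labelled= explicitly"
            )
        unlabelled, labelled = names
    for n in (unlabelled, labelled):
        if n not in rel.fractions:
            raise ValidationError(f"species {n!r} not present in traces")
    return unlabelled, labelled


def fit_first_order(
    rel: RelativeTraces,
    f_label: float,
    opts: FitOptions | None = None,
    t_L: float = 0.0,
    unlabelled: str | None = None,
    labelled: str | None = None,
    sample_sd=None,
) -> ObservedRate:
    """Fit a relative-intensity group with the shared-parameter first-order law.

    The first species of the group is taken as the unlabelled (decaying)
    trace and the second as its labelled complement unless named explicitly.
    Masked time points are excluded from the fit.
    """
    opts = opts or FitOptions()
    unlabelled, labelled = _pair_columns(rel, unlabelled, labelled)
    ok = ~rel.mask
    est = FirstOrderExchange(
        f_label=f_label,
        t_L=t_L,
        float_t_L=opts.float_t_L,
        float_f_eq=opts.float_f_eq,
        weighting=opts.weighting,
    )
    y = np.column_stack([rel[unlabelled][ok], rel[labelled][ok]])
    sd = np.asarray(sample_sd, float)[ok] if sample_sd is not None else None
    est.fit(rel.times[ok], y, sample_sd=sd)
    return est.report_


@dataclass
class CompetitiveFitResult:
    """Per-host rates from a single multi-host experiment, with error isolation."""

    rates: dict[str, ObservedRate]
    errors: dict[str, str]

    def ratio_table(self):
        """DataFrame of pairwise rate ratios k(row)/k(col)."""
        import pandas as pd

        hosts = list(self.rates)
        data = [
            [self.rates[a].k_ms / self.rates[b].k_ms for b in hosts] for a in hosts
        ]
        return pd.DataFrame(data, index=hosts, columns=hosts)


def fit_competitive(
    rel_by_host: dict[str, RelativeTraces],
    f_label: float,
    opts: FitOptions | None = None,
    t_L: float = 0.0,
) -> CompetitiveFitResult:
    """Fit several hosts monitored in one experiment, sharing the time base.

    Each host group gets an independent first-order fit (same known t_L); a
    failure on one host is recorded and does not abort the others.
    """
    if len(rel_by_host) < 2:
        raise ValidationError("competitive fitting needs >= 2 host groups")
    rates: dict[str, ObservedRate] = {}
    errors: dict[str, str] = {}
    for host, rel in rel_by_host.items():
        try:
            rates[host] = fit_first_order(rel, f_label=f_label, opts=opts, t_L=t_L)
        except (DegenerateDataError, FitConvergenceError, ValidationError) as exc:
            errors[host] = f"{type(exc).__name__}: {exc}"
    return CompetitiveFitResult(rates=rates, errors=errors)


def check_quantitation_limit(
    rate: ObservedRate,
    opts: FitOptions | None = None,
    sample_times=None,
    t_L: float = 0.0,
) -> QualifiedRate:
    """Qualify a fitted rate against the instrument's quantitation envelope.

    Flags 'too_fast' when k_ms exceeds the limit (the exchange completes while
    the labelled ligand is still being added and infused), and 'undersampled'
    when fewer than 3 samples fall within the first 1/k after addition (the
    decay is over before it is sampled, whatever its magnitude).
    """
    opts = opts or FitOptions()
    flags: list[str] = []
    if rate.k_ms > opts.quantitation_limit:
        flags.append("too_fast")
    if sample_times is not None and rate.k_ms > 0:
        t = np.asarray(sample_times, dtype=float)
        n_early = int(np.sum((t >= t_L) & (t <= t_L + 1.0 / rate.k_ms)))
        if n_early < 3:
            flags.append("undersampled")
    return QualifiedRate(rate=rate, flags=flags)
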