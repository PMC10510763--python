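"""Mechanistic model of ligand exchange monitored by delayed reactant labelling.

The exchange scheme is

    M(X) + Py   <-- k_on / k_off -->  M(Py)
    M(X) + PyL  <-- k_on / k_off -->  M(PyL)

where M is the host (a metal complex whose auxiliary ligand X is lost on
ionization), Py the unlabelled ligand and PyL its isotopologue added after a
delay t_L. Labelled and unlabelled ligand share the same rate constants (no
kinetic isotope effect: coordination happens through a donor atom remote from
the label). Free-ligand pools are depleted explicitly as the host binds and
releases, so small-excess regimes are meaningful; the familiar analytic
single-exponential solution is recovered in the large-excess limit, where the
relative bound-species signal relaxes at exactly ``k_off``.

A two-site variant models hosts with two inequivalent binding sites (a cavity
site and an outer site) that exchange independently against the same
well-mixed ligand pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .containers import RelativeTraces, TimeTraces
from .exceptions import IntegrationError, ValidationError

__all__ = [
    "RateConstants",
    "TwoSiteRateConstants",
    "SolutionComposition",
    "Trajectory",
    "closed_form_relative",
    "simulate_single_site",
    "simulate_two_site",
    "predict_kms",
    "scan_kms_vs_equivalents",
    "SINGLE_SITE_CLASSES",
    "TWO_SITE_CLASSES",
]

#: observable class names exposed by the single-site model (bound host species)
SINGLE_SITE_CLASSES = ("bound_unlabelled", "bound_labelled")
#: observable class names exposed by the two-site model
TWO_SITE_CLASSES = ("PP", "PL", "LL")


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate constants of one exchange site.

    k_on in M^-1 s^-1, k_off in s^-1; both strictly positive and finite.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def kd(self) -> float:
        """Dissociation constant k_off/k_on (molar)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class TwoSiteRateConstants:
    """Rate constants for a host with an inner (cavity) and an outer site."""

    inner: RateConstants
    outer: RateConstants


@dataclass(frozen=True)
class SolutionComposition:
    """Concentrations and timing of a DRL experiment.

    ``t_u=None`` means the host is pre-equilibrated with the unlabelled ligand
    before the observation window starts (the standard protocol: phase I has
    reached its steady state before the labelled ligand is added at ``t_L``).
    """

    host_total: float  # M
    ligand_unlabelled: float  # M, present from t_u (or pre-equilibrated)
    ligand_labelled: float  # M, added at t_L
    t_L: float = 0.0  # s
    t_u: float | None = None  # s; None = pre-equilibrated at grid start
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if not np.isfinite(self.host_total) or self.host_total <= 0:
            raise ValidationError("host_total must be finite and > 0")
        for name in ("ligand_unlabelled", "ligand_labelled"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
        if self.ligand_unlabelled + self.ligand_labelled <= 0:
            raise ValidationError("at least one ligand pool must be > 0")
        if self.t_u is not None and self.t_u >= self.t_L:
            raise ValidationError("t_u must precede t_L")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")

    @property
    def f_label(self) -> float:
        """Labelled fraction of the total ligand pool."""
        return self.ligand_labelled / (self.ligand_unlabelled + self.ligand_labelled)

    @classmethod
    def from_equivalents(
        cls,
        host_total: float,
        equiv_unlabelled: float,
        equiv_labelled: float,
        **kwargs,
    ) -> "SolutionComposition":
        """Build from ligand/host equivalents instead of molar concentrations."""
        return cls(
            host_total=host_total,
            ligand_unlabelled=equiv_unlabelled * host_total,
            ligand_labelled=equiv_labelled * host_total,
            **kwargs,
        )


@dataclass
class Trajectory:
    """Time-resolved species concentrations (molar) from a simulation."""

    times: np.ndarray
    species: dict[str, np.ndarray]
    host_total: float
    host_species: tuple[str, ...]  # species counted in the host mass balance
    observable_classes: tuple[str, ...]  # bound classes reported by ESI-MS

    def check_conservation(self, rtol: float = 1e-9) -> None:
        total = sum(self.species[name] for name in self.host_species)
        if np.any(np.abs(total - self.host_total) > rtol * self.host_total):
            worst = float(np.max(np.abs(total - self.host_total)) / self.host_total)
            raise IntegrationError(
                "host mass balance violated",
                {"max_relative_error": worst, "rtol": rtol},
            )

    def to_traces(self) -> TimeTraces:
        """Observable-class concentrations as (noise-free) intensity traces."""
        return TimeTraces(
            times=self.times,
            intensities={c: np.clip(self.species[c], 0.0, None) for c in self.observable_classes},
        )

    def to_relative(self, group_id: str = "host") -> RelativeTraces:
        """Normalize the observable classes to within-group fractions."""
        stack = np.vstack([self.species[c] for c in self.observable_classes])
        total = stack.sum(axis=0)
        mask = total <= 0
        fractions = np.where(mask, np.nan, stack / np.where(mask, 1.0, total))
        return RelativeTraces(
            times=self.times,
            fractions={
                c: np.clip(fractions[i], 0.0, 1.0)
                for i, c in enumerate(self.observable_classes)
            },
            group_id=group_id,
            mask=mask,
        )

    def to_frame(self):
        return self.to_traces().to_frame().rename(columns={"intensity": "value"})


def _check_grid(times, t_L: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValidationError("times must be a 1-D grid with >= 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing (sorted, unique)")
    if times[0] > t_L or times[-1] < t_L:
        raise ValidationError("time grid must cover the labelled-ligand addition time t_L")
    return times


def closed_form_relative(
    k_off: float,
    f_label: float,
    t_L: float,
    times,
    species: tuple[str, str] = SINGLE_SITE_CLASSES,
) -> RelativeTraces:
    """Analytic large-excess DRL observable.

    Under pseudo-first-order conditions the unlabelled bound fraction follows

        p(t) = (1 - f_label) + f_label * exp(-k_off * (t - t_L))    for t >= t_L

    with p = 1 before the labelled ligand is added, and the labelled fraction
    is its complement. The plateau (1 - f_label, f_label) reflects the
    labelled/unlabelled ratio of the ligand pool.
    """
    if not 0.0 <= f_label <= 1.0:
        raise ValidationError("f_label must be in [0, 1]")
    if k_off < 0 or not np.isfinite(k_off):
        raise ValidationError("k_off must be finite and >= 0")
    times = np.asarray(times, dtype=float)
    dt = np.clip(times - t_L, 0.0, None)
    p = (1.0 - f_label) + f_label * np.exp(-k_off * dt)
    return RelativeTraces(
        times=times,
        fractions={species[0]: p, species[1]: 1.0 - p},
        group_id="closed_form",
    )


def _equilibrium_bound(host: float, ligand: float, kd: float) -> float:
    """Bound complex concentration for 1:1 binding (exact quadratic root)."""
    b = host + ligand + kd
    disc = b * b - 4.0 * host * ligand
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def _integrate(rhs, y0, segments, times, rtol, atol):
    """Piecewise integration across concentration-step events.

    segments: list of (t_start, t_end, state_transform) where state_transform
    is applied to y at t_start (instantaneous addition events).
    """
    out = np.full((len(y0), times.size), np.nan)
    y = np.asarray(y0, dtype=float)
    for t0, t1, transform in segments:
        if transform is not None:
            y = transform(y)
        sel = (times >= t0) & (times <= t1)
        # grid points in (t0, t1]; t0 itself belongs to the previous segment
        # except for the very first one
        t_eval = times[sel]
        if t_eval.size:
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="LSODA",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"ODE integration failed: {sol.message}",
                    {"segment": (t0, t1), "status": sol.status},
                )
            out[:, sel] = sol.y
            y = sol.y[:, -1] if t_eval[-1] == t1 else solve_ivp(
                rhs, (t_eval[-1], t1), sol.y[:, -1], method="LSODA", rtol=rtol, atol=atol
            ).y[:, -1]
        else:
            sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(
                    f"ODE integration failed: {sol.message}",
                    {"segment": (t0, t1), "status": sol.status},
                )
            y = sol.y[:, -1]
    return out


def simulate_single_site(
    rates: RateConstants,
    comp: SolutionComposition,
    times,
    rtol: float = 1e-8,
    mixing_tau: float = 0.0,
) -> Trajectory:
    """Integrate the single-site exchange scheme on a time grid.

    State: bound unlabelled P, bound labelled L, free pools Py and PyL; the
    free host is host_total - P - L. The labelled pool steps up at ``t_L``
    (instantaneous by default; ``mixing_tau`` > 0 feeds it in exponentially to
    mimic a finite mixing time). Adaptive stiff-capable integration at relative
    tolerance ``rtol`` and absolute tolerance 1e-12 * host_total: k_on and
    k_off can differ by many orders of magnitude.
    """
    times = _check_grid(times, comp.t_L)
    atol = 1e-12 * comp.host_total
    k_on, k_off, host = rates.k_on, rates.k_off, comp.host_total
    tau = float(mixing_tau)
    if tau < 0:
        raise ValidationError("mixing_tau must be >= 0")

    # state: [P, L, Py_free, PyL_free, labelled_reservoir]
    def rhs(t, y):
        P, L, Py, PyL, R = y
        F = host - P - L
        dP = k_on * F * Py - k_off * P
        dL = k_on * F * PyL - k_off * L
        influx = (R / tau) if tau > 0 else 0.0
        return [dP, dL, -dP, -dL + influx, -influx]

    if comp.t_u is None:
        # phase I already at steady state: exact 1:1 binding equilibrium
        P0 = _equilibrium_bound(host, comp.ligand_unlabelled, rates.kd)
        y0 = [P0, 0.0, comp.ligand_unlabelled - P0, 0.0, 0.0]
        events = [times[0]]
    else:
        if times[0] > comp.t_u:
            raise ValidationError("grid must cover t_u when it is given")
        y0 = [0.0, 0.0, 0.0, 0.0, 0.0]
        events = [times[0], comp.t_u]

    def add_unlabelled(y):
        y = y.copy()
        y[2] += comp.ligand_unlabelled
        return y

    def add_labelled(y):
        y = y.copy()
        if tau > 0:
            y[4] += comp.ligand_labelled
        else:
            y[3] += comp.ligand_labelled
        return y

    segments = []
    if comp.t_u is None:
        segments.append((times[0], comp.t_L, None))
    else:
        segments.append((times[0], comp.t_u, None))
        segments.append((comp.t_u, comp.t_L, add_unlabelled))
    segments.append((comp.t_L, times[-1], add_labelled))
    # drop zero-length leading segments
    segments = [(a, b, tr) for a, b, tr in segments if b > a or tr is not None]

    y = _integrate(rhs, y0, segments, times, rtol, atol)
    # the grid point exactly at t_L belongs to the pre-addition state
    P, L, Py, PyL, _ = y
    F = host - P - L
    traj = Trajectory(
        times=times,
        species={
            "host_free": F,
            "bound_unlabelled": P,
            "bound_labelled": L,
            "ligand_unlabelled_free": Py,
            "ligand_labelled_free": PyL,
        },
        host_total=host,
        host_species=("host_free", "bound_unlabelled", "bound_labelled"),
        observable_classes=SINGLE_SITE_CLASSES,
    )
    traj.check_conservation()
    return traj


# two-site state ordering: site occupancy in {0: vacant, 1: unlabelled, 2: labelled}
_TS_STATES = [(i, j) for i in range(3) for j in range(3)]
_TS_INDEX = {s: n for n, s in enumerate(_TS_STATES)}


def simulate_two_site(
    rates: TwoSiteRateConstants,
    comp: SolutionComposition,
    times,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the two-site exchange scheme (inner cavity + outer site).

    Each complex carries two sites that bind/release ligand independently,
    drawing from the same well-mixed labelled/unlabelled pools; vacant-site
    states are modelled explicitly so both k_on and k_off of each site are
    honoured. Observable classes are the fully-occupied label combinations:
    PP (both unlabelled), PL (either mixed state) and LL (both labelled),
    mirroring the three isotopologue ions of a bis-ligand complex.
    """
    times = _check_grid(times, comp.t_L)
    atol = 1e-12 * comp.host_total
    host = comp.host_total
    kin, kout = rates.inner, rates.outer

    def rhs(t, y):
        c = y[:9]
        Py, PyL = y[9], y[10]
        pools = (Py, PyL)
        dc = np.zeros(9)
        dPy = 0.0
        dPyL = 0.0
        for (i, j), n in _TS_INDEX.items():
            # inner site transitions
            if i == 0:
                for lab, pool in ((1, Py), (2, PyL)):
                    rate = kin.k_on * pool * c[n]
                    dc[n] -= rate
                    dc[_TS_INDEX[(lab, j)]] += rate
                    if lab == 1:
                        dPy -= rate
                    else:
                        dPyL -= rate
            else:
                rate = kin.k_off * c[n]
                dc[n] -= rate
                dc[_TS_INDEX[(0, j)]] += rate
                if i == 1:
                    dPy += rate
                else:
                    dPyL += rate
            # outer site transitions
            if j == 0:
                for lab, pool in ((1, Py), (2, PyL)):
                    rate = kout.k_on * pool * c[n]
                    dc[n] -= rate
                    dc[_TS_INDEX[(i, lab)]] += rate
                    if lab == 1:
                        dPy -= rate
                    else:
                        dPyL -= rate
            else:
                rate = kout.k_off * c[n]
                dc[n] -= rate
                dc[_TS_INDEX[(i, 0)]] += rate
                if j == 1:
                    dPy += rate
                else:
                    dPyL += rate
        return np.concatenate([dc, [dPy, dPyL]])

    # pre-equilibration with the unlabelled pool only: independent-site
    # occupancies theta_s = Py/(Py + Kd_s) with self-consistent free ligand
    lig0 = comp.ligand_unlabelled

    def free_ligand_residual(py_free):
        theta_in = py_free / (py_free + kin.kd)
        theta_out = py_free / (py_free + kout.kd)
        return py_free + host * (theta_in + theta_out) - lig0

    if lig0 > 0:
        py_free0 = brentq(free_ligand_residual, 0.0, lig0, xtol=1e-18, rtol=1e-14)
    else:
        py_free0 = 0.0
    th_in = py_free0 / (py_free0 + kin.kd) if lig0 > 0 else 0.0
    th_out = py_free0 / (py_free0 + kout.kd) if lig0 > 0 else 0.0
    y0 = np.zeros(11)
    for (i, j), n in _TS_INDEX.items():
        pi = (1 - th_in) if i == 0 else (th_in if i == 1 else 0.0)
        pj = (1 - th_out) if j == 0 else (th_out if j == 1 else 0.0)
        y0[n] = host * pi * pj
    y0[9] = py_free0

    def add_labelled(y):
        y = y.copy()
        y[10] += comp.ligand_labelled
        return y

    segments = [(times[0], comp.t_L, None), (comp.t_L, times[-1], add_labelled)]
    segments = [(a, b, tr) for a, b, tr in segments if b > a or tr is not None]
    y = _integrate(rhs, y0, segments, times, rtol, atol)

    species = {
        f"C{i}{j}": y[_TS_INDEX[(i, j)]] for (i, j) in _TS_STATES
    }
    species["ligand_unlabelled_free"] = y[9]
    species["ligand_labelled_free"] = y[10]
    species["PP"] = y[_TS_INDEX[(1, 1)]]
    species["PL"] = y[_TS_INDEX[(1, 2)]] + y[_TS_INDEX[(2, 1)]]
    species["LL"] = y[_TS_INDEX[(2, 2)]]
    traj = Trajectory(
        times=times,
        species=species,
        host_total=host,
        host_species=tuple(f"C{i}{j}" for (i, j) in _TS_STATES),
        observable_classes=TWO_SITE_CLASSES,
    )
    traj.check_conservation()
    return traj


def _default_grid(k_off: float, t_L: float, dt: float = 1.0, horizons: float = 5.0) -> np.ndarray:
    """Sampling grid used for k_MS prediction: dt-spaced over horizons/k_off."""
    span = horizons / k_off
    n = int(np.ceil(span / dt)) + 1
    return t_L + dt * np.arange(n)


def predict_kms(
    rates: RateConstants,
    comp: SolutionComposition,
    fit_options=None,
    dt: float = 1.0,
    horizons: float = 5.0,
):
    """Predict the MS-observed rate constant for given conditions.

    Simulates a noise-free trajectory, normalizes the bound species to the
    relative-intensity observable, and fits it with the first-order law —
    exactly the procedure applied to measured DRL curves. At large ligand
    excess (>= 100 equivalents) the result converges to ``k_off``; at small
    excess the finite free pool makes the observed rate larger.

    Returns an ``ObservedRate`` (see :mod:`drlkit.fitting`).
    """
    from .fitting import FitOptions, fit_first_order

    times = _default_grid(rates.k_off, comp.t_L, dt=dt, horizons=horizons)
    traj = simulate_single_site(rates, comp, times)
    rel = traj.to_relative()
    opts = fit_options or FitOptions()
    return fit_first_order(rel, f_label=comp.f_label, opts=opts, t_L=comp.t_L)


def scan_kms_vs_equivalents(
    rates: RateConstants,
    equivalents_list,
    f_label: float = 0.5,
    host_total: float = 1e-5,
    dt: float = 1.0,
    horizons: float = 5.0,
):
    """k_MS as a function of total ligand excess (labelled + unlabelled).

    Each entry of ``equivalents_list`` is the TOTAL ligand-to-host ratio,
    split between pools by ``f_label``. Returns a DataFrame with columns
    (equivalents, k_ms, stderr). The sequence is non-increasing and approaches
    ``k_off`` asymptotically.
    """
    import pandas as pd

    equivalents_list = list(equivalents_list)
    if not equivalents_list or any(e <= 0 for e in equivalents_list):
        raise ValidationError("equivalents_list must be non-empty and positive")
    if sorted(equivalents_list) != equivalents_list:
        raise ValidationError("equivalents_list must be sorted ascending")
    rows = []
    for eq in equivalents_list:
        comp = SolutionComposition.from_equivalents(
            host_total,
            equiv_unlabelled=(1.0 - f_label) * eq,
            equiv_labelled=f_label * eq,
        )
        obs = predict_kms(rates, comp, dt=dt, horizons=horizons)
        rows.append({"equivalents": eq, "k_ms": obs.k_ms, "stderr": obs.stderr})
    return pd.DataFrame(rows)
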