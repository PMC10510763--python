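"""Synthetic DRL datasets from known ground truth.

Emulates what the instrument records during a delayed-labelling run: bound
isotopologue complexes give ion intensities proportional to their solution
concentrations (equal ionization efficiency for isotopologues, configurable
response factors otherwise), degraded by

* multiplicative spray drift — one common-mode factor per time point shared
  by every species, the dominant ESI instability and the reason relative
  intensities are the robust observable;
* additive baseline noise (detector floor at zero);
* optional Poisson-like shot noise with variance proportional to intensity.

It can also render each time point into a centroided peak list with
nominal-mass isotope envelopes, so that the extraction stage (XIC windows,
envelope-overlap correction) can be exercised end-to-end; a light species'
M+5 line overlaps the monoisotopic line of its D5-labelled partner exactly
as in real spectra.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ISOTOPE_ABUNDANCES
from .containers import TimeTraces
from .exceptions import ValidationError
from .kinetics import (
    RateConstants,
    SolutionComposition,
    TwoSiteRateConstants,
    simulate_single_site,
    simulate_two_site,
)

__all__ = [
    "NoiseModel",
    "SpeciesSpec",
    "IsotopePattern",
    "isotope_pattern",
    "parse_formula",
    "generate_drl_dataset",
    "render_spectra",
    "apply_crosstalk",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of the synthetic instrument.

    spray_drift_sd is the relative SD of the per-time-point common-mode
    factor (default 0.10, a typical ESI infusion stability); additive_sd is
    in absolute intensity units; shot_scale links intensity to variance
    (var = shot_scale * intensity).
    """

    spray_drift_sd: float = 0.10
    additive_sd: float = 0.0
    shot_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spray_drift_sd", "additive_sd", "shot_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def quiet(cls, seed: int = 0) -> "NoiseModel":
        return cls(spray_drift_sd=0.0, additive_sd=0.0, shot_scale=0.0, seed=seed)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict) -> dict[str, int]:
    """Element->count map from a Hill-style formula string (supports D)."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValidationError(f"cannot parse formula {formula!r}")
    for el, n in counts.items():
        if el not in ISOTOPE_ABUNDANCES:
            raise ValidationError(f"unknown element symbol {el!r}")
        if n < 0:
            raise ValidationError(f"negative count for element {el!r}")
    return counts


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated nominal-mass isotope envelope."""

    offsets: tuple[int, ...]  # Da from monoisotopic, increasing
    abundances: tuple[float, ...]  # sum to 1

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets)
        ab = np.asarray(self.abundances)
        if off.size != ab.size or off.size == 0:
            raise ValidationError("offsets and abundances must be equal-length, non-empty")
        if np.any(off < 0) or np.any(np.diff(off) <= 0):
            raise ValidationError("offsets must be non-negative and increasing")
        if abs(ab.sum() - 1.0) > 1e-9 or np.any(ab < 0):
            raise ValidationError("abundances must be >= 0 and sum to 1")

    def abundance_at(self, offset: int) -> float:
        try:
            return self.abundances[self.offsets.index(offset)]
        except ValueError:
            return 0.0

    @classmethod
    def single_line(cls) -> "IsotopePattern":
        return cls(offsets=(0,), abundances=(1.0,))


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """dist convolved with itself n times (binary exponentiation)."""
    result = np.array([1.0])
    base = dist
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def isotope_pattern(formula: str | dict, abundance_floor: float = 1e-6) -> IsotopePattern:
    """Nominal-mass isotope envelope of an elemental composition.

    Per-element multinomial distributions (natural abundances from a fixed
    published table) are convolved across the formula, truncated below
    ``abundance_floor`` and renormalized. Fine isotopic structure within a
    nominal mass is deliberately aggregated: envelope overlap at integer
    mass shifts is all the DRL workflow needs.
    """
    if not 0.0 <= abundance_floor < 1.0:
        raise ValidationError("abundance_floor must be in [0, 1)")
    counts = parse_formula(formula)
    envelope = np.array([1.0])
    for el, n in counts.items():
        if n == 0:
            continue
        iso = ISOTOPE_ABUNDANCES[el]
        width = iso[-1][0] + 1
        dist = np.zeros(width)
        for off, ab in iso:
            dist[off] = ab
        envelope = np.convolve(envelope, _convolve_power(dist, n))
    keep = envelope >= abundance_floor
    if not keep.any():
        raise ValidationError("abundance_floor removes the entire pattern")
    offsets = np.nonzero(keep)[0]
    abund = envelope[keep]
    abund = abund / abund.sum()
    return IsotopePattern(offsets=tuple(int(o) for o in offsets), abundances=tuple(abund))


@dataclass(frozen=True)
class SpeciesSpec:
    """One detected ion: name, monoisotopic m/z, optional composition."""

    name: str
    mz: float
    formula: str | dict | None = None
    response_factor: float = 1.0  # isotopologues share ionization efficiency
    charge: int = 1
    pattern: IsotopePattern | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError("mz must be > 0")
        if self.response_factor <= 0:
            raise ValidationError("response_factor must be > 0")
        if self.charge < 1:
            raise ValidationError("charge must be >= 1")

    def resolve_pattern(self, abundance_floor: float = 1e-6) -> IsotopePattern:
        if self.pattern is not None:
            return self.pattern
        if self.formula is not None:
            return isotope_pattern(self.formula, abundance_floor)
        raise ValidationError(f"species {self.name!r} has neither a formula nor a pattern")


def generate_drl_dataset(
    truth: RateConstants | TwoSiteRateConstants,
    comp: SolutionComposition,
    species: dict[str, SpeciesSpec],
    noise: NoiseModel,
    times,
    intensity_scale: float = 1.0,
) -> TimeTraces:
    """Noisy intensity traces from ground-truth kinetics.

    ``species`` maps the model's observable class names (single site:
    bound_unlabelled/bound_labelled; two-site: PP/PL/LL) one-to-one onto
    detected ions. Intensity = intensity_scale * response_factor *
    concentration, then perturbed by the noise model; runs with the same seed
    are bit-identical.
    """
    if isinstance(truth, TwoSiteRateConstants):
        traj = simulate_two_site(truth, comp, times)
    elif isinstance(truth, RateConstants):
        traj = simulate_single_site(truth, comp, times)
    else:
        raise ValidationError("truth must be RateConstants or TwoSiteRateConstants")
    classes = set(traj.observable_classes)
    if set(species) != classes:
        raise ValidationError(
            f"species keys {sorted(species)} must match observable classes {sorted(classes)}"
        )
    rng = np.random.default_rng(noise.seed)
    n = traj.times.size
    # common-mode spray factor, lognormal with unit mean, shared by all species
    if noise.spray_drift_sd > 0:
        sigma = np.sqrt(np.log1p(noise.spray_drift_sd**2))
        drift = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
    else:
        drift = np.ones(n)
    intensities: dict[str, np.ndarray] = {}
    for cls_name, spec in species.items():
        clean = intensity_scale * spec.response_factor * np.clip(traj.species[cls_name], 0, None)
        signal = clean * drift
        if noise.shot_scale > 0:
            signal = signal + rng.normal(0.0, 1.0, size=n) * np.sqrt(noise.shot_scale * signal)
        if noise.additive_sd > 0:
            signal = signal + rng.normal(0.0, noise.additive_sd, size=n)
        intensities[spec.name] = np.clip(signal, 0.0, None)
    return TimeTraces(times=traj.times, intensities=intensities)


def apply_crosstalk(traces: TimeTraces, source: str, dest: str, fraction: float) -> TimeTraces:
    """Mix a fraction of one channel into another (post-source fragmentation).

    Bis-ligand complexes can shed one ligand in the transfer region and land
    in the 1:1 channel; this moves ``fraction`` of the source intensity into
    the destination channel.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must be in [0, 1)")
    out = {k: v.copy() for k, v in traces.intensities.items()}
    moved = fraction * out[source]
    out[source] = out[source] - moved
    out[dest] = out[dest] + moved
    return TimeTraces(times=traces.times, intensities=out)


def render_spectra(
    traces: TimeTraces,
    species: list[SpeciesSpec],
    mz_sigma: float = 0.0,
    abundance_floor: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Centroided peak-list series (time_s, mz, intensity) from traces.

    Each species contributes one centroid per isotope-envelope line at
    mz + offset/charge, with intensity = trace * abundance. ``mz_sigma`` > 0
    adds Gaussian centroid jitter (calibration noise). Overlapping species
    (e.g. a light ion's M+5 on its D5 partner's monoisotopic line) emit
    separate rows at the same m/z; downstream XIC windows sum them.
    """
    if mz_sigma > 0 and rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for spec in species:
        if spec.name not in traces.intensities:
            raise ValidationError(f"no trace for species {spec.name!r}")
        pattern = spec.resolve_pattern(abundance_floor)
        trace = traces[spec.name]
        for off, ab in zip(pattern.offsets, pattern.abundances):
            mz = spec.mz + off / spec.charge
            mzs = np.full(traces.times.size, mz)
            if mz_sigma > 0:
                mzs = mzs + rng.normal(0.0, mz_sigma, size=mzs.size)
            rows.append(
                pd.DataFrame(
                    {"time_s": traces.times, "mz": mzs, "intensity": trace * ab}
                )
            )
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["time_s", "mz"], kind="stable")
        .reset_index(drop=True)
    )


def write_truth_sidecar(path, truth, comp: SolutionComposition, noise: NoiseModel) -> None:
    """Echo ground-truth parameters next to a dataset for recovery tests."""
    if isinstance(truth, TwoSiteRateConstants):
        truth_d = {
            "model": "two_site",
            "inner": {"k_on": truth.inner.k_on, "k_off": truth.inner.k_off},
            "outer": {"k_on": truth.outer.k_on, "k_off": truth.outer.k_off},
        }
    else:
        truth_d = {"model": "single_site", "k_on": truth.k_on, "k_off": truth.k_off}
    payload = {
        "truth": truth_d,
        "composition": {
            "host_total_M": comp.host_total,
            "ligand_unlabelled_M": comp.ligand_unlabelled,
            "ligand_labelled_M": comp.ligand_labelled,
            "t_L_s": comp.t_L,
            "temperature_K": comp.temperature,
            "f_label": comp.f_label,
        },
        "noise": {
            "spray_drift_sd": noise.spray_drift_sd,
            "additive_sd": noise.additive_sd,
            "shot_scale": noise.shot_scale,
            "seed": noise.seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
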