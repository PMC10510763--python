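"""From raw peak lists to the normalized DRL observable.

Pipeline: XIC extraction over closed m/z windows -> optional isotope-envelope
overlap correction (non-negative unmixing) -> within-group normalization to
relative intensities. Includes the bis-complex renormalization: the doubly
unlabelled and doubly labelled ions are normalized together, excluding the
mixed isotopologue, which isolates the slow (cavity-site) exchange as a clean
first-order process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import RelativeTraces, TimeTraces
from .exceptions import ValidationError
from .synthetic import IsotopePattern

logger = logging.getLogger(__name__)

__all__ = [
    "XICWindow",
    "extract_xic",
    "correct_overlap",
    "build_mixing_matrix",
    "normalize_group",
    "renormalize_pair",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_mzml",
]


@dataclass(frozen=True)
class XICWindow:
    """Closed m/z interval [target_mz - half_width, target_mz + half_width]."""

    target_mz: float
    species: str
    half_width: float = 0.5  # Da; default separates unit-spaced isotope lines

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValidationError("half_width must be > 0")
        if self.target_mz <= 0:
            raise ValidationError("target_mz must be > 0")


def read_peaklist_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_s", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ValidationError(f"peak-list CSV missing columns: {sorted(missing)}")
    return df


def write_peaklist_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_mzml(path) -> pd.DataFrame:
    """Centroided mzML -> peak-list DataFrame (time_s, mz, intensity)."""
    from pyteomics import mzml as _mzml

    rows = []
    with _mzml.read(str(path)) as reader:
        for spectrum in reader:
            try:
                scan = spectrum["scanList"]["scan"][0]
                t = float(scan["scan start time"]) * (
                    60.0 if getattr(scan["scan start time"], "unit_info", "") == "minute" else 1.0
                )
            except (KeyError, IndexError):
                raise ValidationError("mzML spectrum lacks a scan start time")
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "mz": spectrum["m/z array"],
                        "intensity": spectrum["intensity array"],
                    }
                )
            )
    if not rows:
        raise ValidationError("mzML file contains no spectra")
    return pd.concat(rows, ignore_index=True)


def extract_xic(peaklists: pd.DataFrame, windows: list[XICWindow]) -> TimeTraces:
    """Sum peak intensities inside each window, per time point.

    Window boundaries are inclusive (a peak exactly on the edge is counted).
    Every time point present in the peak lists appears in the output; windows
    with no peaks at a time point get zero.
    """
    if peaklists.empty:
        raise ValidationError("empty peak-list series")
    if not windows:
        raise ValidationError("no XIC windows given")
    times = np.sort(peaklists["time_s"].unique()).astype(float)
    index = pd.Index(times, name="time_s")
    intensities = {}
    for w in windows:
        sel = (peaklists["mz"] >= w.target_mz - w.half_width) & (
            peaklists["mz"] <= w.target_mz + w.half_width
        )
        series = (
            peaklists.loc[sel].groupby("time_s")["intensity"].sum().reindex(index, fill_value=0.0)
        )
        intensities[w.species] = series.to_numpy(float)
    return TimeTraces(times=times, intensities=intensities)


def build_mixing_matrix(
    windows: list[XICWindow],
    patterns: dict[str, IsotopePattern],
    mz_by_species: dict[str, float],
    charge: int = 1,
) -> pd.DataFrame:
    """Mixing matrix M with M[i, j] = fraction of species j's envelope that
    lands in window i; observed = M @ true."""
    names = [w.species for w in windows]
    M = np.zeros((len(windows), len(names)))
    for i, w in enumerate(windows):
        for j, s in enumerate(names):
            pat = patterns[s]
            mono = mz_by_species[s]
            for off, ab in zip(pat.offsets, pat.abundances):
                mz = mono + off / charge
                if w.target_mz - w.half_width <= mz <= w.target_mz + w.half_width:
                    M[i, j] += ab
    return pd.DataFrame(M, index=names, columns=names)


def correct_overlap(
    traces: TimeTraces,
    mixing: pd.DataFrame,
) -> TimeTraces:
    """Undo isotope-envelope bleed between windows by non-negative unmixing.

    ``mixing`` is a square species x species matrix (rows: observed window,
    columns: true species) such that observed = mixing @ true; it must be
    diagonally dominant (each window is dominated by its own species). Solves
    per time point with non-negative least squares, so corrected intensities
    never go negative on noisy data.
    """
    names = list(mixing.index)
    if list(mixing.columns) != names:
        raise ValidationError("mixing matrix must have identical row/column species")
    missing = set(names) - set(traces.species)
    if missing:
        raise ValidationError(f"traces missing species {sorted(missing)}")
    M = mixing.to_numpy(float)
    diag = np.abs(np.diag(M))
    off_diag = np.abs(M).sum(axis=1) - diag
    if np.any(diag <= off_diag):
        raise ValidationError("mixing matrix must be strictly diagonally dominant")
    if np.linalg.cond(M) > 1e8:
        raise ValidationError("mixing matrix is ill-conditioned")
    obs = np.vstack([traces[n] for n in names])
    true = np.empty_like(obs)
    for t in range(obs.shape[1]):
        true[:, t], _ = nnls(M, obs[:, t])
    out = dict(traces.intensities)
    for i, n in enumerate(names):
        out[n] = true[i]
    return TimeTraces(times=traces.times, intensities=out)


def normalize_group(traces: TimeTraces, group: list[str], group_id: str = "group") -> RelativeTraces:
    """Within-group fractions: intensity / group total, per time point.

    Time points where the whole group is zero are masked (kept in the time
    base, excluded from fitting) and counted in the log — never silently
    dropped.
    """
    missing = set(group) - set(traces.species)
    if missing:
        raise ValidationError(f"group members not in traces: {sorted(missing)}")
    if not group:
        raise ValidationError("empty group")
    stack = np.vstack([traces[s] for s in group])
    total = stack.sum(axis=0)
    mask = total <= 0
    if mask.any():
        logger.warning(
            "group %s: %d all-zero time point(s) masked out of %d",
            group_id,
            int(mask.sum()),
            mask.size,
        )
    safe_total = np.where(mask, 1.0, total)
    fractions = np.where(mask, np.nan, stack / safe_total)
    return RelativeTraces(
        times=traces.times,
        fractions={s: fractions[i] for i, s in enumerate(group)},
        group_id=group_id,
        mask=mask,
    )


def renormalize_pair(
    traces: TimeTraces, species_a: str, species_b: str, group_id: str | None = None
) -> RelativeTraces:
    """Two-member renormalization excluding everything else.

    For bis-ligand complexes, normalizing the doubly-unlabelled and
    doubly-labelled ions together (leaving out the mixed isotopologue) turns
    the slow cavity-site exchange into a single first-order process that the
    standard DRL fit can consume.
    """
    return normalize_group(
        traces, [species_a, species_b], group_id=group_id or f"{species_a}|{species_b}"
    )
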