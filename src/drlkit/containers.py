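"""Shared in-memory containers for time-resolved MS traces.

``TimeTraces`` holds absolute (arbitrary-unit) intensities per species on a
common time grid; ``RelativeTraces`` holds within-group normalized fractions,
the DRL observable. Both round-trip through tidy long-format CSV
(``time_s, species, value``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["TimeTraces", "RelativeTraces"]


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("times must be a non-empty 1-D array")
    if not np.all(np.isfinite(times)):
        raise ValidationError("times must be finite")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    return times


@dataclass
class TimeTraces:
    """Per-species intensity time series on a shared grid.

    Parameters
    ----------
    times : array of float
        Seconds, strictly increasing.
    intensities : mapping of species name -> array
        Non-negative intensities, one array per species, same length as times.
    """

    times: np.ndarray
    intensities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        clean: dict[str, np.ndarray] = {}
        for name, values in self.intensities.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ValidationError(
                    f"intensity series {name!r} has length {arr.size}, expected {self.times.size}"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValidationError(f"intensity series {name!r} must be finite and >= 0")
            clean[name] = arr
        self.intensities = clean

    @property
    def species(self) -> list[str]:
        return list(self.intensities)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.intensities[species]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format DataFrame (time_s, species, intensity)."""
        frames = [
            pd.DataFrame({"time_s": self.times, "species": name, "intensity": vals})
            for name, vals in self.intensities.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeTraces":
        value_col = "intensity" if "intensity" in df.columns else "value"
        wide = df.pivot_table(index="time_s", columns="species", values=value_col, sort=True)
        if wide.isna().any().any():
            raise ValidationError("trace table has missing (time, species) combinations")
        return cls(
            times=wide.index.to_numpy(float),
            intensities={str(c): wide[c].to_numpy(float) for c in wide.columns},
        )

    @classmethod
    def from_csv(cls, path) -> "TimeTraces":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class RelativeTraces:
    """Within-group normalized fractions vs. time (the DRL observable).

    Fractions sum to 1 across the group at every unmasked time point; time
    points where the whole group had zero signal are masked, never dropped,
    so the time base stays aligned with the raw data.
    """

    times: np.ndarray
    fractions: dict[str, np.ndarray]
    group_id: str = "group"
    mask: np.ndarray | None = None  # True = masked (unusable) time point

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        if self.mask is None:
            self.mask = np.zeros(self.times.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.times.shape:
                raise ValidationError("mask length must match times")
        clean: dict[str, np.ndarray] = {}
        for name, values in self.fractions.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ValidationError(
                    f"fraction series {name!r} has length {arr.size}, expected {self.times.size}"
                )
            clean[name] = arr
        self.fractions = clean
        ok = ~self.mask
        if clean and ok.any():
            stacked = np.vstack([v[ok] for v in clean.values()])
            if np.any(stacked < -1e-9) or np.any(stacked > 1 + 1e-9):
                raise ValidationError("fractions must lie in [0, 1]")
            total = stacked.sum(axis=0)
            if np.any(np.abs(total - 1.0) > 1e-9):
                raise ValidationError("group fractions must sum to 1 at every time point")

    @property
    def species(self) -> list[str]:
        return list(self.fractions)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def __getitem__(self, species: str) -> np.ndarray:
        return self.fractions[species]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "time_s": self.times,
                    "species": name,
                    "fraction": vals,
                    "group": self.group_id,
                    "masked": self.mask,
                }
            )
            for name, vals in self.fractions.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RelativeTraces":
        group = str(df["group"].iloc[0]) if "group" in df.columns else "group"
        wide = df.pivot_table(index="time_s", columns="species", values="fraction", sort=True)
        mask = None
        if "masked" in df.columns:
            mask = (
                df.groupby("time_s", sort=True)["masked"].any().to_numpy(bool)
            )
        return cls(
            times=wide.index.to_numpy(float),
            fractions={str(c): wide[c].to_numpy(float) for c in wide.columns},
            group_id=group,
            mask=mask,
        )

    @classmethod
    def from_csv(cls, path) -> "RelativeTraces":
        return cls.from_frame(pd.read_csv(path))
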