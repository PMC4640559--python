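"""Time-series datasets and the weighted-SSE machinery they feed.

Measurements are tidy records of (species, condition, replicate, time_min,
value) in arbitrary units.  Each (species, condition) series carries a
time-independent inverted mean-square weight

    w = n_t / sum_t x(t)^2

so the weighted SSE is invariant to uniform rescaling of any single
series — matching the use of relative (fold-change) densitometry data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesDataset", "DataError", "read_timeseries", "write_timeseries"]

COLUMNS = ("species", "condition", "replicate", "time_min", "value")


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Observed (or synthetic) measurements with fitting weights."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["time_min"] = df["time_min"].astype(float)
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            bad = df.index[df["value"] < 0][0]
            raise DataError(f"negative value at row {bad}")
        dup = df.duplicated(subset=["species", "condition", "replicate", "time_min"])
        if dup.any():
            raise DataError(f"duplicate record at row {df.index[dup][0]}")
        counts = df.groupby(["species", "condition"])["time_min"].nunique()
        if (counts < 2).any():
            name = counts.index[counts < 2][0]
            raise DataError(f"series {name} has fewer than 2 timepoints")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        species: str,
        times: Iterable[float],
        values: Iterable[float],
        condition: str = "serum",
        replicate: int = 1,
    ) -> "TimeSeriesDataset":
        df = pd.DataFrame(
            {
                "species": species,
                "condition": condition,
                "replicate": replicate,
                "time_min": list(times),
                "value": list(values),
            }
        )
        return cls(df)

    @classmethod
    def concat(cls, parts: Iterable["TimeSeriesDataset"]) -> "TimeSeriesDataset":
        return cls(pd.concat([p.records for p in parts], ignore_index=True))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.records["species"].unique())

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.records["condition"].unique())

    def subset(self, species=None, condition=None) -> "TimeSeriesDataset":
        df = self.records
        if species is not None:
            wanted = [species] if isinstance(species, str) else list(species)
            df = df[df["species"].isin(wanted)]
        if condition is not None:
            df = df[df["condition"] == condition]
        if df.empty:
            raise DataError(f"empty subset (species={species}, condition={condition})")
        return TimeSeriesDataset(df)

    def series(self, species: str, condition: str, replicate=None) -> pd.Series:
        """One replicate's series, or the across-replicate median if
        ``replicate`` is None (data-side features are computed on medians)."""
        df = self.records
        df = df[(df["species"] == species) & (df["condition"] == condition)]
        if df.empty:
            raise DataError(f"no series for ({species}, {condition})")
        if replicate is not None:
            df = df[df["replicate"] == replicate]
            return df.set_index("time_min")["value"].sort_index()
        return df.groupby("time_min")["value"].median().sort_index()

    def weights(self) -> dict[tuple[str, str], float]:
        """w_{s,e} = n_t / sum_t x(t)^2 computed on the median series."""
        out: dict[tuple[str, str], float] = {}
        for (s, e), _ in self.records.groupby(["species", "condition"]):
            med = self.series(s, e)
            ssq = float(np.sum(med.to_numpy() ** 2))
            if ssq == 0:
                raise DataError(f"all-zero series ({s}, {e}): weight undefined")
            out[(s, e)] = len(med) / ssq
        return out


def dataset_weights(data: TimeSeriesDataset) -> dict[tuple[str, str], float]:
    """Per-(species, condition) inverted mean-square weights."""
    return data.weights()


def read_timeseries(path: str | Path) -> TimeSeriesDataset:
    """Read a comma-delimited table with the standard header."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return TimeSeriesDataset(df)


def write_timeseries(data: TimeSeriesDataset, path: str | Path,
                     provenance: Mapping[str, str] | None = None) -> None:
    df = data.records.copy()
    for key, value in (provenance or {}).items():
        df[key] = value
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
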