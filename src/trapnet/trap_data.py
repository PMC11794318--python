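"""Data model and I/O for weekly trap-count records.

Counts are kept internally in hundreds of pests.  The response used by the
growth model is the within-season cumulative count, which is non-decreasing
in week by construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRegistry",
    "TrapDataset",
    "CumulativeSeries",
    "read_trap_csv",
    "impute_missing",
    "cumulative_counts",
    "project_coordinates",
]

EARTH_RADIUS_KM = 6371.0

_COUNT_COLUMNS = ["year", "site_id", "week", "count"]
_SITE_COLUMNS = ["site_id", "x_km", "y_km"]


@dataclass(frozen=True)
class SiteRegistry:
    """Candidate trap locations with planar coordinates in kilometres."""

    site_ids: tuple[int, ...]
    coords: np.ndarray  # (L, 2) km

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "site_ids", tuple(int(s) for s in self.site_ids))
        # singletons are allowed so prediction targets can be one site;
        # candidate registries backing a dataset must have >= 2 (checked there)
        if len(self.site_ids) < 1:
            raise ValueError("registry needs at least 1 site")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site ids must be unique")
        if coords.shape != (len(self.site_ids), 2):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.site_ids)} sites"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.site_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def index_of(self, site_id: int) -> int:
        return self.site_ids.index(int(site_id))

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (km)."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def subset(self, site_ids: Iterable[int]) -> "SiteRegistry":
        ids = [int(s) for s in site_ids]
        idx = [self.index_of(s) for s in ids]
        return SiteRegistry(tuple(ids), self.coords[idx])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "site_id": self.site_ids,
                "x_km": self.coords[:, 0],
                "y_km": self.coords[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, lonlat: bool = False) -> "SiteRegistry":
        df = pd.read_csv(path)
        if lonlat:
            missing = {"site_id", "lon", "lat"} - set(df.columns)
            if missing:
                raise ValueError(f"sites file missing columns: {sorted(missing)}")
            coords = project_coordinates(df[["lon", "lat"]].to_numpy(float))
        else:
            missing = set(_SITE_COLUMNS) - set(df.columns)
            if missing:
                raise ValueError(f"sites file missing columns: {sorted(missing)}")
            coords = df[["x_km", "y_km"]].to_numpy(float)
        return cls(tuple(int(s) for s in df["site_id"]), coords)


@dataclass(frozen=True)
class CumulativeSeries:
    """Within-season cumulative counts for one site-year."""

    year: int
    site_id: int
    values: np.ndarray
    strict: bool = True  # False only for raw-noise simulation experiments

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.strict and np.any(np.diff(vals) < -1e-12):
            raise ValueError(
                f"cumulative series for (year={self.year}, site={self.site_id}) "
                "is not non-decreasing"
            )


@dataclass
class TrapDataset:
    """Weekly trap counts indexed by (year, site, week).

    ``records`` holds one row per (year, site_id, week); a NaN ``count``
    marks a flagged-missing cell awaiting imputation.  Site-years with no
    rows at all are treated as absent, not missing.
    """

    registry: SiteRegistry
    records: pd.DataFrame
    imputation_log: list[tuple[int, int, int, float]] = field(default_factory=list)
    allow_negative: bool = False  # simulation escape hatch; field data is never negative

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing_cols = set(_COUNT_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"records missing columns: {sorted(missing_cols)}")
        df = df[_COUNT_COLUMNS].astype(
            {"year": int, "site_id": int, "week": int, "count": float}
        )
        df = df.sort_values(["year", "site_id", "week"]).reset_index(drop=True)
        self.records = df
        self._validate()

    def _validate(self) -> None:
        if len(self.registry) < 2:
            raise ValueError("a trap dataset needs at least 2 candidate sites")
        df = self.records
        dup = df.duplicated(subset=["year", "site_id", "week"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate record for (year=%d, site=%d, week=%d)"
                % (row["year"], row["site_id"], row["week"])
            )
        known = set(self.registry.site_ids)
        unknown = set(df["site_id"]) - known
        if unknown:
            raise ValueError(f"sites in counts absent from registry: {sorted(unknown)}")
        if (df["week"] < 1).any():
            raise ValueError("weeks must be 1-based positive indices")
        observed = df["count"].dropna()
        if not self.allow_negative and (observed < 0).any():
            raise ValueError("negative counts are not allowed")
        # every observed site-year must span the full contiguous week range
        wpy = self.weeks_per_year
        for (year, site), grp in df.groupby(["year", "site_id"]):
            weeks = sorted(grp["week"])
            expect = list(range(1, wpy[year] + 1))
            if weeks != expect:
                raise ValueError(
                    f"site-year (year={year}, site={site}) has weeks {weeks}, "
                    f"expected 1..{wpy[year]} (use NA rows for missing cells)"
                )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.records["year"].unique()))

    @property
    def weeks_per_year(self) -> dict[int, int]:
        return {
            int(y): int(w) for y, w in self.records.groupby("year")["week"].max().items()
        }

    @property
    def site_years(self) -> set[tuple[int, int]]:
        """Observed (site, year) combinations."""
        return {
            (int(s), int(y))
            for y, s in self.records[["year", "site_id"]].drop_duplicates().itertuples(
                index=False
            )
        }

    @property
    def n_missing(self) -> int:
        return int(self.records["count"].isna().sum())

    @property
    def has_missing(self) -> bool:
        return self.n_missing > 0

    def missing_cells(self) -> list[tuple[int, int, int]]:
        rows = self.records[self.records["count"].isna()]
        return [
            (int(r.year), int(r.site_id), int(r.week)) for r in rows.itertuples()
        ]

    def to_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out["count"] = out["count"].map(
            lambda v: "NA" if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        )
        out.to_csv(path, index=False)

    def replace(self, **kwargs) -> "TrapDataset":
        return dataclasses.replace(self, **kwargs)


def project_coordinates(lonlat: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Project (lon, lat) degree pairs to planar km about their centroid.

    Equirectangular projection: ``x = R cos(lat0) dlon``, ``y = R dlat``
    (radians, R = 6371 km).  Accurate for small extents; the centroid maps
    to the origin.
    """
    arr = np.asarray(lonlat, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an array of (lon, lat) pairs")
    lon, lat = arr[:, 0], arr[:, 1]
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude must be in [-180, 180], latitude in [-90, 90]")
    lon0, lat0 = lon.mean(), lat.mean()
    x = EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0)) * np.deg2rad(lon - lon0)
    y = EARTH_RADIUS_KM * np.deg2rad(lat - lat0)
    return np.column_stack([x, y])


def read_trap_csv(
    path: str | Path,
    coord_path: str | Path,
    *,
    lonlat: bool = False,
    counts_in_individuals: bool = False,
) -> TrapDataset:
    """Read counts and site files into a validated :class:`TrapDataset`.

    The counts file has header ``year,site_id,week,count`` with ``NA``
    marking a flagged-missing cell.  ``counts_in_individuals=True`` divides
    raw counts by 100 so the internal unit is hundreds of pests.
    """
    registry = SiteRegistry.from_csv(coord_path, lonlat=lonlat)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing_cols = set(_COUNT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"counts file missing columns: {sorted(missing_cols)}")
    if counts_in_individuals:
        df = df.assign(count=df["count"] / 100.0)
    return TrapDataset(registry, df)


def impute_missing(ds: TrapDataset, *, on: str = "weekly") -> TrapDataset:
    """Fill flagged-missing cells with the mean of all other sites for the
    same year and week.

    ``on="weekly"`` (default) averages weekly counts; ``on="cumulative"``
    averages the running sums of the donors and differences back to a
    weekly count.  Idempotent; only NaN cells change.  The returned
    dataset's ``imputation_log`` lists every imputed (year, site, week,
    value).
    """
    if on not in ("weekly", "cumulative"):
        raise ValueError("on must be 'weekly' or 'cumulative'")
    if not ds.has_missing:
        return ds.replace(imputation_log=list(ds.imputation_log))
    df = ds.records.copy()
    log: list[tuple[int, int, int, float]] = list(ds.imputation_log)
    for year, site, week in ds.missing_cells():
        donors = df[
            (df["year"] == year) & (df["week"] == week) & (df["site_id"] != site)
        ]["count"].dropna()
        if donors.empty:
            raise ValueError(
                f"no donor sites for missing cell (year={year}, week={week})"
            )
        if on == "weekly":
            value = float(donors.mean())
        else:
            donor_sites = df[
                (df["year"] == year)
                & (df["week"] == week)
                & (df["site_id"] != site)
                & df["count"].notna()
            ]["site_id"]
            cums = []
            for d in donor_sites:
                block = df[
                    (df["year"] == year) & (df["site_id"] == d) & (df["week"] <= week)
                ]["count"]
                if block.notna().all():
                    cums.append(float(block.sum()))
            if not cums:
                raise ValueError(
                    f"no complete donor series for cell (year={year}, week={week})"
                )
            prior = df[
                (df["year"] == year) & (df["site_id"] == site) & (df["week"] < week)
            ]["count"]
            value = max(float(np.mean(cums)) - float(prior.sum()), 0.0)
        mask = (
            (df["year"] == year) & (df["site_id"] == site) & (df["week"] == week)
        )
        df.loc[mask, "count"] = value
        log.append((year, site, week, value))
    return TrapDataset(
        ds.registry, df, imputation_log=log, allow_negative=ds.allow_negative
    )


def cumulative_counts(ds: TrapDataset) -> list[CumulativeSeries]:
    """Per site-year running sums over weeks.

    Requires a complete dataset; call :func:`impute_missing` first if any
    cell is flagged missing.
    """
    if ds.has_missing:
        raise ValueError(
            "dataset has flagged-missing cells; run impute_missing first"
        )
    out = []
    for (year, site), grp in ds.records.groupby(["year", "site_id"]):
        vals = grp.sort_values("week")["count"].to_numpy(float)
        out.append(
            CumulativeSeries(
                int(year), int(site), np.cumsum(vals), strict=not ds.allow_negative
            )
        )
    return out


def cumulative_table(ds: TrapDataset) -> dict[tuple[int, int, int], float]:
    """Cumulative counts as a flat map (year, site, week) -> value."""
    table: dict[tuple[int, int, int], float] = {}
    for series in cumulative_counts(ds):
        for w, v in enumerate(series.values, start=1):
            table[(series.year, series.site_id, w)] = float(v)
    return table
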