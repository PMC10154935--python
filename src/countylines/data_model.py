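"""Domain types and file I/O for territory-level origin--destination studies.

The spatial unit is the police force territory. A study consists of a
territory table (population, representative point, optional region tag),
a table of raw social covariates per territory, square origin--destination
matrices of distances (km) and travel times (minutes) between the
territories' most populous places, and observed counts of detected
distribution lines from a single origin (Greater London) per destination
and year.

All tabular formats are plain CSV:

* ``territories.csv`` — ``id,name,population,lon,lat[,region_tag]``
* ``covariates.csv``  — ``id`` plus the six raw covariate columns
* ``od_distance.csv`` / ``od_travel_time.csv`` — square matrices with an
  id header row and id index column
* ``lines.csv``       — long format ``origin,destination,year,count``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ReconciliationError, ValidationError

#: Raw covariate columns, in canonical order.
COVARIATE_NAMES: tuple[str, ...] = (
    "misuse_admissions",
    "poisoning_admissions",
    "police_officers",
    "gdhi",
    "knife_crimes",
    "hospital_beds",
)

#: The five covariates that may enter a retail-model utility as benefits.
#: Daytime hospital beds are a normaliser only, never a benefit.
BENEFIT_NAMES: tuple[str, ...] = (
    "misuse_admissions",
    "poisoning_admissions",
    "police_officers",
    "gdhi",
    "knife_crimes",
)

#: Admissions covariates affected by the per-bed normalisation mode.
ADMISSION_NAMES: tuple[str, ...] = ("misuse_admissions", "poisoning_admissions")

MET_POLICE_ID = "metropolitan-police"
CITY_OF_LONDON_ID = "city-of-london"
LONDON_ID = "london"


@dataclass(frozen=True)
class Territory:
    """A police force territory.

    ``population`` is resident persons; ``lon``/``lat`` hold the coordinates
    of the territory's representative point (its most populous place) —
    geographic for real data, planar km for synthetic studies.
    """

    id: str
    name: str
    population: float
    lon: float
    lat: float
    region_tag: str | None = None

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError(
                f"territory {self.id!r}: population must be > 0, got {self.population}"
            )


@dataclass(frozen=True)
class CovariateTable:
    """Raw (un-normalised) social covariates, one row per territory.

    ``values`` is indexed by territory id with exactly the columns in
    :data:`COVARIATE_NAMES`; all entries are nonnegative yearly totals
    (gdhi is the aggregate disposable income of the territory).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COVARIATE_NAMES) - set(self.values.columns)
        if missing:
            raise FormatError(f"covariate table missing columns: {sorted(missing)}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate territory ids in covariate table")
        if (self.values[list(COVARIATE_NAMES)] < 0).any().any():
            raise ValidationError("covariate values must be >= 0")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class ODMatrix:
    """A square origin--destination matrix of distances (km) or travel
    times (minutes) between territory representative points."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # "distance" | "travel_time"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise FormatError(
                f"OD matrix shape {self.values.shape} does not match {n} ids"
            )
        if self.kind not in ("distance", "travel_time"):
            raise FormatError(f"unknown OD matrix kind {self.kind!r}")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in OD matrix")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError(f"{self.kind} matrix diagonal must be zero")
        off = self.values[~np.eye(n, dtype=bool)]
        if (off <= 0).any():
            raise ValidationError(f"{self.kind} matrix off-diagonal entries must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def row(self, origin: str, destinations: Iterable[str] | None = None) -> pd.Series:
        """Entries from ``origin`` to ``destinations`` (all other ids by default)."""
        frame = self.to_frame()
        if origin not in frame.index:
            raise ReconciliationError(f"origin {origin!r} not in OD matrix")
        if destinations is None:
            destinations = [i for i in self.ids if i != origin]
        return frame.loc[origin, list(destinations)]


@dataclass(frozen=True)
class LineCounts:
    """Observed detected-line counts from one origin in one year.

    ``counts`` maps destination id to a nonnegative integer count; the
    origin never appears among the destinations.
    """

    origin: str
    year: str
    counts: pd.Series

    def __post_init__(self) -> None:
        if self.origin in self.counts.index:
            raise ValidationError(
                f"origin {self.origin!r} must not appear among destinations"
            )
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("line counts must be >= 0")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("line counts must be integers")

    @property
    def total(self) -> float:
        """Total origin outflow T_i = sum of counts over destinations."""
        return float(self.counts.sum())


@dataclass
class Study:
    """A complete origin--destination study: territories, covariates, OD
    matrices and per-year line counts, reconciled to one id set."""

    territories: list[Territory]
    covariates: CovariateTable
    distances: ODMatrix
    travel_times: ODMatrix
    lines: dict[str, LineCounts]
    origin: str = LONDON_ID

    def __post_init__(self) -> None:
        ids = [t.id for t in self.territories]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate territory ids")
        idset = set(ids)
        for label, other in (
            ("covariates", set(self.covariates.ids)),
            ("distance matrix", set(self.distances.ids)),
            ("travel-time matrix", set(self.travel_times.ids)),
        ):
            if other != idset:
                raise ReconciliationError(
                    f"{label} ids do not match territory table "
                    f"(missing {sorted(idset - other)}, extra {sorted(other - idset)})"
                )
        if self.origin not in idset:
            raise ReconciliationError(f"origin {self.origin!r} not a territory")
        for year, lc in self.lines.items():
            extra = set(lc.counts.index) - idset
            if extra:
                raise ReconciliationError(
                    f"line counts {year}: unknown destinations {sorted(extra)}"
                )

    @property
    def destination_ids(self) -> list[str]:
        return [t.id for t in self.territories if t.id != self.origin]

    def population(self) -> pd.Series:
        return pd.Series(
            {t.id: t.population for t in self.territories}, name="population"
        )

    def territory_frame(self) -> pd.DataFrame:
        return territories_to_frame(self.territories)


# ---------------------------------------------------------------------------
# readers / writers


def territories_to_frame(territories: Iterable[Territory]) -> pd.DataFrame:
    rows = [
        {
            "id": t.id,
            "name": t.name,
            "population": t.population,
            "lon": t.lon,
            "lat": t.lat,
            "region_tag": t.region_tag,
        }
        for t in territories
    ]
    return pd.DataFrame(rows).set_index("id")


def read_territories(path: str | Path) -> list[Territory]:
    """Read and validate a territory table.

    Raises :class:`FormatError` on missing columns and
    :class:`ValidationError` on duplicate ids or nonpositive populations.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "name", "population", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"{path}: duplicate territory ids {dupes}")
    tags = df["region_tag"] if "region_tag" in df.columns else [None] * len(df)
    return [
        Territory(
            id=row.id,
            name=str(row.name_),
            population=float(row.population),
            lon=float(row.lon),
            lat=float(row.lat),
            region_tag=None if tag is None or pd.isna(tag) else str(tag),
        )
        for row, tag in zip(
            df.rename(columns={"name": "name_"}).itertuples(index=False), tags
        )
    ]


def write_territories(territories: Iterable[Territory], path: str | Path) -> None:
    territories_to_frame(territories).to_csv(path)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing 'id' column")
    return CovariateTable(df.set_index("id"))


def write_covariates(covariates: CovariateTable, path: str | Path) -> None:
    covariates.values.to_csv(path, index_label="id")


def read_od_matrix(path: str | Path, kind: str) -> ODMatrix:
    """Read a square OD matrix whose header row and index column carry the
    territory ids. Asymmetric id sets raise :class:`ReconciliationError`."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ReconciliationError(f"{path}: row ids differ from column ids")
    if df.isna().any().any():
        raise FormatError(f"{path}: matrix contains missing values")
    return ODMatrix(ids=tuple(df.index), values=df.to_numpy(dtype=float), kind=kind)


def write_od_matrix(matrix: ODMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def read_line_counts(path: str | Path) -> dict[str, LineCounts]:
    """Read long-format line counts and return one :class:`LineCounts`
    per year label (a single origin is required)."""
    df = pd.read_csv(path, dtype={"origin": str, "destination": str, "year": str})
    required = {"origin", "destination", "year", "count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    origins = df["origin"].unique()
    if len(origins) != 1:
        raise FormatError(f"{path}: expected a single origin, found {list(origins)}")
    out: dict[str, LineCounts] = {}
    for year, grp in df.groupby("year"):
        counts = grp.set_index("destination")["count"].astype(float)
        if counts.index.duplicated().any():
            raise ValidationError(f"{path}: duplicate destinations for year {year}")
        out[str(year)] = LineCounts(origin=origins[0], year=str(year), counts=counts)
    return out


def write_line_counts(lines: Mapping[str, LineCounts], path: str | Path) -> None:
    rows = []
    for year in sorted(lines):
        lc = lines[year]
        for dest, count in lc.counts.items():
            rows.append(
                {
                    "origin": lc.origin,
                    "destination": dest,
                    "year": lc.year,
                    "count": int(round(count)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_study(directory: str | Path, origin: str = LONDON_ID) -> Study:
    """Assemble a :class:`Study` from the five canonical CSVs in ``directory``."""
    directory = Path(directory)
    return Study(
        territories=read_territories(directory / "territories.csv"),
        covariates=read_covariates(directory / "covariates.csv"),
        distances=read_od_matrix(directory / "od_distance.csv", kind="distance"),
        travel_times=read_od_matrix(
            directory / "od_travel_time.csv", kind="travel_time"
        ),
        lines=read_line_counts(directory / "lines.csv"),
        origin=origin,
    )


def save_study(study: Study, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_territories(study.territories, directory / "territories.csv")
    write_covariates(study.covariates, directory / "covariates.csv")
    write_od_matrix(study.distances, directory / "od_distance.csv")
    write_od_matrix(study.travel_times, directory / "od_travel_time.csv")
    write_line_counts(study.lines, directory / "lines.csv")


# ---------------------------------------------------------------------------
# transformations


def merge_london(
    territories: list[Territory],
    covariates: CovariateTable,
    lines: Mapping[str, LineCounts] | None = None,
    *,
    met_id: str = MET_POLICE_ID,
    col_id: str = CITY_OF_LONDON_ID,
    merged_id: str = LONDON_ID,
) -> tuple[list[Territory], CovariateTable, dict[str, LineCounts]]:
    """Merge the Metropolitan Police and City of London territories into a
    single Greater London territory.

    Population and every raw covariate are summed; line counts emitted from
    either constituent origin are summed per destination. Normalised rates
    must be recomputed from the merged raw values afterwards — they are
    never averaged. If either constituent id is absent the inputs are
    returned unchanged with a warning.
    """
    lines = dict(lines or {})
    ids = {t.id for t in territories}
    if met_id not in ids or col_id not in ids:
        warnings.warn(
            f"merge_london: {met_id!r} and/or {col_id!r} absent; no merge performed",
            stacklevel=2,
        )
        return list(territories), covariates, lines

    by_id = {t.id: t for t in territories}
    met, col = by_id[met_id], by_id[col_id]
    pop = met.population + col.population
    # representative point: population-weighted mean of the constituents
    lon = (met.lon * met.population + col.lon * col.population) / pop
    lat = (met.lat * met.population + col.lat * col.population) / pop
    merged = Territory(
        id=merged_id,
        name="London",
        population=pop,
        lon=lon,
        lat=lat,
        region_tag=met.region_tag,
    )
    out_terr = [t for t in territories if t.id not in (met_id, col_id)]
    out_terr.insert(0, merged)

    cov = covariates.values
    merged_row = cov.loc[[met_id, col_id]].sum(axis=0)
    cov = cov.drop(index=[met_id, col_id])
    cov = pd.concat([pd.DataFrame([merged_row], index=[merged_id]), cov])
    out_cov = CovariateTable(cov)

    out_lines: dict[str, LineCounts] = {}
    for year, lc in lines.items():
        counts = lc.counts.copy()
        origin = merged_id if lc.origin in (met_id, col_id) else lc.origin
        # counts addressed to the constituents collapse onto the merged id
        inner = [i for i in (met_id, col_id) if i in counts.index]
        if inner:
            merged_count = counts.loc[inner].sum()
            counts = counts.drop(index=inner)
            if merged_count > 0:
                counts.loc[merged_id] = merged_count
        out_lines[year] = LineCounts(origin=origin, year=lc.year, counts=counts)
    # a single origin may arrive as two LineCounts objects (one per constituent)
    return out_terr, out_cov, out_lines


def normalise_covariates(
    territories: list[Territory],
    covariates: CovariateTable,
    admissions_mode: str = "per_100k",
) -> pd.DataFrame:
    """Normalise raw covariates to rates per 100 000 inhabitants.

    In ``per_bed`` mode the two hospital-admissions covariates are instead
    divided by daytime hospital beds per capita (beds / population); every
    other covariate stays per-100k. Returns a DataFrame of benefits w_j^(n)
    indexed by territory id with the five benefit columns.
    """
    if admissions_mode not in ("per_100k", "per_bed"):
        raise ValidationError(f"unknown admissions_mode {admissions_mode!r}")
    pop = pd.Series({t.id: t.population for t in territories})
    cov = covariates.values.loc[pop.index]
    out = pd.DataFrame(index=pop.index)
    for name in BENEFIT_NAMES:
        out[name] = cov[name] * 1e5 / pop
    if admissions_mode == "per_bed":
        beds = cov["hospital_beds"]
        if (beds <= 0).any():
            bad = beds.index[beds <= 0].tolist()
            raise ValidationError(
                f"per_bed normalisation requires beds > 0; offending territories {bad}"
            )
        for name in ADMISSION_NAMES:
            out[name] = cov[name] / (beds / pop)
    return out
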