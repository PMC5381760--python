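"""Location records: reading, validation, deduplication and filtering.

A record is one georeferenced individual with a coat-colour phenotype and a
provenance label.  Filtering follows three rules, applied in a fixed order so
removal counts reconcile: (1) record age relative to a reference year,
(2) exact coordinate duplicates, (3) excessive vegetation-index change at the
record location.  Camera-trap records additionally get a buffer-based
deduplication to avoid double-counting the same individual.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import pairwise_haversine_km
from .raster import Raster

__all__ = [
    "PHENOTYPES",
    "SOURCES",
    "LocationRecord",
    "FilterReport",
    "read_records",
    "write_records",
    "records_to_frame",
    "modelling_eligible",
    "dedup_camera_traps",
    "filter_records",
    "assign_biomes",
    "attach_env_values",
]

PHENOTYPES = ("melanistic", "non_melanistic", "unconfirmed_melanistic")
SOURCES = ("museum", "field_capture", "camera_trap", "communication")

DEFAULT_DEDUP_DIAMETER_KM = 25.0
DEFAULT_MAX_AGE_YEARS = 20
DEFAULT_NDVI_CUTOFF = 0.7


@dataclass
class LocationRecord:
    """One georeferenced individual."""

    id: str
    lon: float
    lat: float
    phenotype: str
    source: str = "communication"
    year: int | None = None
    #: set when the record is a camera-trap image of a visually identified
    #: individual; such records are never merged by the buffer dedup rule
    identified_individual: bool = False
    biome: str | None = None
    env_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon = float(self.lon)
        self.lat = float(self.lat)
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"record {self.id}: longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"record {self.id}: latitude {self.lat} outside [-90, 90]")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"record {self.id}: unknown phenotype {self.phenotype!r}; "
                f"expected one of {PHENOTYPES}"
            )
        if self.source not in SOURCES:
            raise ValueError(
                f"record {self.id}: unknown source {self.source!r}; expected one of {SOURCES}"
            )


@dataclass
class FilterReport:
    """Reconciled accounting of the record-filtering stage."""

    n_input: int
    n_removed_age: int
    n_removed_duplicate: int
    n_removed_ndvi: int
    n_output: int
    removed_ids: list[str] = field(default_factory=list)
    n_unfilterable: int = 0

    def __post_init__(self) -> None:
        removed = self.n_removed_age + self.n_removed_duplicate + self.n_removed_ndvi
        if self.n_output != self.n_input - removed:
            raise ValueError("FilterReport counts do not reconcile")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


_REQUIRED_COLUMNS = ("id", "lon", "lat", "phenotype")


def read_records(path: str | Path) -> list[LocationRecord]:
    """Read a record CSV (columns: id, lon, lat, phenotype[, source, year])."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: record table is empty")
        return []
    records = []
    for idx, row in df.iterrows():
        try:
            lon = float(row["lon"])
            lat = float(row["lat"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {idx}: malformed coordinates ({exc})") from None
        year = row.get("year")
        year = None if pd.isna(year) else int(year)
        try:
            records.append(
                LocationRecord(
                    id=str(row["id"]),
                    lon=lon,
                    lat=lat,
                    phenotype=str(row["phenotype"]),
                    source=str(row.get("source", "communication")),
                    year=year,
                    identified_individual=bool(row.get("identified_individual", False)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx}: {exc}") from None
    return records


def records_to_frame(records: Sequence[LocationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "lon": r.lon,
                "lat": r.lat,
                "phenotype": r.phenotype,
                "source": r.source,
                "year": r.year,
                "identified_individual": r.identified_individual,
                "biome": r.biome,
            }
        )
    return pd.DataFrame(rows, columns=["id", "lon", "lat", "phenotype", "source", "year",
                                       "identified_individual", "biome"])


def write_records(records: Sequence[LocationRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def modelling_eligible(records: Iterable[LocationRecord]) -> list[LocationRecord]:
    """Drop unconfirmed-melanistic records (conservatively treated as absent)."""
    return [r for r in records if r.phenotype != "unconfirmed_melanistic"]


def dedup_camera_traps(
    records: Sequence[LocationRecord],
    diameter_km: float = DEFAULT_DEDUP_DIAMETER_KM,
) -> list[LocationRecord]:
    """Collapse same-phenotype camera-trap records within a buffer diameter.

    Among camera-trap records of identical phenotype whose pairwise distance is
    below ``diameter_km``, only the first of each connected cluster is kept,
    except records flagged as visually identified individuals, which are always
    retained.
    """
    keep = [True] * len(records)
    cam_idx = [
        i
        for i, r in enumerate(records)
        if r.source == "camera_trap" and not r.identified_individual
    ]
    for phen in PHENOTYPES:
        group = [i for i in cam_idx if records[i].phenotype == phen]
        if len(group) < 2:
            continue
        lon = [records[i].lon for i in group]
        lat = [records[i].lat for i in group]
        dist = pairwise_haversine_km(lon, lat)
        # union-find over the "closer than the buffer" graph
        parent = list(range(len(group)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                if dist[a, b] < diameter_km:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        for a in range(len(group)):
            if find(a) != a:
                keep[group[a]] = False
    return [r for i, r in enumerate(records) if keep[i]]


def filter_records(
    records: Sequence[LocationRecord],
    reference_year: int,
    ndvi_change: Raster | None = None,
    ndvi_cutoff: float = DEFAULT_NDVI_CUTOFF,
    max_age_years: int = DEFAULT_MAX_AGE_YEARS,
) -> tuple[list[LocationRecord], FilterReport]:
    """Apply the age / exact-duplicate / vegetation-change filters, in order.

    A record failing several rules is charged to the first rule that catches
    it.  Records whose location falls outside the ``ndvi_change`` raster are
    kept and counted as unfilterable.
    """
    removed_age: list[str] = []
    removed_dup: list[str] = []
    removed_ndvi: list[str] = []
    n_unfilterable = 0

    survivors: list[LocationRecord] = []
    for r in records:
        if r.year is not None and (reference_year - r.year) >= max_age_years:
            removed_age.append(r.id)
        else:
            survivors.append(r)

    seen: dict[tuple[float, float], int] = {}
    stage2: list[LocationRecord] = []
    for r in survivors:
        key = (r.lon, r.lat)
        if key in seen:
            prev_i = seen[key]
            prev = stage2[prev_i]
            # keep the melanistic member of a conflicting duplicate pair
            if r.phenotype == "melanistic" and prev.phenotype != "melanistic":
                warnings.warn(
                    f"duplicate coordinates with phenotype conflict at {key}: "
                    f"keeping melanistic record {r.id}, dropping {prev.id}"
                )
                removed_dup.append(prev.id)
                stage2[prev_i] = r
            else:
                if r.phenotype != prev.phenotype:
                    warnings.warn(
                        f"duplicate coordinates with phenotype conflict at {key}: "
                        f"keeping {prev.id}, dropping {r.id}"
                    )
                removed_dup.append(r.id)
        else:
            seen[key] = len(stage2)
            stage2.append(r)

    stage3: list[LocationRecord] = []
    if ndvi_change is None:
        stage3 = stage2
    else:
        for r in stage2:
            val = float(ndvi_change.sample([r.lon], [r.lat])[0])
            if np.isnan(val):
                warnings.warn(
                    f"record {r.id} outside vegetation-change raster; kept unfiltered"
                )
                n_unfilterable += 1
                stage3.append(r)
            elif abs(val) >= ndvi_cutoff:
                removed_ndvi.append(r.id)
            else:
                stage3.append(r)

    report = FilterReport(
        n_input=len(records),
        n_removed_age=len(removed_age),
        n_removed_duplicate=len(removed_dup),
        n_removed_ndvi=len(removed_ndvi),
        n_output=len(stage3),
        removed_ids=removed_age + removed_dup + removed_ndvi,
        n_unfilterable=n_unfilterable,
    )
    return stage3, report


def assign_biomes(
    records: Sequence[LocationRecord],
    biome_layer: Raster,
    labels: dict[int, str] | None = None,
) -> list[LocationRecord]:
    """Set each record's biome from the containing raster cell.

    ``labels`` optionally maps integer cell codes to names; otherwise the code
    itself (as ``biome_<k>``) is used.  Records on nodata or off-grid get a
    missing biome with a warning.
    """
    out = []
    for r in records:
        val = float(biome_layer.sample([r.lon], [r.lat])[0])
        r2 = dataclasses.replace(r)
        if np.isnan(val):
            warnings.warn(f"record {r.id} falls on nodata/off-grid; biome set to missing")
            r2.biome = None
        else:
            code = int(round(val))
            r2.biome = labels[code] if labels else f"biome_{code}"
        out.append(r2)
    return out


def attach_env_values(records: Sequence[LocationRecord], env) -> list[LocationRecord]:
    """Store per-layer environmental values on each record."""
    lon = [r.lon for r in records]
    lat = [r.lat for r in records]
    sampled = env.sample(lon, lat)
    out = []
    for i, r in enumerate(records):
        r2 = dataclasses.replace(r)
        r2.env_values = {name: float(vals[i]) for name, vals in sampled.items()}
        out.append(r2)
    return out
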