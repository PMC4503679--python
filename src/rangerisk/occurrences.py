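"""Occurrence records: validation, deduplication and candidate selection.

The candidate-selection pipeline mirrors the sequential accounting used in
herbarium-based Red List screening: species with no georeferenced records
are dropped first, then single-country species (the assessment targets
regional endemics present in more than one country), then species with any
record below the montane altitude threshold, then taxonomic synonyms.
Each excluded species is attributed to the *first* rule it fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grids import Grid

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["species_id", "lon", "lat", "elevation_m", "country"]

#: decimal places used for coordinate identity during deduplication
DEDUP_DECIMALS = 6


@dataclass
class OccurrenceSet:
    """Georeferenced records for one species.

    ``df`` holds columns lon, lat, elevation_m, country (elevation and
    country may be NaN/None until assigned).
    """

    species_id: str
    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = {"lon", "lat"} - set(self.df.columns)
        if missing:
            raise ValueError(f"{self.species_id}: missing columns {missing}")
        for col in ("elevation_m", "country"):
            if col not in self.df.columns:
                self.df[col] = np.nan
        bad = (self.df.lon.abs() > 180) | (self.df.lat.abs() > 90)
        if bad.any():
            raise ValueError(f"{self.species_id}: coordinates out of range")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def points(self) -> np.ndarray:
        return self.df[["lon", "lat"]].to_numpy(dtype=float)

    @property
    def countries(self) -> set:
        return set(self.df.country.dropna().unique())


def make_set(species_id, lon, lat, elevation_m=None, country=None, provenance=""):
    """Convenience constructor from parallel arrays."""
    df = pd.DataFrame({"lon": np.asarray(lon, dtype=float), "lat": np.asarray(lat, dtype=float)})
    df["elevation_m"] = np.nan if elevation_m is None else np.asarray(elevation_m, dtype=float)
    df["country"] = None if country is None else list(country)
    return OccurrenceSet(species_id, df, provenance)


def dedupe(occ: OccurrenceSet) -> OccurrenceSet:
    """One record per distinct (lon, lat), first occurrence kept, order stable.

    Coordinate identity is exact equality after rounding to 6 decimals
    (~0.1 m), which collapses herbarium re-entries that differ only in
    metadata. Idempotent.
    """
    key = occ.df[["lon", "lat"]].round(DEDUP_DECIMALS)
    keep = ~key.duplicated(keep="first")
    return OccurrenceSet(occ.species_id, occ.df.loc[keep].reset_index(drop=True), occ.provenance)


def assign_elevation(occ: OccurrenceSet, terrain: Grid) -> tuple[OccurrenceSet, int]:
    """Set elevation_m from the DEM cell containing each record.

    Point-in-cell uses half-open intervals [west, east) x (south, north],
    so edge points are assigned to exactly one cell. Out-of-extent records
    are flagged invalid and excluded; the count of such records is
    returned alongside the cleaned set. DEM elevation overrides any
    previously reported elevation.
    """
    row, col, inside = terrain.cell_index(occ.df.lon.to_numpy(), occ.df.lat.to_numpy())
    n_invalid = int((~inside).sum())
    if n_invalid:
        log.warning("%s: %d record(s) outside DEM extent flagged invalid_georeference",
                    occ.species_id, n_invalid)
    df = occ.df.loc[inside].reset_index(drop=True).copy()
    df["elevation_m"] = terrain.data[row[inside], col[inside]]
    return OccurrenceSet(occ.species_id, df, occ.provenance), n_invalid


@dataclass
class FilterReport:
    """Per-rule exclusion counts for a candidate-selection run.

    Invariant: initial == len(survivors) + sum of exclusion counts.
    """

    initial: int
    exclusions: dict[str, int]
    survivors: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # species_id -> rule

    def __post_init__(self) -> None:
        total = len(self.survivors) + sum(self.exclusions.values())
        if total != self.initial:
            raise ValueError(
                f"filter accounting broken: {self.initial} initial vs "
                f"{len(self.survivors)} survivors + {sum(self.exclusions.values())} excluded"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "initial": self.initial,
                "exclusions": self.exclusions,
                "n_survivors": len(self.survivors),
                "survivors": list(self.survivors),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


RULES = ("no_georeference", "single_country", "below_altitude", "taxonomy")


def _first_failure(occ: OccurrenceSet, synonyms: set, threshold_m: float) -> str | None:
    if len(occ) == 0 or occ.df.elevation_m.isna().all():
        return "no_georeference"
    if len(occ.countries) < 2:
        return "single_country"
    if (occ.df.elevation_m < threshold_m).any():
        return "below_altitude"
    if occ.species_id in synonyms:
        return "taxonomy"
    return None


def select_candidates(
    species_sets: Mapping[str, OccurrenceSet],
    synonyms: Iterable[str] = (),
    threshold_m: float = 1500.0,
) -> FilterReport:
    """Run the full exclusion pipeline and account for every species.

    Order: no georeferenced records -> single country -> any record below
    ``threshold_m`` -> taxonomic synonym. A species survives iff it fails
    none of the rules; excluded species are attributed to the first
    failing rule.
    """
    synonyms = set(synonyms)
    counts = {rule: 0 for rule in RULES}
    survivors: list[str] = []
    excluded: dict[str, str] = {}
    for sid, occ in species_sets.items():
        rule = _first_failure(occ, synonyms, threshold_m)
        if rule is None:
            survivors.append(sid)
        else:
            counts[rule] += 1
            excluded[sid] = rule
            log.debug("excluded %s: %s", sid, rule)
    return FilterReport(len(species_sets), counts, survivors, excluded)


def altitude_filter(
    species_sets: Mapping[str, OccurrenceSet], threshold_m: float = 1500.0
) -> FilterReport:
    """Single-rule report: a species survives iff *every* record is at or
    above ``threshold_m`` (a record at exactly the threshold does not
    exclude). Species with no records are counted as no_georeference."""
    counts = {"no_georeference": 0, "below_altitude": 0}
    survivors, excluded = [], {}
    for sid, occ in species_sets.items():
        if len(occ) == 0 or occ.df.elevation_m.isna().all():
            counts["no_georeference"] += 1
            excluded[sid] = "no_georeference"
        elif (occ.df.elevation_m < threshold_m).any():
            counts["below_altitude"] += 1
            excluded[sid] = "below_altitude"
        else:
            survivors.append(sid)
    return FilterReport(len(species_sets), counts, survivors, excluded)


def multi_country_filter(species_sets: Mapping[str, OccurrenceSet]) -> FilterReport:
    """Survivor iff records span at least two distinct countries."""
    counts = {"single_country": 0}
    survivors, excluded = [], {}
    for sid, occ in species_sets.items():
        if len(occ.countries) >= 2:
            survivors.append(sid)
        else:
            if not occ.countries:
                log.warning("%s: no country labels; treated as single-country", sid)
            counts["single_country"] += 1
            excluded[sid] = "single_country"
    return FilterReport(len(species_sets), counts, survivors, excluded)


def modelling_eligibility(
    species_sets: Mapping[str, OccurrenceSet], min_records: int = 5
) -> dict[str, list[str]]:
    """Partition species by record count after deduplication.

    modellable: >= min_records unique records (distribution model fitted);
    mcp_only: 3 .. min_records-1 records (a convex hull exists but the
    species is excluded from modelling); data_deficient: < 3 records (no
    hull is defined).
    """
    out: dict[str, list[str]] = {"modellable": [], "mcp_only": [], "data_deficient": []}
    for sid, occ in species_sets.items():
        n = len(dedupe(occ))
        if n >= min_records:
            out["modellable"].append(sid)
        elif n >= 3:
            out["mcp_only"].append(sid)
        else:
            out["data_deficient"].append(sid)
    return out


def write_occurrences_csv(species_sets: Mapping[str, OccurrenceSet], path: str | Path) -> None:
    frames = []
    for sid, occ in species_sets.items():
        df = occ.df.copy()
        df.insert(0, "species_id", sid)
        frames.append(df[RECORD_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_occurrences_csv(path: str | Path) -> dict[str, OccurrenceSet]:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns {missing}")
    out = {}
    for sid, grp in df.groupby("species_id", sort=False):
        out[str(sid)] = OccurrenceSet(
            str(sid), grp.drop(columns="species_id").reset_index(drop=True), str(path)
        )
    return out
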