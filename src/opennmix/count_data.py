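"""Data model and I/O for multi-site count time series.

The data unit is one seasonal total count of adult animals per site and
year (volunteer "toad patrol" totals at road-crossing sites).  Series are
ragged: sites start in different calendar years, run for different lengths,
and may skip years.  A recorded count of 0 is a valid observation (the site
was surveyed and nothing was found); a missing year is a gap and is *not*
a zero.

Two table layouts are supported: a long table with columns
``site,year,count`` (optionally ``region``/``species``) and a wide
site x year matrix whose empty cells mark gaps.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteSeries",
    "CountDataset",
    "PeriodScheme",
    "RegionMap",
    "DatasetSummary",
    "DialectError",
    "ParseError",
    "read_count_table",
    "write_count_table",
    "filter_min_years",
    "restrict_years",
    "assign_uk_region",
    "dataset_summary",
    "stratum_key",
    "UK_SCHEME",
    "CH_SCHEME",
    "PRESET_SCHEMES",
    "UK_REGIONS",
]


class DialectError(ValueError):
    """Raised when a count table's layout cannot be recognised."""


class ParseError(ValueError):
    """Raised when a cell of a count table cannot be parsed."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSeries:
    """One site's count time series: ``counts[k]`` animals in ``years[k]``.

    Parameters
    ----------
    site_id
        Opaque site identifier, unique within a dataset.
    years
        Strictly increasing calendar years with an observation.
    counts
        Non-negative integer seasonal totals aligned with ``years``.
    species, region
        Optional labels carried through filtering and model fitting.
    """

    site_id: str
    years: tuple[int, ...]
    counts: tuple[int, ...]
    species: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)
        if len(years) == 0:
            raise ValueError(f"site {self.site_id!r}: series needs >= 1 observation")
        if len(years) != len(counts):
            raise ValueError(f"site {self.site_id!r}: years and counts differ in length")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"site {self.site_id!r}: years must be strictly increasing")
        if any(c < 0 for c in counts):
            raise ValueError(f"site {self.site_id!r}: negative count")

    @property
    def first_year(self) -> int:
        return self.years[0]

    @property
    def last_year(self) -> int:
        return self.years[-1]

    @property
    def n_obs(self) -> int:
        """Number of observed (surveyed) years."""
        return len(self.years)

    @property
    def span(self) -> int:
        """Calendar years from first to last observation, inclusive."""
        return self.last_year - self.first_year + 1

    def observed(self, year: int) -> bool:
        return year in set(self.years)

    def count_in(self, year: int) -> int:
        return self.counts[self.years.index(year)]


@dataclass(frozen=True)
class CountDataset:
    """A collection of :class:`SiteSeries` for one species and country."""

    series: tuple[SiteSeries, ...]
    species: str | None = None
    country: str | None = None

    def __post_init__(self) -> None:
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        ids = [s.site_id for s in series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site ids: {dup}")
        labels = {s.species for s in series if s.species is not None}
        if len(labels) > 1:
            raise ValueError(f"mixed species labels in one dataset: {sorted(labels)}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def n_sites(self) -> int:
        return len(self.series)

    @property
    def year_range(self) -> tuple[int, int] | None:
        if not self.series:
            return None
        return (min(s.first_year for s in self.series),
                max(s.last_year for s in self.series))

    def site(self, site_id: str) -> SiteSeries:
        for s in self.series:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    # convenience wrappers over the module-level operations
    def filter_min_years(self, min_years: int = 5) -> "CountDataset":
        return filter_min_years(self, min_years)

    def restrict_years(self, start: int, end: int) -> "CountDataset":
        return restrict_years(self, start, end)

    def summary(self) -> "DatasetSummary":
        return dataset_summary(self)


# ---------------------------------------------------------------------------
# period schemes (decade strata)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodScheme:
    """Contiguous, non-overlapping calendar windows indexing model strata.

    Growth rate and detection probability are held constant within a
    period (a decade in the national analyses) and may differ between
    periods.
    """

    periods: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        periods = tuple((int(a), int(b)) for a, b in self.periods)
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "labels", tuple(self.labels))
        if not periods:
            raise ValueError("scheme needs >= 1 period")
        if len(periods) != len(self.labels):
            raise ValueError("one label per period required")
        for (a, b) in periods:
            if b < a:
                raise ValueError(f"period ({a}, {b}) has non-positive width")
        for (a1, b1), (a2, b2) in zip(periods, periods[1:]):
            if a2 != b1 + 1:
                raise ValueError(
                    f"periods must be contiguous and ordered; gap/overlap between "
                    f"({a1},{b1}) and ({a2},{b2})"
                )

    @classmethod
    def decades(cls, start: int, end: int, width: int = 10,
                labels: Sequence[str] | None = None) -> "PeriodScheme":
        """Equal-width windows covering [start, end]."""
        if (end - start + 1) % width:
            raise ValueError("window not divisible into equal periods")
        periods = tuple((a, a + width - 1) for a in range(start, end + 1, width))
        if labels is None:
            labels = tuple(f"{a}-{b}" for a, b in periods)
        return cls(periods, tuple(labels))

    @property
    def start(self) -> int:
        return self.periods[0][0]

    @property
    def end(self) -> int:
        return self.periods[-1][1]

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def covers(self, year: int) -> bool:
        return self.start <= year <= self.end

    def index_for(self, year: int) -> int:
        if not self.covers(year):
            raise KeyError(f"year {year} outside scheme {self.start}-{self.end}")
        for k, (a, b) in enumerate(self.periods):
            if a <= year <= b:
                return k
        raise AssertionError("unreachable")

    def label_for(self, year: int) -> str:
        return self.labels[self.index_for(year)]


#: Decades used for the United Kingdom analysis window (counts restricted
#: to 1985-2014 before fitting).
UK_SCHEME = PeriodScheme.decades(1985, 2014)

#: Decades used for the Switzerland analysis window (1973-2012).
CH_SCHEME = PeriodScheme.decades(1973, 2012)

PRESET_SCHEMES: dict[str, PeriodScheme] = {
    "uk_1985_2014": UK_SCHEME,
    "ch_1973_2012": CH_SCHEME,
}


def stratum_key(period_label: str, region: str | None = None) -> str:
    """Canonical key naming a model stratum: ``"period"`` or ``"region|period"``."""
    return period_label if region is None else f"{region}|{period_label}"


# ---------------------------------------------------------------------------
# UK region lookup
# ---------------------------------------------------------------------------

UK_REGIONS: dict[str, tuple[str, ...]] = {
    "North": ("Scotland", "Northumberland", "Cumbria", "Durham", "Yorkshire",
              "Lancashire", "Cheshire", "Derbyshire"),
    "West": ("Wales", "Shropshire", "Staffordshire", "Herefordshire",
             "Worcestershire", "Gloucestershire", "Wiltshire", "Dorset",
             "Somerset", "Devon", "Cornwall"),
    "Central": ("Nottinghamshire", "Leicestershire", "Northamptonshire",
                "Rutland", "Cambridgeshire", "Warwickshire", "Oxfordshire",
                "Buckinghamshire", "Bedfordshire"),
    "East": ("Lincolnshire", "Norfolk", "Suffolk", "Essex", "Hertfordshire"),
    "South-East": ("Berkshire", "London", "Hampshire", "Surrey", "Kent",
                   "Sussex", "Isle of Wight"),
}

# volunteer-entered variants folded onto the canonical county names
_COUNTY_ALIASES: dict[str, str] = {
    "east sussex": "sussex",
    "west sussex": "sussex",
    "north yorkshire": "yorkshire",
    "south yorkshire": "yorkshire",
    "west yorkshire": "yorkshire",
    "east yorkshire": "yorkshire",
    "east riding of yorkshire": "yorkshire",
    "greater london": "london",
    "county durham": "durham",
}


def _normalise_county(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class RegionMap:
    """County -> region lookup (five UK regions), case-insensitive."""

    lookup: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def uk_default(cls) -> "RegionMap":
        table: dict[str, str] = {}
        for region, counties in UK_REGIONS.items():
            for county in counties:
                table[_normalise_county(county)] = region
        return cls(lookup=table)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.lookup.values()))

    def region_for(self, county: str) -> str:
        key = _normalise_county(county)
        key = _COUNTY_ALIASES.get(key, key)
        try:
            return self.lookup[key]
        except KeyError:
            valid = ", ".join(sorted(self.lookup))
            raise KeyError(
                f"unknown county {county!r}; known counties: {valid}"
            ) from None


def assign_uk_region(county: str, region_map: RegionMap | None = None) -> str:
    """Map a UK county label to one of the five analysis regions."""
    if region_map is None:
        region_map = RegionMap.uk_default()
    return region_map.region_for(county)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _to_count(value, where: str) -> int:
    """Parse a cell into a non-negative integer count."""
    if isinstance(value, str):
        value = value.strip()
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"{where}: count {value!r} is not a number") from None
    if not math.isfinite(f) or f != int(f):
        raise ParseError(f"{where}: count {value!r} is not an integer")
    n = int(f)
    if n < 0:
        raise ParseError(f"{where}: negative count {n}")
    return n


def _read_frame(source) -> pd.DataFrame:
    """Load a delimited text table with all cells kept as strings."""
    if isinstance(source, (str, Path)):
        handle: io.TextIOBase | str | Path = source
    else:
        handle = source
    return pd.read_csv(handle, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def _looks_like_year(label: str) -> bool:
    s = str(label).strip()
    return s.isdigit() and 1000 <= int(s) <= 3000


def _sniff_dialect(df: pd.DataFrame) -> str:
    cols = [str(c).strip().lower() for c in df.columns]
    if {"site", "year", "count"}.issubset(cols):
        return "long"
    year_cols = sum(_looks_like_year(c) for c in df.columns[1:])
    if len(df.columns) >= 2 and year_cols == len(df.columns) - 1:
        return "wide"
    raise DialectError(
        f"cannot recognise table layout from header {list(df.columns)!r}; "
        "expected long columns (site, year, count) or a wide site x year matrix"
    )


def _series_from_records(records: dict[str, dict[int, int]],
                         meta: dict[str, dict[str, str | None]],
                         species: str | None) -> list[SiteSeries]:
    out = []
    for site_id, by_year in records.items():
        years = tuple(sorted(by_year))
        counts = tuple(by_year[y] for y in years)
        m = meta.get(site_id, {})
        out.append(SiteSeries(site_id=site_id, years=years, counts=counts,
                              species=m.get("species", species) or species,
                              region=m.get("region")))
    return out


def read_count_table(source, dialect: str = "auto", species: str | None = None,
                     country: str | None = None) -> CountDataset:
    """Read a delimited count table into a :class:`CountDataset`.

    Parameters
    ----------
    source
        Path or text stream of a delimited (comma/tab/semicolon) table.
    dialect
        ``"long"`` (columns site, year, count and optionally region /
        species), ``"wide"`` (site rows x year columns, blank = gap) or
        ``"auto"`` to sniff from the header.

    Missing cells become gaps in the series, never zero counts.
    """
    df = _read_frame(source)
    if dialect == "auto":
        dialect = _sniff_dialect(df)
    if dialect not in ("long", "wide"):
        raise DialectError(f"unknown dialect {dialect!r}")

    records: dict[str, dict[int, int]] = {}
    meta: dict[str, dict[str, str | None]] = {}

    if dialect == "long":
        cols = {str(c).strip().lower(): c for c in df.columns}
        for required in ("site", "year", "count"):
            if required not in cols:
                raise DialectError(f"long table lacks a {required!r} column")
        for idx, row in df.iterrows():
            where = f"row {idx + 2}"  # 1-based with header line
            site = str(row[cols["site"]]).strip()
            raw_year = row[cols["year"]]
            raw_count = row[cols["count"]]
            if pd.isna(site) or site == "" or site.lower() == "nan":
                raise ParseError(f"{where}: empty site id")
            try:
                year = int(str(raw_year).strip())
            except (TypeError, ValueError):
                raise ParseError(f"{where}: year {raw_year!r} is not an integer") from None
            if pd.isna(raw_count) or str(raw_count).strip() == "":
                continue  # unsurveyed year listed explicitly -> gap
            count = _to_count(raw_count, where)
            by_year = records.setdefault(site, {})
            if year in by_year:
                raise ParseError(f"{where}: duplicate (site, year) = ({site}, {year})")
            by_year[year] = count
            m = meta.setdefault(site, {})
            if "region" in cols and not pd.isna(row[cols["region"]]):
                m["region"] = str(row[cols["region"]]).strip()
            if "species" in cols and not pd.isna(row[cols["species"]]):
                m["species"] = str(row[cols["species"]]).strip()
    else:  # wide
        site_col = df.columns[0]
        years = []
        for c in df.columns[1:]:
            if not _looks_like_year(c):
                raise DialectError(f"wide table column {c!r} is not a year")
            years.append(int(str(c).strip()))
        for idx, row in df.iterrows():
            where = f"row {idx + 2}"
            site = str(row[site_col]).strip()
            if site == "" or site.lower() == "nan":
                raise ParseError(f"{where}: empty site id")
            if site in records:
                raise ParseError(f"{where}: duplicate site row {site!r}")
            by_year: dict[int, int] = {}
            for year, col in zip(years, df.columns[1:]):
                cell = row[col]
                if pd.isna(cell) or str(cell).strip() in ("", "NA", "na", "NaN"):
                    continue
                by_year[year] = _to_count(cell, f"{where}, year {year}")
            if by_year:
                records[site] = by_year

    series = _series_from_records(records, meta, species)
    series.sort(key=lambda s: s.site_id)
    return CountDataset(series=tuple(series), species=species, country=country)


def write_count_table(ds: CountDataset, target, dialect: str = "long") -> None:
    """Write a dataset back to delimited text (canonical long CSV by default)."""
    if dialect == "long":
        rows = []
        has_region = any(s.region for s in ds.series)
        for s in ds.series:
            for y, c in zip(s.years, s.counts):
                row = {"site": s.site_id, "year": y, "count": c}
                if has_region:
                    row["region"] = s.region
                rows.append(row)
        cols = ["site", "year", "count"] + (["region"] if has_region else [])
        pd.DataFrame(rows, columns=cols).to_csv(target, index=False)
    elif dialect == "wide":
        yr = ds.year_range
        years = list(range(yr[0], yr[1] + 1)) if yr else []
        table = {}
        for s in ds.series:
            by_year = dict(zip(s.years, s.counts))
            table[s.site_id] = [by_year.get(y, "") for y in years]
        df = pd.DataFrame.from_dict(table, orient="index", columns=[str(y) for y in years])
        df.index.name = "site"
        df.to_csv(target)
    else:
        raise DialectError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# filtering and summaries
# ---------------------------------------------------------------------------


def filter_min_years(ds: CountDataset, min_years: int = 5) -> CountDataset:
    """Keep only series with at least ``min_years`` observed (surveyed) years.

    Short series are dominated by natural between-year fluctuation and
    carry little trend information; the analyses here retain sites with
    five or more years of data.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    kept = tuple(s for s in ds.series if s.n_obs >= min_years)
    return CountDataset(series=kept, species=ds.species, country=ds.country)


def restrict_years(ds: CountDataset, start: int, end: int) -> CountDataset:
    """Drop observations outside [start, end]; drop series left empty."""
    if start > end:
        raise ValueError("start must be <= end")
    out = []
    for s in ds.series:
        pairs = [(y, c) for y, c in zip(s.years, s.counts) if start <= y <= end]
        if pairs:
            out.append(SiteSeries(site_id=s.site_id,
                                  years=tuple(y for y, _ in pairs),
                                  counts=tuple(c for _, c in pairs),
                                  species=s.species, region=s.region))
    return CountDataset(series=tuple(out), species=ds.species, country=ds.country)


@dataclass(frozen=True)
class DatasetSummary:
    """Descriptive summary of a dataset (site counts, series lengths, counts)."""

    n_sites: int
    n_observations: int
    mean_series_length: float | None  # observed years per site, 1 decimal
    min_series_length: int | None
    max_series_length: int | None
    year_range: tuple[int, int] | None
    count_quantiles: dict[str, float] | None

    def to_dict(self) -> dict:
        d = {
            "n_sites": self.n_sites,
            "n_observations": self.n_observations,
            "mean_series_length": self.mean_series_length,
            "min_series_length": self.min_series_length,
            "max_series_length": self.max_series_length,
            "year_range": list(self.year_range) if self.year_range else None,
            "count_quantiles": self.count_quantiles,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def dataset_summary(ds: CountDataset) -> DatasetSummary:
    """Summarise sites, series lengths and the count distribution.

    ``mean_series_length`` is the mean number of observed years per site,
    rounded to one decimal.
    """
    if not ds.series:
        return DatasetSummary(n_sites=0, n_observations=0, mean_series_length=None,
                              min_series_length=None, max_series_length=None,
                              year_range=None, count_quantiles=None)
    lengths = np.array([s.n_obs for s in ds.series])
    counts = np.concatenate([np.asarray(s.counts) for s in ds.series])
    qs = np.percentile(counts, [0, 25, 50, 75, 100])
    return DatasetSummary(
        n_sites=ds.n_sites,
        n_observations=int(lengths.sum()),
        mean_series_length=round(float(lengths.mean()), 1),
        min_series_length=int(lengths.min()),
        max_series_length=int(lengths.max()),
        year_range=ds.year_range,
        count_quantiles={"min": float(qs[0]), "q25": float(qs[1]),
                         "median": float(qs[2]), "q75": float(qs[3]),
                         "max": float(qs[4])},
    )
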