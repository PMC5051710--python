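"""Synthetic count datasets drawn from the open N-mixture generative model.

Latent abundance at a site follows ``N_t ~ Poisson(lambda * N_{t-1})`` with
a period-specific (decade) growth rate ``lambda``; the initial abundance is
``N_first ~ Poisson(Lambda_i)`` with a site-specific mean; and an observed
seasonal count is a binomial thinning ``y_t ~ Binomial(N_t, p)`` with a
period- (and optionally region-) specific detection probability.

Defaults emulate the volunteer "toads on roads" study design: ~140 sites,
staggered start years across a four-decade window, mean series length near
14 observed years, site population means spanning tens to thousands of
adults (log-uniform), detection between 0.2 and 0.8, and occasional missing
survey years inside a series.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .count_data import (
    CH_SCHEME,
    UK_SCHEME,
    CountDataset,
    PeriodScheme,
    SiteSeries,
    stratum_key,
)

__all__ = [
    "Scenario",
    "TruthRecord",
    "simulate_site",
    "simulate_dataset",
    "recovery_scenario",
]


def _as_param_table(values, scheme: PeriodScheme,
                    regions: tuple[str, ...] | None, name: str,
                    lo: float, hi_inclusive: float | None) -> dict[str, float]:
    """Expand per-period values (sequence, or region -> sequence mapping)
    into a flat ``stratum_key -> value`` table, validating ranges."""
    table: dict[str, float] = {}
    if isinstance(values, Mapping):
        if regions is None:
            raise ValueError(f"{name} given per region but scenario has no regions")
        for region in regions:
            if region not in values:
                raise ValueError(f"{name} missing entries for region {region!r}")
            seq = tuple(values[region])
            if len(seq) != scheme.n_periods:
                raise ValueError(f"{name}[{region!r}] needs {scheme.n_periods} values")
            for label, v in zip(scheme.labels, seq):
                table[stratum_key(label, region)] = float(v)
    else:
        seq = tuple(values)
        if len(seq) != scheme.n_periods:
            raise ValueError(f"{name} needs {scheme.n_periods} values (one per period)")
        for label, v in zip(scheme.labels, seq):
            table[label] = float(v)
    for k, v in table.items():
        if not v > lo:
            raise ValueError(f"{name}[{k}] = {v} must be > {lo}")
        if hi_inclusive is not None and v > hi_inclusive:
            raise ValueError(f"{name}[{k}] = {v} must be <= {hi_inclusive}")
    return table


@dataclass(frozen=True)
class Scenario:
    """Study-design parameters for the synthetic-data generator.

    Parameters
    ----------
    n_sites
        Number of monitored sites.
    period_scheme
        Decade windows; one growth rate / detection value per period
        (per region when ``regions`` is set).
    true_lambda, true_p
        Per-period truth, either a sequence (national) or a mapping
        ``region -> sequence``.  Defaults are decade values typical of the
        Swiss common-toad series (early growth, then sustained decline;
        detection 0.35-0.45).
    init_mean_range
        Range of the site initial-abundance means ``Lambda_i`` (animals);
        sites are drawn log-uniformly so most populations are small and a
        few are very large.
    series_length_mean
        Target mean number of *observed* years per series.
    start_year_distribution
        Optional calendar-year weights for series start years; default is
        uniform over feasible starts inside the scheme window.
    missing_prob
        Probability an interior year of a running series goes unsurveyed
        (the first and last years are always observed).
    regions
        Optional ``(label, weight)`` allocation of sites to regions.
    """

    n_sites: int = 140
    period_scheme: PeriodScheme = CH_SCHEME
    true_lambda: Sequence[float] | Mapping[str, Sequence[float]] = (
        1.081, 0.977, 0.982, 0.980)
    true_p: Sequence[float] | Mapping[str, Sequence[float]] = (
        0.390, 0.358, 0.420, 0.443)
    init_mean_range: tuple[float, float] = (50.0, 8000.0)
    series_length_mean: float = 14.0
    min_span: int = 5
    start_year_distribution: Mapping[int, float] | None = None
    missing_prob: float = 0.1
    regions: tuple[tuple[str, float], ...] | None = None
    species: str = "common_toad"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        lo, hi = self.init_mean_range
        if not (0 < lo <= hi <= 20000):
            raise ValueError("init_mean_range must satisfy 0 < lo <= hi <= 20000")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must be in [0, 1)")
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")
        # populate validated flat tables once
        object.__setattr__(self, "_lambda_table", _as_param_table(
            self.true_lambda, self.period_scheme, self.region_labels,
            "true_lambda", 0.0, None))
        object.__setattr__(self, "_p_table", _as_param_table(
            self.true_p, self.period_scheme, self.region_labels,
            "true_p", 0.0, 1.0))

    # -- lookups -----------------------------------------------------------

    @property
    def region_labels(self) -> tuple[str, ...] | None:
        if self.regions is None:
            return None
        return tuple(r for r, _ in self.regions)

    @property
    def lambda_table(self) -> dict[str, float]:
        return dict(self._lambda_table)  # type: ignore[attr-defined]

    @property
    def p_table(self) -> dict[str, float]:
        return dict(self._p_table)  # type: ignore[attr-defined]

    def lambda_for(self, year: int, region: str | None = None) -> float:
        label = self.period_scheme.label_for(year)
        table = self._lambda_table  # type: ignore[attr-defined]
        key = stratum_key(label, region) if isinstance(self.true_lambda, Mapping) else label
        if key not in table:
            raise KeyError(f"no growth-rate stratum for year {year}, region {region!r}")
        return table[key]

    def p_for(self, year: int, region: str | None = None) -> float:
        label = self.period_scheme.label_for(year)
        table = self._p_table  # type: ignore[attr-defined]
        key = stratum_key(label, region) if isinstance(self.true_p, Mapping) else label
        if key not in table:
            raise KeyError(f"no detection stratum for year {year}, region {region!r}")
        return table[key]

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_lambda_table", None)
        d.pop("_p_table", None)
        d["period_scheme"] = {"periods": [list(p) for p in self.period_scheme.periods],
                              "labels": list(self.period_scheme.labels)}
        if self.start_year_distribution is not None:
            d["start_year_distribution"] = {int(k): float(v)
                                            for k, v in self.start_year_distribution.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        ps = d.get("period_scheme")
        if isinstance(ps, Mapping):
            d["period_scheme"] = PeriodScheme(
                periods=tuple(tuple(p) for p in ps["periods"]),
                labels=tuple(ps["labels"]))
        elif isinstance(ps, str):
            from .count_data import PRESET_SCHEMES
            d["period_scheme"] = PRESET_SCHEMES[ps]
        for key in ("init_mean_range",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("regions") is not None:
            d["regions"] = tuple((str(r), float(w)) for r, w in d["regions"])
        if d.get("true_lambda") is not None and not isinstance(d["true_lambda"], Mapping):
            d["true_lambda"] = tuple(d["true_lambda"])
        if d.get("true_p") is not None and not isinstance(d["true_p"], Mapping):
            d["true_p"] = tuple(d["true_p"])
        if d.get("start_year_distribution") is not None:
            d["start_year_distribution"] = {int(k): float(v)
                                            for k, v in d["start_year_distribution"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def recovery_scenario(n_sites: int = 150, seed: int = 0, **overrides) -> Scenario:
    """Small-population benchmark scenario used for parameter-recovery checks.

    Three decades (1985-2014) with national growth rates (1.05, 0.98, 0.97)
    and detection (0.3, 0.4, 0.5); site means are log-uniform on [20, 200]
    so the latent state space stays small enough for exact validation.
    """
    kwargs = dict(
        n_sites=n_sites,
        period_scheme=UK_SCHEME,
        true_lambda=(1.05, 0.98, 0.97),
        true_p=(0.3, 0.4, 0.5),
        init_mean_range=(20.0, 200.0),
        series_length_mean=14.0,
        missing_prob=0.1,
        seed=seed,
    )
    kwargs.update(overrides)
    return Scenario(**kwargs)


@dataclass
class TruthRecord:
    """True parameters and latent trajectories behind a simulated dataset."""

    lambda_table: dict[str, float]
    p_table: dict[str, float]
    init_mean: dict[str, float]                       # site -> Lambda_i
    site_region: dict[str, str | None]
    trajectories: dict[str, tuple[int, tuple[int, ...]]]  # site -> (first_year, N path)
    scenario: dict = field(default_factory=dict)

    def latent(self, site_id: str) -> tuple[int, np.ndarray]:
        first, path = self.trajectories[site_id]
        return first, np.asarray(path, dtype=np.int64)

    def to_json(self, path=None, **kwargs) -> str | None:
        payload = {
            "lambda_table": self.lambda_table,
            "p_table": self.p_table,
            "init_mean": self.init_mean,
            "site_region": self.site_region,
            "trajectories": {k: [v[0], list(v[1])] for k, v in self.trajectories.items()},
            "scenario": self.scenario,
        }
        text = json.dumps(payload, **kwargs)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_json(cls, source) -> "TruthRecord":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            lambda_table=payload["lambda_table"],
            p_table=payload["p_table"],
            init_mean=payload["init_mean"],
            site_region=payload["site_region"],
            trajectories={k: (int(v[0]), tuple(int(x) for x in v[1]))
                          for k, v in payload["trajectories"].items()},
            scenario=payload.get("scenario", {}),
        )


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    # per-site substream: reproducible and independent of generation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(site_index)]))


def _draw_span(scenario: Scenario, rng: np.random.Generator) -> int:
    """Series span (first to last year inclusive) targeting the configured
    mean number of observed years once interior missingness is applied."""
    scheme = scenario.period_scheme
    width = scheme.end - scheme.start + 1
    q = 1.0 - scenario.missing_prob
    # E[n_obs] = 2 + (span - 2) q  =>  solve for the span mean
    target_span = 2.0 + max(scenario.series_length_mean - 2.0, 0.0) / q
    mu = max(target_span - scenario.min_span, 0.0)
    span = scenario.min_span + int(rng.poisson(mu))
    return int(min(max(span, 1), width))


def _simulate_site_full(scenario: Scenario, site_index: int,
                        seed: int | None) -> tuple[SiteSeries, np.ndarray, float]:
    if site_index < 0:
        raise ValueError("site_index must be >= 0")
    rng = _site_rng(scenario.seed if seed is None else seed, site_index)

    region: str | None = None
    if scenario.regions is not None:
        labels = [r for r, _ in scenario.regions]
        weights = np.array([w for _, w in scenario.regions], dtype=float)
        region = str(rng.choice(labels, p=weights / weights.sum()))

    lo, hi = scenario.init_mean_range
    lam_init = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    scheme = scenario.period_scheme
    span = _draw_span(scenario, rng)
    feasible_last = scheme.end - span + 1
    if scenario.start_year_distribution:
        years_w = [(int(y), float(w)) for y, w in scenario.start_year_distribution.items()
                   if scheme.start <= int(y) <= feasible_last]
        if not years_w:
            raise ValueError("start_year_distribution has no feasible start years")
        ys = np.array([y for y, _ in years_w])
        ws = np.array([w for _, w in years_w])
        start = int(rng.choice(ys, p=ws / ws.sum()))
    else:
        start = int(rng.integers(scheme.start, feasible_last + 1))

    # observation mask: endpoints always surveyed, interior thinned
    observed = np.ones(span, dtype=bool)
    if span > 2:
        observed[1:-1] = rng.random(span - 2) >= scenario.missing_prob

    N = np.zeros(span, dtype=np.int64)
    N[0] = rng.poisson(lam_init)
    for j in range(1, span):
        year = start + j
        lam = scenario.lambda_for(year, region)
        N[j] = rng.poisson(lam * N[j - 1]) if N[j - 1] > 0 else 0

    years, counts = [], []
    for j in range(span):
        if observed[j]:
            year = start + j
            p = scenario.p_for(year, region)
            years.append(year)
            counts.append(int(rng.binomial(N[j], p)))

    series = SiteSeries(site_id=f"site{site_index:03d}", years=tuple(years),
                        counts=tuple(counts), species=scenario.species,
                        region=region)
    return series, N, lam_init


def simulate_site(scenario: Scenario, site_index: int,
                  seed: int | None = None) -> tuple[SiteSeries, np.ndarray]:
    """Simulate one site: returns the observed series and the latent path.

    The latent path covers every calendar year from the first to the last
    year of the series (transitions advance annually through gap years);
    counts are emitted only for surveyed years.  Deterministic for a fixed
    ``(seed, site_index)``.
    """
    series, N, _ = _simulate_site_full(scenario, site_index, seed)
    return series, N


def simulate_dataset(scenario: Scenario,
                     seed: int | None = None) -> tuple[CountDataset, TruthRecord]:
    """Simulate a full multi-site dataset plus its :class:`TruthRecord`."""
    series_list, init_mean, site_region, trajectories = [], {}, {}, {}
    for i in range(scenario.n_sites):
        s, N, lam_init = _simulate_site_full(scenario, i, seed)
        series_list.append(s)
        init_mean[s.site_id] = lam_init
        site_region[s.site_id] = s.region
        trajectories[s.site_id] = (s.first_year, tuple(int(n) for n in N))
    ds = CountDataset(series=tuple(series_list), species=scenario.species,
                      country="synthetic")
    truth = TruthRecord(lambda_table=scenario.lambda_table,
                        p_table=scenario.p_table,
                        init_mean=init_mean, site_region=site_region,
                        trajectories=trajectories,
                        scenario=scenario.to_dict())
    return ds, truth
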