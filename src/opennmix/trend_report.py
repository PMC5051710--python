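"""Trend tables, decline projections and IUCN criterion-A2 categories.

A growth rate lambda compounds multiplicatively: over h years abundance
changes by the factor lambda^h, i.e. a percent decline of
100 * (1 - lambda^h).  An annual rate of 0.96 therefore loses more than
30% inside a decade, which meets the red-list A2 threshold for
"vulnerable" (past population reduction >= 30%, causes possibly not
ceased, understood, or reversible).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .count_data import PeriodScheme

__all__ = [
    "project_decline",
    "iucn_a2_category",
    "build_trend_report",
    "TrendReport",
    "plot_trends",
    "IUCN_CATEGORIES",
]

IUCN_CATEGORIES = ("least_concern", "vulnerable", "endangered",
                   "critically_endangered")

#: Red-list criterion A2 cut-offs on % decline over the assessment horizon.
DEFAULT_A2_THRESHOLDS = (30.0, 50.0, 80.0)


def project_decline(lam: float, n_years: int) -> float:
    """Percent population change over ``n_years`` at annual growth ``lam``.

    Positive values are declines, negative values growth:
    ``100 * (1 - lam ** n_years)``.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    return 100.0 * (1.0 - lam ** n_years)


def iucn_a2_category(decline_percent: float,
                     thresholds: Sequence[float] = DEFAULT_A2_THRESHOLDS) -> str:
    """Map a percent decline to a red-list criterion A2 category.

    Thresholds (default 30/50/80%) are inclusive: a decline exactly at a
    cut-off takes the more threatened category, matching the criterion's
    ">= 30%" phrasing.
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) != 3 or any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("thresholds must be three increasing cut-offs")
    if decline_percent >= t[2]:
        return "critically_endangered"
    if decline_percent >= t[1]:
        return "endangered"
    if decline_percent >= t[0]:
        return "vulnerable"
    return "least_concern"


_PARAM_RE = re.compile(r"^(lambda|p)\[(.+)\]$")


def _parse_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Split parameter names like ``lambda[West|1985-1994]`` into columns."""
    df = summary.copy()
    if "parameter" in df.columns:
        df = df.set_index("parameter")
    rows = []
    for name, row in df.iterrows():
        m = _PARAM_RE.match(str(name))
        if not m:
            continue
        kind, key = m.groups()
        region, _, period = key.rpartition("|")
        rows.append({"kind": kind, "region": region or None, "period": period,
                     "mean": float(row["mean"]), "cri_lo": float(row["cri_lo"]),
                     "cri_hi": float(row["cri_hi"])})
    out = pd.DataFrame(rows)
    if not out.empty:
        bad = out[(out["cri_lo"] > out["mean"]) | (out["mean"] > out["cri_hi"])]
        if len(bad):
            first = bad.iloc[0]
            raise ValueError(
                f"inconsistent credible interval for {first['kind']}"
                f"[{first['period']}]: mean {first['mean']} outside "
                f"({first['cri_lo']}, {first['cri_hi']})"
            )
    return out


@dataclass
class TrendReport:
    """Per-stratum growth-rate and detection table with decline projections.

    ``table`` has one row per (region, period) growth-rate stratum: the
    posterior mean and CRI of lambda, the projected percent decline over
    ``horizon`` years at the mean and at both CRI endpoints, and the
    IUCN A2 category of the mean projection.  ``detection`` tabulates p.
    """

    table: pd.DataFrame
    detection: pd.DataFrame
    horizon: int
    thresholds: tuple[float, float, float] = DEFAULT_A2_THRESHOLDS

    def to_csv(self, target) -> None:
        self.table.to_csv(target, index=False)

    @classmethod
    def read_csv(cls, source, horizon: int | None = None) -> "TrendReport":
        table = pd.read_csv(source).replace({np.nan: None})
        table["region"] = [r if r else None for r in table.get("region", [None] * len(table))]
        h = horizon if horizon is not None else int(table["horizon"].iloc[0])
        return cls(table=table, detection=pd.DataFrame(), horizon=h)


def build_trend_report(summary: pd.DataFrame, scheme: PeriodScheme,
                       horizon: int = 10,
                       thresholds: Sequence[float] = DEFAULT_A2_THRESHOLDS,
                       ) -> TrendReport:
    """Assemble the trend table from a posterior summary.

    ``summary`` is the :func:`~opennmix.bayes_fit.posterior_summary` frame
    (or any table indexed by ``lambda[...]`` / ``p[...]`` names with mean,
    cri_lo, cri_hi columns).  Every period of ``scheme`` must appear for
    every region present.  Decline projections use the posterior-mean
    growth rate, with projections at the CRI endpoints reported alongside.
    """
    parsed = _parse_summary(summary)
    lam = parsed[parsed["kind"] == "lambda"] if not parsed.empty else parsed
    det = parsed[parsed["kind"] == "p"] if not parsed.empty else parsed
    if lam.empty:
        raise ValueError("summary contains no growth-rate (lambda[...]) entries")

    regions = sorted({r for r in lam["region"] if r is not None}) or [None]
    for region in regions:
        sub = lam[lam["region"].isnull()] if region is None else lam[lam["region"] == region]
        missing = [lbl for lbl in scheme.labels if lbl not in set(sub["period"])]
        if missing:
            where = f" (region {region})" if region else ""
            raise ValueError(f"summary lacks growth-rate strata{where}: {missing}")

    rows = []
    for _, r in lam.iterrows():
        decline_mean = project_decline(r["mean"], horizon)
        # a higher growth rate projects a smaller decline
        decline_hi_lam = project_decline(r["cri_hi"], horizon)
        decline_lo_lam = project_decline(r["cri_lo"], horizon)
        rows.append({
            "region": r["region"], "period": r["period"],
            "lambda_mean": r["mean"], "lambda_cri_lo": r["cri_lo"],
            "lambda_cri_hi": r["cri_hi"],
            "decline_pct": decline_mean,
            "decline_pct_at_cri_lo": decline_lo_lam,
            "decline_pct_at_cri_hi": decline_hi_lam,
            "horizon": horizon,
            "iucn_a2": iucn_a2_category(decline_mean, thresholds),
        })
    order = {lbl: i for i, lbl in enumerate(scheme.labels)}
    table = pd.DataFrame(rows).sort_values(
        by=["region", "period"],
        key=lambda col: col.map(order) if col.name == "period" else col,
        na_position="first").reset_index(drop=True)
    detection = det.rename(columns={"mean": "p_mean", "cri_lo": "p_cri_lo",
                                    "cri_hi": "p_cri_hi"}).drop(columns=["kind"])
    return TrendReport(table=table, detection=detection.reset_index(drop=True),
                       horizon=horizon, thresholds=tuple(float(x) for x in thresholds))


def plot_trends(report: TrendReport, path=None, title: str | None = None):
    """Dot-and-whisker plot of growth rates by period (one panel per region)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table
    regions = list(dict.fromkeys(table["region"]))
    fig, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions), 3.5),
                             sharey=True, squeeze=False)
    for ax, region in zip(axes[0], regions):
        sub = table[table["region"].isnull()] if region is None else \
            table[table["region"] == region]
        x = np.arange(len(sub))
        ax.errorbar(x, sub["lambda_mean"],
                    yerr=[sub["lambda_mean"] - sub["lambda_cri_lo"],
                          sub["lambda_cri_hi"] - sub["lambda_mean"]],
                    fmt="o", capsize=3, color="k")
        ax.axhline(1.0, ls=":", color="grey")
        ax.set_xticks(x, sub["period"], rotation=45)
        ax.set_title(region or "all sites")
        ax.set_ylabel("growth rate $\\lambda$")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
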