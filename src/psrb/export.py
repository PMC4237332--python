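"""Assemble indicator outputs into dashboard data products.

One tidy record per unit x indicator (baseline + trend), exported as
CSV, per-indicator GeoJSON choropleths, a machine-readable JSON feed,
and per-unit protection trend charts.  Numbers pass through untouched;
rounding happens only in chart labels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping

from .errors import ConfigurationError, DataIntegrityError
from .kba import ProtectionSeries
from .spatial import SpatialUnit

__all__ = [
    "INDICATOR_NAMES",
    "IndicatorRecord",
    "build_indicator_table",
    "export_products",
    "read_feed",
]

INDICATOR_NAMES = ("forest", "rli", "kba_protection", "freshwater", "survey_score")

# Baseline year and trend window per indicator; freshwater and the survey
# score are single-date (no trend can be estimated).
_BASELINE_YEAR = {"forest": 2000, "rli": 2008, "kba_protection": 2010, "freshwater": 2010, "survey_score": 2012}
_TREND_WINDOW = {"forest": (2000, 2005), "rli": (1980, 2008), "kba_protection": (1980, 2010)}
# RLI trend is reported in units of 1e-3 per year, flagged explicitly.
_TREND_SCALE = {"rli": 0.001}

RECORD_COLUMNS = [
    "unit_id",
    "unit_level",
    "indicator",
    "baseline_value",
    "baseline_year",
    "trend_value",
    "trend_scale",
    "trend_start",
    "trend_end",
]


@dataclass(frozen=True)
class IndicatorRecord:
    unit_id: str
    unit_level: str
    indicator: str
    baseline_value: float
    baseline_year: int
    trend_value: float | None = None
    trend_scale: float = 1.0
    trend_window: tuple[int, int] | None = None


def _records_from(
    df: pd.DataFrame | None,
    indicator: str,
    baseline_col: str,
    trend_col: str | None,
    levels: Mapping[str, str],
) -> list[IndicatorRecord]:
    if df is None:
        return []
    scale = _TREND_SCALE.get(indicator, 1.0)
    window = _TREND_WINDOW.get(indicator)
    out = []
    for _, row in df.iterrows():
        trend = None
        if trend_col is not None and trend_col in row and not pd.isna(row[trend_col]):
            trend = float(row[trend_col]) / scale
        out.append(
            IndicatorRecord(
                unit_id=row["unit_id"],
                unit_level=levels.get(row["unit_id"], "country"),
                indicator=indicator,
                baseline_value=float(row[baseline_col]),
                baseline_year=_BASELINE_YEAR[indicator],
                trend_value=trend,
                trend_scale=scale,
                trend_window=window if trend is not None else None,
            )
        )
    return out


def build_indicator_table(
    units: Sequence[SpatialUnit],
    forest: pd.DataFrame | None = None,
    rli: pd.DataFrame | None = None,
    kba: pd.DataFrame | None = None,
    freshwater: pd.DataFrame | None = None,
    survey: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy unit x indicator table; missing values stay NaN, never zero.

    ``rli`` expects the per-taxon table from :func:`psrb.rli.compute_rli_table`
    (the pooled 'all' rows feed the headline record); ``survey`` expects the
    per-country score table, averaged over the four indicator questions.
    """
    if all(x is None for x in (forest, rli, kba, freshwater, survey)):
        raise ConfigurationError("at least one indicator output is required")
    levels = {u.id: u.level for u in units}

    records: list[IndicatorRecord] = []
    records += _records_from(forest, "forest", "mean_cover_2000", "annual_rate", levels)
    if rli is not None:
        pooled = rli[rli["taxon"] == "all"].dropna(subset=["rli_last"])
        records += _records_from(pooled, "rli", "rli_last", "annual_change", levels)
    records += _records_from(kba, "kba_protection", "baseline_2010", "annual_rate", levels)
    records += _records_from(freshwater, "freshwater", "mean_index", None, levels)
    if survey is not None:
        pooled_survey = (
            survey.groupby("country_id", as_index=False)["score"].mean()
            .rename(columns={"country_id": "unit_id"})
        )
        records += _records_from(pooled_survey, "survey_score", "score", None, levels)

    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.unit_id, rec.indicator)
        if key in seen:
            raise DataIntegrityError(f"duplicate record for unit={rec.unit_id} indicator={rec.indicator}")
        seen.add(key)

    rows = [
        {
            "unit_id": r.unit_id,
            "unit_level": r.unit_level,
            "indicator": r.indicator,
            "baseline_value": r.baseline_value,
            "baseline_year": r.baseline_year,
            "trend_value": np.nan if r.trend_value is None else r.trend_value,
            "trend_scale": r.trend_scale,
            "trend_start": np.nan if r.trend_window is None else r.trend_window[0],
            "trend_end": np.nan if r.trend_window is None else r.trend_window[1],
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.sort_values(["unit_level", "unit_id", "indicator"]).reset_index(drop=True)


KNOWN_FORMATS = ("csv", "geojson", "json", "png", "svg")


def export_products(
    records: pd.DataFrame,
    units: Sequence[SpatialUnit],
    series: Mapping[str, ProtectionSeries] | None,
    outdir: str,
    formats: Sequence[str] = ("csv", "geojson", "json"),
) -> list[str]:
    """Write the selected products; returns the list of files written.

    Output is deterministic: stable row ordering, repr float formatting,
    fixed file names.
    """
    unknown = [f for f in formats if f not in KNOWN_FORMATS]
    if unknown:
        raise ConfigurationError(f"unknown export format(s): {unknown}")
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    series = series or {}

    if "csv" in formats:
        path = os.path.join(outdir, "indicator_table.csv")
        tidy = records.sort_values(["unit_level", "unit_id", "indicator"])
        # countries first, then region rows in their own block
        blocks = [tidy[tidy["unit_level"] == "country"], tidy[tidy["unit_level"] == "region"]]
        pd.concat(blocks).to_csv(path, index=False, float_format=lambda v: repr(float(v)))
        written.append(path)

    if "geojson" in formats:
        geo = {u.id: u for u in units}
        for indicator in sorted(records["indicator"].unique()):
            sub = records[records["indicator"] == indicator]
            features = []
            for _, row in sub.sort_values("unit_id").iterrows():
                unit = geo.get(row["unit_id"])
                if unit is None:
                    continue
                features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "unit_id": row["unit_id"],
                            "unit_level": row["unit_level"],
                            "baseline_value": None if pd.isna(row["baseline_value"]) else row["baseline_value"],
                            "trend_value": None if pd.isna(row["trend_value"]) else row["trend_value"],
                        },
                        "geometry": geom_mapping(unit.geometry),
                    }
                )
            path = os.path.join(outdir, f"choropleth_{indicator}.geojson")
            with open(path, "w") as fh:
                json.dump({"type": "FeatureCollection", "features": features}, fh)
            written.append(path)

    if "json" in formats:
        feed = {
            "records": [
                {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
                for row in records.to_dict(orient="records")
            ],
            "series": {
                uid: {
                    "years": s.years.tolist(),
                    "mean_pct": s.mean_pct.tolist(),
                    "ci_low": s.ci_low.tolist(),
                    "ci_high": s.ci_high.tolist(),
                    "n_boot": s.n_boot,
                }
                for uid, s in sorted(series.items())
            },
        }
        path = os.path.join(outdir, "feed.json")
        with open(path, "w") as fh:
            json.dump(feed, fh)
        written.append(path)

    chart_exts = [f for f in ("png", "svg") if f in formats]
    if chart_exts:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for uid, s in sorted(series.items()):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.plot(s.years, s.mean_pct, "-", color="black", label="mean % protected")
            ax.plot(s.years, s.ci_low, "--", color="gray", linewidth=0.9, label="95% CI")
            ax.plot(s.years, s.ci_high, "--", color="gray", linewidth=0.9)
            ax.set_xlabel("year")
            ax.set_ylabel("KBA protection (%)")
            ax.set_title(f"{uid}: protected-area coverage of KBAs")
            ax.set_ylim(-2, 102)
            ax.legend(loc="upper left", fontsize=8)
            fig.tight_layout()
            for ext in chart_exts:
                path = os.path.join(outdir, f"kba_protection_{uid}.{ext}")
                fig.savefig(path)
                written.append(path)
            plt.close(fig)
    return written


def read_feed(path: str) -> dict:
    """Read back the JSON feed written by :func:`export_products`."""
    with open(path) as fh:
        return json.load(fh)
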