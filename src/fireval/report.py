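"""Orchestration of the annual accuracy-assessment workflow and its outputs.

For every year and product this computes the detected-percentage, the
confusion-matrix metrics and the total error; for every year and aggregation
factor, the Pareto boundary of the reference map and its AUPB; and for the
whole period the reference-area-weighted summaries plus, per product, the
regression of annual total error on annual AUPB at the product's working
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GridMismatchError
from .grid import BurnGrid, aggregate_fraction, burned_area_ha
from .pareto import RegressionResult, fit_te_vs_aupb, pareto_boundary
from .spatial import (
    ErrorSummary,
    confusion_counts,
    metrics,
    total_error,
    weighted_error_summary,
)
from .temporal import AnnualRecord, weighted_average_percentage

__all__ = [
    "AssessmentConfig",
    "AssessmentReport",
    "run_assessment",
    "report_tables",
    "recompute_te_table",
]


@dataclass
class AssessmentConfig:
    """Inputs of one assessment run.

    ``reference`` maps year -> reference burn map; ``products`` maps product
    name -> {year -> product burn map} (missing years are simply absent from
    the report, they are not an error).  ``factors`` are the aggregation
    ratios at which Pareto boundaries are built; ``product_factors``
    optionally assigns each product the factor matching its native
    resolution, enabling the TE-vs-AUPB regression.
    """

    reference: Mapping[int, BurnGrid]
    products: Mapping[str, Mapping[int, BurnGrid]]
    factors: tuple[int, ...] = ()
    n_steps: int | str = 101
    product_factors: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("at least one reference year is required")
        for f in self.factors:
            if f < 2:
                raise ValueError("aggregation factors must be >= 2")


@dataclass
class AssessmentReport:
    """Results of :func:`run_assessment`.

    ``annual_percent``: wide table (year, AFS_ha, one column per product).
    ``errors``: long table (year, product, CE, OE, P, TE).
    ``aupb``: wide table (year, one column per resolution in metres).
    ``summary``: per-product multi-year ErrorSummary (weighted CE/OE, P, TE).
    ``percent_summary``: per-product multi-year detected percentage.
    ``regressions``: per-product TE-vs-AUPB fit (where >= 3 years overlap).
    """

    annual_percent: pd.DataFrame
    errors: pd.DataFrame
    aupb: pd.DataFrame
    summary: dict[str, ErrorSummary]
    percent_summary: dict[str, float]
    regressions: dict[str, RegressionResult]


def run_assessment(config: AssessmentConfig) -> AssessmentReport:
    """Run the full per-year assessment across products and resolutions."""
    years = sorted(config.reference)
    base_spec = config.reference[years[0]].spec
    for year, ref in config.reference.items():
        if ref.spec != base_spec:
            raise GridMismatchError(f"reference grid for {year} is off the base grid")

    bar_ha = {y: burned_area_ha(config.reference[y]) for y in years}

    percent_rows: list[dict] = []
    error_rows: list[dict] = []
    for year in years:
        row: dict = {"year": year, "AFS_ha": bar_ha[year]}
        ref = config.reference[year]
        for name, by_year in config.products.items():
            grid = by_year.get(year)
            if grid is None:
                continue
            if grid.spec != base_spec:
                raise GridMismatchError(f"{name} grid for {year} is off the base grid")
            bap = burned_area_ha(grid)
            P = bap / bar_ha[year] if bar_ha[year] else np.nan
            row[name] = 100.0 * P if np.isfinite(P) else np.nan
            m = metrics(confusion_counts(grid, ref))
            error_rows.append(
                {
                    "year": year,
                    "product": name,
                    "CE": m.CE,
                    "OE": m.OE,
                    "P": P,
                    "TE": total_error(m.CE, m.OE, P) if np.isfinite(P) else np.nan,
                    "BAP_ha": bap,
                    "BAR_ha": bar_ha[year],
                }
            )
        percent_rows.append(row)

    aupb_rows: list[dict] = []
    aupb_by_factor: dict[int, dict[int, float]] = {f: {} for f in config.factors}
    for year in years:
        ref = config.reference[year]
        row = {"year": year}
        for factor in config.factors:
            if ref.burned_pixels == 0:
                row[f"res_{factor * base_spec.pixel_size:g}m"] = np.nan
                continue
            frac = aggregate_fraction(ref, factor)
            curve = pareto_boundary(frac, config.n_steps)
            row[f"res_{frac.spec.pixel_size:g}m"] = curve.aupb
            aupb_by_factor[factor][year] = curve.aupb
        aupb_rows.append(row)

    errors = pd.DataFrame(
        error_rows, columns=["year", "product", "CE", "OE", "P", "TE", "BAP_ha", "BAR_ha"]
    )
    summary: dict[str, ErrorSummary] = {}
    percent_summary: dict[str, float] = {}
    regressions: dict[str, RegressionResult] = {}
    for name in config.products:
        sub = errors[errors["product"] == name]
        if sub.empty:
            continue
        summary[name] = weighted_error_summary(
            list(zip(sub["CE"], sub["OE"], sub["BAP_ha"], sub["BAR_ha"]))
        )
        percent_summary[name] = weighted_average_percentage(
            AnnualRecord(int(y), bar, bap)
            for y, bar, bap in zip(sub["year"], sub["BAR_ha"], sub["BAP_ha"])
        )
        factor = config.product_factors.get(name)
        if factor in aupb_by_factor:
            pairs = [
                (aupb_by_factor[factor][int(y)], te)
                for y, te in zip(sub["year"], sub["TE"])
                if int(y) in aupb_by_factor[factor] and np.isfinite(te)
            ]
            if len(pairs) >= 3 and np.ptp([a for a, _ in pairs]) > 0:
                regressions[name] = fit_te_vs_aupb(pairs)

    return AssessmentReport(
        annual_percent=pd.DataFrame(percent_rows),
        errors=errors,
        aupb=pd.DataFrame(aupb_rows),
        summary=summary,
        percent_summary=percent_summary,
        regressions=regressions,
    )


def report_tables(report: AssessmentReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report as CSV tables plus a full-precision JSON bundle.

    Percentages are printed at 2 decimals, error fractions at 3 decimals and
    AUPB as x 10^-3 values at 3 decimals, mirroring the usual presentation of
    burned-area validation tables; the JSON bundle keeps full precision so a
    write/read round trip is lossless.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pct = report.annual_percent.copy()
    for col in pct.columns:
        if col == "year":
            continue
        fmt = "%.2f"
        pct[col] = pct[col].map(lambda v: "" if pd.isna(v) else fmt % v)
    paths["annual_percent"] = outdir / "annual_percent.csv"
    pct.to_csv(paths["annual_percent"], index=False)

    err = report.errors.copy()
    for col in ("CE", "OE", "P", "TE"):
        err[col] = err[col].map(lambda v: "" if pd.isna(v) else "%.3f" % v)
    for col in ("BAP_ha", "BAR_ha"):
        err[col] = err[col].map(lambda v: "" if pd.isna(v) else "%.2f" % v)
    paths["errors"] = outdir / "errors.csv"
    err.to_csv(paths["errors"], index=False)

    au = report.aupb.copy()
    for col in au.columns:
        if col == "year":
            continue
        au[col] = au[col].map(lambda v: "" if pd.isna(v) else "%.3f" % (1000.0 * v))
    paths["aupb"] = outdir / "aupb_x1e3.csv"
    au.to_csv(paths["aupb"], index=False)

    bundle = {
        "annual_percent": report.annual_percent.to_dict(orient="records"),
        "errors": report.errors.to_dict(orient="records"),
        "aupb": report.aupb.to_dict(orient="records"),
        "summary": {
            name: {"CE": s.CE, "OE": s.OE, "P": s.P, "TE": s.TE}
            for name, s in report.summary.items()
        },
        "percent_summary": report.percent_summary,
        "regressions": {
            name: {
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "n": r.n,
            }
            for name, r in report.regressions.items()
        },
    }
    paths["json"] = outdir / "report.json"
    paths["json"].write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return paths


def recompute_te_table(
    percent: pd.DataFrame, errors: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Recompute every TE cell of a published error table from (CE, OE, P).

    ``percent`` is the wide detected-percentage table (column per product,
    ``year`` as strings) and ``errors`` the long CE/OE/TE table.  Returns the
    table with a ``TE_recomputed`` column (rounded to the published 3
    decimals) and the maximum absolute deviation from the published TE.
    """
    pct = percent.set_index("year")
    out = errors.copy()
    recomputed = []
    for _, row in out.iterrows():
        p = pct.at[str(row["year"]), row["product"]] / 100.0
        recomputed.append(round(total_error(row["CE"], row["OE"], round(p, 4)), 3))
    out["TE_recomputed"] = recomputed
    max_dev = float((out["TE_recomputed"] - out["TE"]).abs().max())
    return out, max_dev
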