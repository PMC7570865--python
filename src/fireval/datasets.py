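"""Packaged validation statistics for MODIS-era burned-area products in Alaska.

These small tables hold the published per-year accuracy statistics of four
global burned-area products (Fire_CCI 4.1/5.1, MCD45A1 C5.1, MCD64A1 C6)
assessed against the Alaska Fire Service perimeter record for 2000-2017:

* annual reference burned area (ha) and percentage detected per product,
* annual commission / omission / total errors per product,
* annual areas under the Pareto boundary (x 10^-3) at 250/300/500 m.

They serve as worked-example inputs: the total-error identity
TE = CE * P + OE can be recomputed cell by cell from them, and the
fragmentation regression (TE on AUPB) can be reproduced.  The row with
``year == "all"`` carries the published weighted multi-year summary.

Note: the "all" reference-area cell is the published total (11,623,847.75 ha)
and does not equal the sum of the published annual values (11,205,947.75 ha);
computed summaries in this package always report their own sums.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "PRODUCTS",
    "load_annual_percent",
    "load_error_metrics",
    "load_aupb",
]

#: Product column names used across the packaged tables.
PRODUCTS = ("Fire_CCI_4.1", "Fire_CCI_5.1", "MCD45A1_C5.1", "MCD64A1_C6")


def _read(name: str) -> pd.DataFrame:
    with resources.files("fireval.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"year": str})


def load_annual_percent() -> pd.DataFrame:
    """Annual reference burned area (ha) and percent detected per product.

    Columns: ``year`` (string; ``"all"`` for the multi-year row), ``AFS_ha``,
    one percentage column per product (NaN where the product has no data).
    """
    return _read("alaska_annual_percent.csv")


def load_error_metrics() -> pd.DataFrame:
    """Per-year commission, omission and total errors in long form.

    Columns: ``year``, ``product``, ``CE``, ``OE``, ``TE`` (all fractions,
    3 decimals as published).
    """
    return _read("alaska_error_metrics.csv")


def load_aupb() -> pd.DataFrame:
    """Annual areas under the Pareto boundary (x 10^-3) at 250/300/500 m."""
    return _read("alaska_aupb.csv")
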