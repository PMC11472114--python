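"""Cross-classification of vulnerability against hazard exposure: the 3x3 risk matrix.

Each area's overall vulnerability tercile (rows) is crossed with its hazard
tercile (columns) into one of nine cells.  Hazard terciles come from the
continuous exposure metric (flooded-building proportion, or a heat summary),
not from collapsing deciles — ten bins do not partition evenly into three.
Cells are coded row-major, cell_code = (v - 1) * 3 + h, and labelled
"V{v}-H{h}"; V3-H3 (code 9) is the highest-priority cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .index import VulnerabilityResult
from .indicators import AREA_ID
from .ranking import tercile_classify
from .registry import FloodScenario

__all__ = ["build_risk_matrix", "matrix_summary", "cell_code", "cell_label"]


def cell_code(v: int, h: int) -> int:
    """Row-major cell code 1..9 from vulnerability and hazard terciles."""
    if not (1 <= v <= 3 and 1 <= h <= 3):
        raise ParameterError(f"terciles must be in 1..3, got (v={v}, h={h})")
    return (v - 1) * 3 + h


def cell_label(v: int, h: int) -> str:
    return f"V{v}-H{h}"


def build_risk_matrix(
    vulnerability: VulnerabilityResult,
    hazard_values: pd.Series,
    hazard_name: str,
    scenario: FloodScenario | None = None,
) -> pd.DataFrame:
    """One row per area with vulnerability tercile, hazard tercile and cell.

    Parameters
    ----------
    vulnerability : result of :func:`vulnerability_index`
    hazard_values : continuous per-area exposure metric indexed by area_id
        (e.g. proportion of buildings flooded, mean summer tmax)
    hazard_name : "flood" or "heat" (free label carried into the output)
    scenario : optional flood scenario metadata copied into output columns

    Areas missing either side get missing terciles and a missing cell; they
    are retained in the table.  Disjoint area sets raise ``DataError``.
    """
    vt = vulnerability.table.set_index(AREA_ID)["index_tercile"]
    hv = hazard_values.copy()
    hv.index = hv.index.astype(object)
    common = vt.index.intersection(hv.index)
    if len(common) == 0:
        raise DataError("vulnerability and hazard tables share no areas")

    ht = tercile_classify(hv) if hv.notna().any() else pd.Series(pd.NA, index=hv.index, dtype="Int64")
    out = pd.DataFrame(index=vt.index.union(hv.index, sort=False))
    out["vulnerability_tercile"] = vt.reindex(out.index).astype("Int64")
    out["hazard_tercile"] = ht.reindex(out.index).astype("Int64")
    ok = out["vulnerability_tercile"].notna() & out["hazard_tercile"].notna()
    code = (out["vulnerability_tercile"] - 1) * 3 + out["hazard_tercile"]
    out["cell_code"] = code.where(ok).astype("Int64")
    out["cell_label"] = [
        cell_label(int(v), int(h)) if k else pd.NA
        for v, h, k in zip(
            out["vulnerability_tercile"].fillna(0), out["hazard_tercile"].fillna(0), ok
        )
    ]
    out["hazard_name"] = hazard_name
    if scenario is not None:
        out["return_period_years"] = scenario.return_period_years
        out["climate_pathway"] = scenario.climate_pathway
        out["horizon_year"] = scenario.horizon_year
        out["scenario_role"] = scenario.role
    out.index.name = AREA_ID
    return out.reset_index()


def matrix_summary(result: pd.DataFrame) -> pd.DataFrame:
    """3x3 count table with marginals (rows = vulnerability, cols = hazard).

    Counts cover classified areas only; they sum to the number of areas
    with both terciles present.  Raises if nothing is classified.
    """
    ok = result.dropna(subset=["vulnerability_tercile", "hazard_tercile"])
    if len(ok) == 0:
        raise DataError("no classified areas to summarise")
    table = pd.crosstab(
        ok["vulnerability_tercile"].astype(int),
        ok["hazard_tercile"].astype(int),
        rownames=["vulnerability_tercile"],
        colnames=["hazard_tercile"],
        margins=True,
        margins_name="total",
    )
    full = table.reindex(index=[1, 2, 3, "total"], columns=[1, 2, 3, "total"], fill_value=0)
    return full
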