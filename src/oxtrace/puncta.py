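"""RNAScope per-cell transcript puncta summaries.

In fluorescent in situ hybridization (RNAScope), each discrete fluorescent
punctum marks transcript signal in a cell.  Quantification starts from
per-cell punctum counts (spot detection is upstream and out of scope) and
yields, per region: the percent of cells expressing the transcript
(mean +- SD across sections) and the puncta density (mean puncta per cell).
Assay validity is checked against the bundled control probes: the negative
control must show no specific labeling, the positive control more than 15
puncta per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_expressing", "puncta_density", "control_check", "region_summary"]

POSITIVE_CONTROL_MIN_MEAN = 15.0


def percent_expressing(cells: pd.DataFrame, min_puncta: int = 1) -> dict:
    """Percent of cells with >= ``min_puncta`` puncta, mean +- SD over sections.

    ``cells`` needs columns section_id and puncta.  With a single section the
    SD is NaN.  ``min_puncta=0`` trivially yields 100%.
    """
    if cells.empty:
        raise ValueError("empty cell table")
    per_section = (
        cells.assign(expressing=cells["puncta"] >= min_puncta)
        .groupby("section_id")["expressing"]
        .mean()
        * 100.0
    )
    return {
        "percent_mean": float(per_section.mean()),
        "percent_sd": float(per_section.std(ddof=1)) if len(per_section) > 1 else float("nan"),
        "n_sections": int(len(per_section)),
        "n_cells": int(len(cells)),
        "min_puncta": int(min_puncta),
        "per_section": per_section,
    }


def puncta_density(
    cells: pd.DataFrame, among: str = "expressing", min_puncta: int = 1
) -> dict:
    """Mean +- SD puncta per cell, over expressing cells or all cells.

    The convention matters when many cells are silent, so the choice is
    recorded in the output; callers typically report both.
    """
    if among not in {"expressing", "all"}:
        raise ValueError(f"among must be 'expressing' or 'all', got {among!r}")
    counts = cells["puncta"].to_numpy(dtype=float)
    if among == "expressing":
        counts = counts[counts >= min_puncta]
    if counts.size == 0:
        raise ValueError(f"no cells in the '{among}' selection")
    return {
        "mean": float(np.mean(counts)),
        "sd": float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0,
        "n_cells": int(counts.size),
        "among": among,
    }


def control_check(cells: pd.DataFrame, threshold_neg: float = 0.0) -> dict:
    """Validate the control probes.

    Negative control passes when the median puncta per cell is at or below
    ``threshold_neg`` (default 0 — "no specific labeling"); positive control
    passes when the mean exceeds 15 puncta per cell.  A missing control group
    is reported as 'not assessed', not as a failure.
    """
    report: dict[str, dict] = {}
    for probe, rule in (("negative_control", "median"), ("positive_control", "mean")):
        grp = cells.loc[cells["probe"] == probe, "puncta"]
        if grp.empty:
            report[probe] = {"status": "not assessed"}
            continue
        if rule == "median":
            stat = float(grp.median())
            ok = stat <= threshold_neg
            report[probe] = {
                "status": "pass" if ok else "fail",
                "median_puncta": stat,
                "threshold": threshold_neg,
                "n_cells": int(len(grp)),
            }
        else:
            stat = float(grp.mean())
            ok = stat > POSITIVE_CONTROL_MIN_MEAN
            report[probe] = {
                "status": "pass" if ok else "fail",
                "mean_puncta": stat,
                "threshold": POSITIVE_CONTROL_MIN_MEAN,
                "n_cells": int(len(grp)),
            }
    report["overall"] = (
        "pass"
        if all(v.get("status") != "fail" for k, v in report.items() if k != "overall")
        else "fail"
    )
    return report


def region_summary(cells: pd.DataFrame, min_puncta: int = 1) -> pd.DataFrame:
    """Per-region summary of target-probe cells: %expressing and densities."""
    target = cells[cells["probe"] == "target"] if "probe" in cells.columns else cells
    if target.empty:
        raise ValueError("no target-probe cells")
    rows = []
    for region, grp in target.groupby("region", sort=True):
        pe = percent_expressing(grp, min_puncta=min_puncta)
        d_exp = (
            puncta_density(grp, "expressing", min_puncta)
            if (grp["puncta"] >= min_puncta).any()
            else {"mean": float("nan"), "sd": float("nan"), "n_cells": 0}
        )
        d_all = puncta_density(grp, "all", min_puncta)
        rows.append(
            {
                "region": region,
                "n_cells": pe["n_cells"],
                "n_sections": pe["n_sections"],
                "percent_expressing_mean": pe["percent_mean"],
                "percent_expressing_sd": pe["percent_sd"],
                "density_expressing_mean": d_exp["mean"],
                "density_expressing_sd": d_exp["sd"],
                "density_all_mean": d_all["mean"],
                "density_all_sd": d_all["sd"],
            }
        )
    return pd.DataFrame(rows)
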