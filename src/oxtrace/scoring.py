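"""Semi-quantitative staining scores and the Staining Density Index (SDI).

Brightfield surveys of immunostained serial sections record, for every brain
region on every section, an ordinal density score: 0 (no labeled element),
1 (+, sparse), 2 (++, moderate) or 3 (+++, unquantifiably dense).  Because a
region spans a variable number of sections, scores are normalized to region
size by the Staining Density Index

    SDI = (3*N3 + 2*N2 + N1) / (3*NT)

where Nk is the number of sections scoring k and NT the total number of
sections the region spans, including sections with no labeled cells or
fibers.  SDI lies in [0, 1]; 1 means every section was maximally dense.

This module maps raw cell counts and fiber codes to scores, computes per
animal x region x modality SDI records, pools them across animals, classifies
regions into density tertiles, and screens for sex differences with Welch's
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDIRecord",
    "score_from_cell_count",
    "parse_fiber_code",
    "compute_sdi",
    "compute_sdi_table",
    "pool_sdi",
    "classify_tertiles",
    "sex_difference_screen",
    "FIBER_CODES",
]

#: ordinal fiber codes in increasing density order
FIBER_CODES = {"0": 0, "+": 1, "++": 2, "+++": 3}

TERTILE_LABELS = ("very sparse", "sparse", "dense")


@dataclass(frozen=True)
class SDIRecord:
    """Per animal x region x modality section-score tally and its SDI."""

    animal: str
    region: str
    modality: str
    n1: int
    n2: int
    n3: int
    nt: int
    sdi: float


def score_from_cell_count(count: int) -> int:
    """Map a per-section labeled-cell count to the ordinal density score.

    Bins: 0 cells -> 0; 1-6 cells -> 1; 7-11 cells -> 2; >= 12 cells -> 3.
    The published bin edges overlap at 6 and 12; this implementation honors
    the explicit phrases "1-6 cells" (score 1) and "12 or more" (score 3),
    leaving 7-11 for score 2.
    """
    count = int(count)
    if count < 0:
        raise ValueError(f"cell count must be non-negative, got {count}")
    if count == 0:
        return 0
    if count <= 6:
        return 1
    if count < 12:
        return 2
    return 3


def parse_fiber_code(code: str) -> int:
    """Parse an ordinal fiber-density code ('0', '+', '++', '+++') to 0-3.

    Surrounding whitespace is stripped; anything outside the four-symbol
    alphabet raises ``ValueError`` naming the offending token.
    """
    token = str(code).strip()
    try:
        return FIBER_CODES[token]
    except KeyError:
        raise ValueError(
            f"unknown fiber code {code!r}; expected one of {sorted(FIBER_CODES)}"
        ) from None


def compute_sdi(
    scores,
    *,
    animal: str = "",
    region: str = "",
    modality: str = "",
) -> SDIRecord:
    """Compute the SDI for one animal x region x modality set of section scores.

    Parameters
    ----------
    scores
        Iterable of ordinal scores in {0, 1, 2, 3}, one per section the region
        spans (zero-scored sections included — they enter NT).

    Returns
    -------
    SDIRecord with the N1/N2/N3/NT tally and sdi = (3*N3 + 2*N2 + N1)/(3*NT).
    """
    s = np.asarray(list(scores), dtype=int)
    if s.size == 0:
        raise ValueError("empty score set: NT must be >= 1")
    if np.any((s < 0) | (s > 3)):
        bad = s[(s < 0) | (s > 3)]
        raise ValueError(f"scores must be in {{0,1,2,3}}; got {bad.tolist()}")
    nt = int(s.size)
    n1 = int(np.sum(s == 1))
    n2 = int(np.sum(s == 2))
    n3 = int(np.sum(s == 3))
    sdi = (3 * n3 + 2 * n2 + n1) / (3 * nt)
    return SDIRecord(animal, region, modality, n1, n2, n3, nt, sdi)


def compute_sdi_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Compute SDI per (animal, region, modality) group of a long score table.

    ``scores`` needs columns animal, region, modality, score; a sex column is
    carried through if present (it must be constant within animal).
    """
    required = {"animal", "region", "modality", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    rows = []
    has_sex = "sex" in scores.columns
    for (animal, region, modality), grp in scores.groupby(
        ["animal", "region", "modality"], sort=True
    ):
        rec = compute_sdi(
            grp["score"], animal=str(animal), region=str(region), modality=str(modality)
        )
        row = {
            "animal": rec.animal,
            "region": rec.region,
            "modality": rec.modality,
            "n1": rec.n1,
            "n2": rec.n2,
            "n3": rec.n3,
            "nt": rec.nt,
            "sdi": rec.sdi,
        }
        if has_sex:
            sexes = grp["sex"].unique()
            if len(sexes) != 1:
                raise ValueError(f"animal {animal!r} has inconsistent sex labels")
            row["sex"] = sexes[0]
        rows.append(row)
    return pd.DataFrame(rows)


def pool_sdi(records: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Pool per-animal SDI records to one value per region (and modality).

    Pooling is the arithmetic mean of per-animal SDIs ("mean", default) or the
    median ("median").  A region absent from an animal's records is treated as
    missing for that animal, not as zero: zero only enters through an explicit
    record with NT > 0 and all scores 0.
    """
    if "region" not in records.columns or "sdi" not in records.columns:
        raise ValueError("records need 'region' and 'sdi' columns")
    if how not in {"mean", "median"}:
        raise ValueError(f"unknown pooling rule {how!r}")
    keys = ["region"]
    if "modality" in records.columns:
        keys = ["region", "modality"]
    agg = records.groupby(keys, sort=True)["sdi"].agg(["mean", "median", "count"])
    out = agg.reset_index().rename(
        columns={how: "pooled_sdi", "count": "n_animals"}
    )
    drop = {"mean", "median"} - {how}
    return out.drop(columns=[c for c in drop], errors="ignore")[
        keys + ["pooled_sdi", "n_animals"]
    ]


def classify_tertiles(pooled: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Partition regions into dense / sparse / very sparse SDI tertiles.

    Boundaries are the empirical 33.3rd and 66.7th percentiles of the pooled
    SDI (linear interpolation); a value exactly on a boundary goes to the
    denser class.  Returns the classified table and a dict with the two
    boundaries.  Degenerate inputs (all SDIs equal) put every region in one
    class and emit a warning.
    """
    if "pooled_sdi" not in pooled.columns:
        raise ValueError("pooled table needs a 'pooled_sdi' column")
    values = pooled["pooled_sdi"].to_numpy(dtype=float)
    if values.size < 3:
        raise ValueError("tertile classification needs at least 3 regions")
    lo, hi = np.percentile(values, [100 / 3, 200 / 3])
    if lo == hi:
        warnings.warn(
            "degenerate SDI distribution: tertile boundaries coincide; "
            "all regions fall in one class",
            stacklevel=2,
        )
    tertile = np.where(
        values >= hi, "dense", np.where(values >= lo, "sparse", "very sparse")
    )
    out = pooled.copy()
    out["tertile"] = tertile
    return out, {"lower": float(lo), "upper": float(hi)}


def sex_difference_screen(
    records: pd.DataFrame, min_obs: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region Welch's t-test of SDI between sexes.

    Regions with fewer than ``min_obs`` values in either sex are excluded (a
    mean cannot be compared from one observation) and returned separately
    rather than silently dropped.  p-values are two-sided and uncorrected —
    this is an exploratory screen.

    Returns ``(results, excluded)``; results has per-region group means +- SD,
    Welch t, Welch-Satterthwaite df, and p.  When both groups have zero
    variance and equal means the statistic is undefined and reported as NaN.
    """
    for col in ("region", "sex", "sdi"):
        if col not in records.columns:
            raise ValueError(f"records need a {col!r} column")
    results, excluded = [], []
    for region, grp in records.groupby("region", sort=True):
        m = grp.loc[grp["sex"] == "M", "sdi"].to_numpy(dtype=float)
        f = grp.loc[grp["sex"] == "F", "sdi"].to_numpy(dtype=float)
        base = {
            "region": region,
            "n_m": m.size,
            "n_f": f.size,
            "mean_m": float(np.mean(m)) if m.size else np.nan,
            "sd_m": float(np.std(m, ddof=1)) if m.size > 1 else np.nan,
            "mean_f": float(np.mean(f)) if f.size else np.nan,
            "sd_f": float(np.std(f, ddof=1)) if f.size > 1 else np.nan,
        }
        if m.size < min_obs or f.size < min_obs:
            excluded.append({**base, "reason": f"fewer than {min_obs} observations in one sex"})
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(m, f, equal_var=False)
            vm, vf = np.var(m, ddof=1), np.var(f, ddof=1)
            num = (vm / m.size + vf / f.size) ** 2
            den = (vm / m.size) ** 2 / (m.size - 1) + (vf / f.size) ** 2 / (f.size - 1)
            df = num / den if den > 0 else np.nan
        results.append({**base, "t": float(t), "df": float(df), "p": float(p)})
    res_cols = ["region", "n_m", "n_f", "mean_m", "sd_m", "mean_f", "sd_f", "t", "df", "p"]
    exc_cols = ["region", "n_m", "n_f", "mean_m", "sd_m", "mean_f", "sd_f", "reason"]
    return (
        pd.DataFrame(results, columns=res_cols),
        pd.DataFrame(excluded, columns=exc_cols),
    )
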