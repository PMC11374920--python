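"""Fiber-density vs receptor-transcript concordance across brain regions.

Pooled fiber SDI values are matched, region by region, against an external
semi-quantitative receptor-transcript score (ordinal 1-4 per region).  Since
the two surveys delineate regions differently, harmonization goes through an
explicit user-supplied label mapping: a receptor score spanning several
subregions is averaged to one value, and regions without a counterpart on
either side are carried along as excluded, with the reason recorded.

The concordance model is an ordinary least squares fit with a full
receptor x parent-category interaction,

    sdi ~ receptor_score * C(category)

whose per-category slopes ("estimated linear trends") are extracted as linear
contrasts of the coefficients — reference-category slope plus the category's
interaction term — with delta-method standard errors from the coefficient
covariance and two-sided t-tests on the residual df.  A positive trend in a
category means regions with more receptor transcript also carry denser
fibers, i.e. axonal release plausibly supplies the ligand there.

The regression orientation (which variable is the response) is a modeling
choice; trends are slopes of the covariate and can be fit in either
orientation via ``orientation=``.
"""

from __future__ import annotations

import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as scipy_stats

__all__ = [
    "CATEGORIES",
    "harmonize",
    "fit_interaction_model",
    "estimate_trends",
]

#: parent categories included in the trend analysis by default
CATEGORIES = (
    "thalamus",
    "hypothalamus",
    "midbrain",
    "striatum_pallidum",
    "cerebral_cortex",
)


def harmonize(
    sdi_table: pd.DataFrame,
    receptor_table: pd.DataFrame,
    mapping: dict,
) -> tuple[pd.DataFrame, dict]:
    """Join the pooled-SDI and receptor-score tables via a label mapping.

    Parameters
    ----------
    sdi_table
        Columns region, pooled_sdi.
    receptor_table
        Columns region, score.
    mapping
        ``{output_region: {"sdi_label": str, "receptor_labels": [str, ...],
        "category": str}}``.  A multi-label receptor entry is averaged to one
        score.

    Returns
    -------
    (table, audit) — the concordance table has one row per region on either
    side; rows that could not be matched have ``included=False`` and a
    human-readable ``exclusion_reason``.  The audit dict counts matched and
    excluded regions per side; matched + excluded equals the input region
    count on each side.
    """
    sdi_by_label = dict(zip(sdi_table["region"].astype(str), sdi_table["pooled_sdi"]))
    rec_by_label = dict(zip(receptor_table["region"].astype(str), receptor_table["score"]))

    unknown = [
        lab
        for ent in mapping.values()
        for lab in [ent["sdi_label"], *ent["receptor_labels"]]
        if lab not in sdi_by_label and lab not in rec_by_label
    ]
    if unknown:
        raise KeyError(f"mapping references unknown labels: {sorted(set(unknown))}")

    rows = []
    used_sdi, used_rec = set(), set()
    matched_sdi, matched_rec = set(), set()
    for out_region, entry in mapping.items():
        sdi_label = entry["sdi_label"]
        rec_labels = list(entry["receptor_labels"])
        category = entry["category"]
        have_sdi = sdi_label in sdi_by_label
        have_rec = all(lab in rec_by_label for lab in rec_labels) and rec_labels
        if have_sdi:
            used_sdi.add(sdi_label)
        used_rec.update(lab for lab in rec_labels if lab in rec_by_label)
        if have_sdi and have_rec:
            matched_sdi.add(sdi_label)
            matched_rec.update(rec_labels)
            score = sum(rec_by_label[lab] for lab in rec_labels) / len(rec_labels)
            rows.append(
                {
                    "region": out_region,
                    "category": category,
                    "pooled_sdi": float(sdi_by_label[sdi_label]),
                    "receptor_score": float(score),
                    "included": True,
                    "exclusion_reason": "",
                }
            )
        else:
            reason = (
                "no receptor counterpart" if have_sdi else "no fiber-SDI counterpart"
            )
            rows.append(
                {
                    "region": out_region,
                    "category": category,
                    "pooled_sdi": float(sdi_by_label.get(sdi_label, float("nan"))),
                    "receptor_score": float("nan"),
                    "included": False,
                    "exclusion_reason": reason,
                }
            )

    # regions never referenced by the mapping are excluded wholesale
    for label in sdi_by_label:
        if label not in used_sdi:
            rows.append(
                {
                    "region": label,
                    "category": "",
                    "pooled_sdi": float(sdi_by_label[label]),
                    "receptor_score": float("nan"),
                    "included": False,
                    "exclusion_reason": "no receptor counterpart",
                }
            )
    for label in rec_by_label:
        if label not in used_rec:
            rows.append(
                {
                    "region": label,
                    "category": "",
                    "pooled_sdi": float("nan"),
                    "receptor_score": float(rec_by_label[label]),
                    "included": False,
                    "exclusion_reason": "no fiber-SDI counterpart",
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "region",
            "category",
            "pooled_sdi",
            "receptor_score",
            "included",
            "exclusion_reason",
        ],
    )
    audit = {
        "sdi_regions": len(sdi_by_label),
        "receptor_regions": len(rec_by_label),
        "sdi_matched": len(matched_sdi),
        "receptor_matched": len(matched_rec),
        "sdi_excluded": len(sdi_by_label) - len(matched_sdi),
        "receptor_excluded": len(rec_by_label) - len(matched_rec),
        "output_regions": len(table),
        "included": int(table["included"].sum()),
    }
    return table, audit


def fit_interaction_model(
    table: pd.DataFrame,
    orientation: str = "sdi_on_receptor",
    categories: tuple[str, ...] | None = None,
):
    """OLS fit of the full covariate x category interaction model.

    ``orientation='sdi_on_receptor'`` (default) regresses pooled SDI on the
    receptor score; ``'receptor_on_sdi'`` is the transpose.  Only rows with
    ``included=True`` (when the column exists) and a category in
    ``categories`` (default: the five parent categories; hindbrain is carried
    through harmonization but left out here) enter the fit.

    Returns a dict with the fitted results, the interaction F-test from a
    nested-model comparison, coefficient table, and the design description.
    Each category must contribute at least 2 regions, otherwise its slope is
    unidentifiable and an error names it.
    """
    if orientation not in {"sdi_on_receptor", "receptor_on_sdi"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    cats = tuple(categories) if categories is not None else CATEGORIES
    data = table.copy()
    if "included" in data.columns:
        data = data[data["included"]]
    data = data[data["category"].isin(cats)].copy()
    counts = data["category"].value_counts()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(
            f"category with too few regions for a slope: {thin.index.tolist()}"
        )
    if data["category"].nunique() < 2:
        raise ValueError("interaction model needs at least 2 categories")

    if orientation == "sdi_on_receptor":
        response, covariate = "pooled_sdi", "receptor_score"
    else:
        response, covariate = "receptor_score", "pooled_sdi"
    formula = f"{response} ~ {covariate} * C(category)"
    fit = smf.ols(formula, data=data).fit()
    reduced = smf.ols(f"{response} ~ {covariate} + C(category)", data=data).fit()
    df_num = int(reduced.df_resid - fit.df_resid)
    df_den = int(fit.df_resid)
    if df_den < 1:
        raise ValueError(
            "saturated interaction model (no residual degrees of freedom): "
            "add regions per category"
        )
    # nested-model F, guarded against exactly-fitted (zero-residual) data
    tss = max(float(fit.centered_tss), 1e-12)
    ssr_gain = max(float(reduced.ssr - fit.ssr), 0.0)
    num = ssr_gain / df_num
    den = float(fit.ssr) / df_den
    if num <= 1e-12 * tss:
        f_stat, f_p = 0.0, 1.0
    else:
        den = max(den, 1e-12 * tss / df_den)  # keep F finite on perfect fits
        f_stat = num / den
        f_p = float(scipy_stats.f.sf(f_stat, df_num, df_den))
    reference = sorted(data["category"].unique())[0]
    return {
        "fit": fit,
        "data": data,
        "orientation": orientation,
        "response": response,
        "covariate": covariate,
        "reference_category": reference,
        "categories": sorted(data["category"].unique()),
        "interaction_F": f_stat,
        "interaction_p": f_p,
        "interaction_df": (df_num, df_den),
        "coefficients": fit.params.to_dict(),
        "design": f"OLS, formula '{formula}', treatment coding, reference={reference}",
    }


def estimate_trends(model: dict) -> pd.DataFrame:
    """Per-category covariate slope extracted from the interaction fit.

    The trend for the reference category is the covariate coefficient itself;
    for every other category it is the covariate coefficient plus the
    category's interaction coefficient.  Standard errors come from the
    corresponding linear contrast of the coefficient covariance; p-values are
    two-sided t-tests on the residual df.
    """
    fit = model["fit"]
    covariate = model["covariate"]
    names = list(fit.params.index)
    rows = []
    for category in model["categories"]:
        contrast = pd.Series(0.0, index=names)
        contrast[covariate] = 1.0
        inter = f"{covariate}:C(category)[T.{category}]"
        if inter in contrast.index:
            contrast[inter] = 1.0
        elif category != model["reference_category"]:
            raise KeyError(f"category {category!r} absent from the fitted model")
        tt = fit.t_test(contrast.to_numpy())
        rows.append(
            {
                "category": category,
                "trend": float(tt.effect.item()),
                "se": float(tt.sd.item()),
                "t": float(tt.tvalue.item()),
                "p": float(tt.pvalue.item()),
                "df": int(fit.df_resid),
                "ci_low": float(tt.conf_int()[0, 0]),
                "ci_high": float(tt.conf_int()[0, 1]),
            }
        )
    return pd.DataFrame(rows)
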