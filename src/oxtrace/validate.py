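"""Schema validation for the pipeline's delimited input tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "validate_table", "ValidationError"]

MAX_REPORTED = 10


class ValidationError(ValueError):
    """Raised when a table violates its schema; carries the violation list."""

    def __init__(self, schema: str, violations: list[str]):
        self.schema = schema
        self.violations = violations
        shown = "\n  ".join(violations[:MAX_REPORTED])
        more = len(violations) - min(len(violations), MAX_REPORTED)
        tail = f"\n  ... and {more} more" if more > 0 else ""
        super().__init__(f"table fails schema '{schema}':\n  {shown}{tail}")


def _check_range(df, col, lo, hi, violations, integer=False):
    series = pd.to_numeric(df[col], errors="coerce")
    for idx in df.index[series.isna() & df[col].notna()]:
        violations.append(f"row {idx}: {col}={df.at[idx, col]!r} is not numeric")
    ok = series.notna()
    if integer:
        bad_int = ok & (series != series.round())
        for idx in df.index[bad_int]:
            violations.append(f"row {idx}: {col}={series[idx]} is not an integer")
    bad = ok & ((series < lo) | (series > hi))
    for idx in df.index[bad]:
        violations.append(f"row {idx}: {col}={series[idx]} outside [{lo}, {hi}]")


def _check_values(df, col, allowed, violations):
    bad = ~df[col].astype(str).isin(allowed)
    for idx in df.index[bad]:
        violations.append(f"row {idx}: {col}={df.at[idx, col]!r} not in {sorted(allowed)}")


# schema_name -> (required columns, row-check function)
SCHEMAS = {
    "section_scores": (
        ["animal", "sex", "region", "section_index", "modality", "score"],
        lambda df, v: (
            _check_values(df, "sex", {"M", "F"}, v),
            _check_values(df, "modality", {"cells", "fibers"}, v),
            _check_range(df, "score", 0, 3, v, integer=True),
            _check_range(df, "section_index", 0, float("inf"), v, integer=True),
        ),
    ),
    "vesicle_areas": (
        ["vesicle_id", "region", "compartment", "label_status", "area"],
        lambda df, v: (
            _check_values(df, "label_status", {"OXT_pos", "OXT_neg", "unknown"}, v),
            _check_range(df, "area", 1e-12, float("inf"), v),
        ),
    ),
    "profiles": (
        ["profile_id", "region", "compartment", "contains_dcv"],
        lambda df, v: _check_values(
            df, "contains_dcv", {"True", "False", "true", "false", "0", "1"}, v
        ),
    ),
    "cell_puncta": (
        ["cell_id", "section_id", "region", "puncta", "probe"],
        lambda df, v: (
            _check_range(df, "puncta", 0, float("inf"), v, integer=True),
            _check_values(
                df, "probe", {"target", "negative_control", "positive_control"}, v
            ),
        ),
    ),
    "receptor_scores": (
        ["region", "score"],
        lambda df, v: _check_range(df, "score", 1, 4, v),
    ),
    "pooled_sdi": (
        ["region", "pooled_sdi"],
        lambda df, v: _check_range(df, "pooled_sdi", 0, 1, v),
    ),
}


def validate_table(path, schema_name: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Returns the parsed table on success; raises :class:`ValidationError`
    listing the first 10 violations (with row numbers) otherwise.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; have {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_frame(df, schema_name)


def validate_frame(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Validate an in-memory table against a named schema."""
    columns, checker = SCHEMAS[schema_name]
    violations: list[str] = []
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(schema_name, [f"missing columns: {missing}"])
    checker(df, violations)
    if violations:
        raise ValidationError(schema_name, violations)
    return df
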