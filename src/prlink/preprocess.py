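"""Field standardization and cleaning (pipeline step 1).

Both tables in a linkage must be comparable field by field, so text is
uppercased, punctuation is removed, whitespace is collapsed, and known
placeholder values (e.g. "BABY BOY" first names, all-zero identifiers)
are blanked.  Birthdates are parsed and stored alongside derived
year/month/day columns because downstream stages compare dates
componentwise.

The full pass is idempotent and never alters `source_id` or row count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .simulate import SCHEMA_COLUMNS

logger = logging.getLogger(__name__)

FIELD_ROLES = ("name", "date", "ssn", "address")

# Placeholder values commonly keyed into administrative systems when the
# real value is unknown; editable via CleaningRules.
DEFAULT_INVALID_VALUES: dict[str, tuple[str, ...]] = {
    "name": ("BABY BOY", "BABY GIRL", "UNKNOWN", "UNK", "TEST", "NONE", "NA", "N A"),
    "date": (),
    "ssn": (),
    "address": ("UNKNOWN", "NONE", "HOMELESS", "NA", "N A"),
}

# hyphens/apostrophes are deleted so O'BRIEN and OBRIEN unify; any other
# punctuation separates tokens
_DELETE_RE = re.compile(r"[-']")
_PUNCT_RE = re.compile(r"[^A-Z0-9\s]")
_WS_RE = re.compile(r"\s+")
_REPDIGIT_RE = re.compile(r"^(0+|9+)$")

TEXT_COLUMNS = ["first_name", "middle_name", "last_name", "street", "city", "state", "zip"]
NAME_COLUMNS = ["first_name", "middle_name", "last_name"]
DERIVED_DATE_COLUMNS = ["birth_year", "birth_month", "birth_day"]


@dataclass(frozen=True)
class CleaningRules:
    uppercase: bool = True
    strip_special: bool = True
    collapse_whitespace: bool = True
    invalid_values: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_INVALID_VALUES)
    )


DEFAULT_RULES = CleaningRules()


def clean_text_field(value: object, rules: CleaningRules = DEFAULT_RULES) -> str:
    """Normalize one text value; total on text, missing maps to ''.

    Order is fixed: uppercase, delete hyphen/apostrophe, replace other
    punctuation with a space, collapse whitespace, strip.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value)
    if rules.uppercase:
        s = s.upper()
    if rules.strip_special:
        s = _DELETE_RE.sub("", s)
        s = _PUNCT_RE.sub(" ", s)
    if rules.collapse_whitespace:
        s = _WS_RE.sub(" ", s)
    return s.strip()


def nullify_invalid(
    value: str, field_role: str, rules: CleaningRules = DEFAULT_RULES
) -> str:
    """Blank a cleaned value that matches the role's invalid list.

    Identifier-like roles additionally blank repeated all-zero / all-nine
    digit strings (e.g. 00-00-0000 after cleaning).
    """
    if field_role not in FIELD_ROLES:
        raise ValueError(f"unknown field role {field_role!r}; expected one of {FIELD_ROLES}")
    if not value:
        return value
    if value in rules.invalid_values.get(field_role, ()):
        return ""
    if field_role in ("ssn", "date"):
        digits = re.sub(r"[^0-9]", "", value)
        if digits and _REPDIGIT_RE.match(digits):
            return ""
    return value


def standardize_table(
    table: pd.DataFrame, rules: CleaningRules = DEFAULT_RULES
) -> pd.DataFrame:
    """Clean every text column of a record table and derive birth
    year/month/day columns; row count and source_id are preserved.

    Unparseable birthdates become missing (empty string, NA components)
    and their count is logged.
    """
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"record table is missing required columns: {missing_cols}")

    out = table.copy()
    for col in TEXT_COLUMNS:
        col_clean = out[col].map(lambda v: clean_text_field(v, rules))
        if col in NAME_COLUMNS:
            col_clean = col_clean.map(lambda v: nullify_invalid(v, "name", rules))
        elif col == "street":
            col_clean = col_clean.map(lambda v: nullify_invalid(v, "address", rules))
        out[col] = col_clean

    raw = out["birthdate"].astype("string").fillna("").str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    fallback = raw[parsed.isna() & (raw != "")]
    if len(fallback):
        parsed.loc[fallback.index] = pd.to_datetime(
            fallback, errors="coerce", format="mixed", dayfirst=False
        )
    bad = int((parsed.isna() & (raw != "")).sum())
    if bad:
        logger.info("standardize_table: %d unparseable birthdate value(s) set missing", bad)
    out["birthdate"] = parsed.dt.strftime("%Y-%m-%d").fillna("")
    out["birth_year"] = parsed.dt.year.astype("Int64")
    out["birth_month"] = parsed.dt.month.astype("Int64")
    out["birth_day"] = parsed.dt.day.astype("Int64")
    return out
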