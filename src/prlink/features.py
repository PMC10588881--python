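"""Comparison-vector extraction for candidate pairs (pipeline step 3).

Each candidate pair is turned into a fixed roster of binary indicators —
exact field agreement, thresholded Jaro-Winkler name similarity, street
token overlap, and missingness flags — one row per pair, forming the
Boolean comparison matrix consumed by the scoring stage.  A missing field
on either side forces the corresponding agreement indicators to 0 and the
relevant missing indicator to 1, so missingness is informative rather
than an error.

The column registry is fixed and versioned via a hash, and a scorer
trained on one registry refuses matrices built with another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._strings import jaro_winkler

FEATURE_COLUMNS = [
    "exact_first",
    "exact_middle",
    "exact_last",
    "first_initial_match",
    "jw_first_ge_085",
    "jw_last_ge_085",
    "exact_birth_day",
    "exact_birth_month",
    "exact_birth_year",
    "exact_street",
    "street_token_overlap_ge_05",
    "exact_city",
    "exact_zip",
    "missing_middle_any",
    "missing_address_any",
]

JW_THRESHOLD = 0.85
STREET_OVERLAP_THRESHOLD = 0.5


def registry_hash(columns: Sequence[str] = FEATURE_COLUMNS) -> str:
    """Stable hash of an ordered feature-column registry."""
    return hashlib.sha256("|".join(columns).encode()).hexdigest()[:16]


def _date_parts(record: Mapping[str, object]) -> tuple[object, object, object]:
    if "birth_year" in record and not pd.isna(record["birth_year"]):
        return record["birth_year"], record["birth_month"], record["birth_day"]
    raw = str(record.get("birthdate") or "")
    try:
        y, m, d = raw.split("-")
        return int(y), int(m), int(d)
    except ValueError:
        return None, None, None


def _token_jaccard(a: str, b: str) -> float:
    ta, tb = set(a.split()), set(b.split())
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def compare_pair(rec_a: Mapping[str, object], rec_b: Mapping[str, object]) -> dict[str, int]:
    """Comparison vector for one record pair (both records standardized).

    Symmetric in its two arguments.
    """
    fa, fb = str(rec_a.get("first_name") or ""), str(rec_b.get("first_name") or "")
    ma, mb = str(rec_a.get("middle_name") or ""), str(rec_b.get("middle_name") or "")
    la, lb = str(rec_a.get("last_name") or ""), str(rec_b.get("last_name") or "")
    sa, sb = str(rec_a.get("street") or ""), str(rec_b.get("street") or "")
    ca, cb = str(rec_a.get("city") or ""), str(rec_b.get("city") or "")
    za, zb = str(rec_a.get("zip") or ""), str(rec_b.get("zip") or "")
    ya, mo_a, da = _date_parts(rec_a)
    yb, mo_b, db = _date_parts(rec_b)

    def agree(x, y):
        return int(bool(x) and bool(y) and x == y)

    def date_agree(x, y):
        return int(x is not None and y is not None and x == y)

    return {
        "exact_first": agree(fa, fb),
        "exact_middle": agree(ma, mb),
        "exact_last": agree(la, lb),
        "first_initial_match": int(bool(fa) and bool(fb) and fa[0] == fb[0]),
        "jw_first_ge_085": int(bool(fa) and bool(fb) and jaro_winkler(fa, fb) >= JW_THRESHOLD),
        "jw_last_ge_085": int(bool(la) and bool(lb) and jaro_winkler(la, lb) >= JW_THRESHOLD),
        "exact_birth_day": date_agree(da, db),
        "exact_birth_month": date_agree(mo_a, mo_b),
        "exact_birth_year": date_agree(ya, yb),
        "exact_street": agree(sa, sb),
        "street_token_overlap_ge_05": int(
            _token_jaccard(sa, sb) >= STREET_OVERLAP_THRESHOLD
        ),
        "exact_city": agree(ca, cb),
        "exact_zip": agree(za, zb),
        "missing_middle_any": int(not ma or not mb),
        "missing_address_any": int(not sa or not sb),
    }


@dataclass
class FeatureMatrix:
    """Ordered candidate pairs plus their Boolean comparison matrix.

    `frame` columns: id_a, id_b followed by the versioned feature
    registry, rows sorted by (id_a, id_b).
    """

    frame: pd.DataFrame
    columns: tuple[str, ...] = tuple(FEATURE_COLUMNS)

    @property
    def hash(self) -> str:
        return registry_hash(self.columns)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.columns)].to_numpy(dtype=np.int8)

    @property
    def pair_frame(self) -> pd.DataFrame:
        return self.frame[["id_a", "id_b"]]


def _pair_id_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs[["id_a", "id_b"]].copy()
    if hasattr(pairs, "frame"):  # CandidatePairSet
        return pairs.frame[["id_a", "id_b"]].copy()
    return pd.DataFrame(sorted(pairs), columns=["id_a", "id_b"])


def _jw_indicator(names_a: pd.Series, names_b: pd.Series) -> np.ndarray:
    """Thresholded Jaro-Winkler computed once per distinct name pair."""
    df = pd.DataFrame({"a": names_a.to_numpy(), "b": names_b.to_numpy()})
    uniq = df.drop_duplicates()
    vals = {
        (a, b): int(bool(a) and bool(b) and jaro_winkler(a, b) >= JW_THRESHOLD)
        for a, b in zip(uniq["a"], uniq["b"])
    }
    return np.fromiter((vals[t] for t in zip(df["a"], df["b"])), dtype=np.int8, count=len(df))


def _street_overlap_indicator(sa: pd.Series, sb: pd.Series) -> np.ndarray:
    df = pd.DataFrame({"a": sa.to_numpy(), "b": sb.to_numpy()})
    uniq = df.drop_duplicates()
    vals = {
        (a, b): int(_token_jaccard(a, b) >= STREET_OVERLAP_THRESHOLD)
        for a, b in zip(uniq["a"], uniq["b"])
    }
    return np.fromiter((vals[t] for t in zip(df["a"], df["b"])), dtype=np.int8, count=len(df))


def _build_chunk(pairs: pd.DataFrame, table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "source_id", "first_name", "middle_name", "last_name",
        "street", "city", "zip", "birth_year", "birth_month", "birth_day",
    ]
    m = pairs.merge(
        table_a[cols].rename(columns={c: f"{c}_a" for c in cols}),
        left_on="id_a", right_on="source_id_a", how="left",
    ).merge(
        table_b[cols].rename(columns={c: f"{c}_b" for c in cols}),
        left_on="id_b", right_on="source_id_b", how="left",
    )
    dangling = m["source_id_a"].isna() | m["source_id_b"].isna()
    if dangling.any():
        bad = m.loc[dangling, ["id_a", "id_b"]].iloc[0]
        raise KeyError(
            f"candidate pair ({bad['id_a']}, {bad['id_b']}) references a "
            "source_id absent from its table"
        )

    def nb(col):  # non-blank
        return m[col].astype(str) != ""

    def eq(col):
        a, b = m[f"{col}_a"].astype(str), m[f"{col}_b"].astype(str)
        return ((a == b) & nb(f"{col}_a") & nb(f"{col}_b")).to_numpy(dtype=np.int8)

    def date_eq(col):
        a, b = m[f"{col}_a"], m[f"{col}_b"]
        return ((a == b) & a.notna() & b.notna()).to_numpy(dtype=np.int8)

    out = pd.DataFrame({"id_a": m["id_a"], "id_b": m["id_b"]})
    fa = m["first_name_a"].astype(str)
    fb = m["first_name_b"].astype(str)
    out["exact_first"] = eq("first_name")
    out["exact_middle"] = eq("middle_name")
    out["exact_last"] = eq("last_name")
    out["first_initial_match"] = (
        (fa.str.slice(0, 1) == fb.str.slice(0, 1)) & (fa != "") & (fb != "")
    ).to_numpy(dtype=np.int8)
    out["jw_first_ge_085"] = _jw_indicator(fa, fb)
    out["jw_last_ge_085"] = _jw_indicator(m["last_name_a"].astype(str), m["last_name_b"].astype(str))
    out["exact_birth_day"] = date_eq("birth_day")
    out["exact_birth_month"] = date_eq("birth_month")
    out["exact_birth_year"] = date_eq("birth_year")
    out["exact_street"] = eq("street")
    out["street_token_overlap_ge_05"] = _street_overlap_indicator(
        m["street_a"].astype(str), m["street_b"].astype(str)
    )
    out["exact_city"] = eq("city")
    out["exact_zip"] = eq("zip")
    out["missing_middle_any"] = (
        (m["middle_name_a"].astype(str) == "") | (m["middle_name_b"].astype(str) == "")
    ).to_numpy(dtype=np.int8)
    out["missing_address_any"] = (
        (m["street_a"].astype(str) == "") | (m["street_b"].astype(str) == "")
    ).to_numpy(dtype=np.int8)
    return out


def build_matrix(
    pairs,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    chunk_size: int | None = None,
    n_jobs: int = 1,
) -> FeatureMatrix:
    """Vectorized comparison matrix over a candidate pair set.

    Rows follow the canonical pair order (sorted by id_a then id_b);
    chunked evaluation — serial or parallel — is exactly equivalent to
    one-shot evaluation.
    """
    pair_frame = _pair_id_frame(pairs).sort_values(["id_a", "id_b"], ignore_index=True)
    if pair_frame.empty:
        empty = pd.DataFrame(columns=["id_a", "id_b", *FEATURE_COLUMNS])
        return FeatureMatrix(empty)
    if chunk_size is None or chunk_size >= len(pair_frame):
        frame = _build_chunk(pair_frame, table_a, table_b)
    else:
        spans = range(0, len(pair_frame), int(chunk_size))
        if n_jobs == 1:
            chunks = [
                _build_chunk(pair_frame.iloc[i : i + int(chunk_size)], table_a, table_b)
                for i in spans
            ]
        else:
            from joblib import Parallel, delayed

            chunks = Parallel(n_jobs=n_jobs, backend="threading")(
                delayed(_build_chunk)(
                    pair_frame.iloc[i : i + int(chunk_size)], table_a, table_b
                )
                for i in spans
            )
        frame = pd.concat(chunks, ignore_index=True)
    return FeatureMatrix(frame)
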