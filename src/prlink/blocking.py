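"""Candidate-pair generation by TF-IDF character-n-gram name similarity
(pipeline step 2).

The cross-product of two record tables is reduced to candidate pairs: a
pair enters the block when the two first names *or* the two last names
are TF-IDF cosine neighbors (top-k with ties, similarity >= min_sim,
character 4-grams by default) *and* the records agree exactly on birth
month and birth year.

Name similarity is computed once per distinct name string, so cost scales
with vocabulary size rather than table size; candidate pairs are then
assembled with ordinary joins.  Scoring of A-side names proceeds in
batches (`batch_size`) so memory stays bounded on large vocabularies, and
batched execution is exactly equivalent to one-shot execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import TfidfVectorizer

logger = logging.getLogger(__name__)


def char_ngrams(s: str, n: int = 4) -> list[str]:
    """Contiguous character n-grams of `s`, no padding.

    A non-empty string shorter than `n` yields itself as its single
    token; the empty string yields nothing.
    """
    if n < 1:
        raise ValueError(f"n-gram length must be >= 1, got {n}")
    if not s:
        return []
    if len(s) < n:
        return [s]
    return [s[i : i + n] for i in range(len(s) - n + 1)]


class _NgramAnalyzer:
    """Picklable analyzer wrapper around char_ngrams."""

    def __init__(self, n: int):
        self.n = n

    def __call__(self, s: str) -> list[str]:
        return char_ngrams(s, self.n)


class TfidfNameMatcher(BaseEstimator):
    """Top-k TF-IDF cosine neighbors between two name vocabularies.

    Follows the fit/query idiom of nearest-neighbor estimators: `fit` on
    the reference (B-side) names, then `match` a query list.  The IDF
    vocabulary is built on the union of both sides, and every name vector
    is L2-normalized raw-count TF with smoothed IDF, so the dot product
    of two vectors is their cosine similarity.

    Parameters
    ----------
    ngram_length : length of the character n-grams (default 4).
    top_k : neighbors kept per query name; all names tied with the k-th
        best similarity are kept, so exact duplicates are never evicted
        by equal-scored competitors.
    min_sim : minimum cosine similarity (default 0.80).
    batch_size : query names scored per chunk.
    n_jobs : chunks processed in parallel (1 = serial); results are
        identical either way.
    """

    def __init__(
        self,
        ngram_length: int = 4,
        top_k: int = 3,
        min_sim: float = 0.80,
        batch_size: int = 20_000,
        n_jobs: int = 1,
    ):
        self.ngram_length = ngram_length
        self.top_k = top_k
        self.min_sim = min_sim
        self.batch_size = batch_size
        self.n_jobs = n_jobs

    def fit(self, names_b) -> "TfidfNameMatcher":
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if not 0.0 < self.min_sim <= 1.0:
            raise ValueError(f"min_sim must be in (0, 1], got {self.min_sim}")
        self.names_b_ = pd.unique(pd.Series(list(names_b), dtype=object).fillna(""))
        self.names_b_ = np.array([s for s in self.names_b_ if s], dtype=object)
        return self

    def match(self, names_a) -> dict[str, list[str]]:
        """Neighbor map: each distinct non-blank query name -> the B-side
        names with cosine >= min_sim and rank <= top_k (ties included)."""
        uniq_a = pd.unique(pd.Series(list(names_a), dtype=object).fillna(""))
        uniq_a = np.array([s for s in uniq_a if s], dtype=object)
        if len(uniq_a) == 0 or len(self.names_b_) == 0:
            return {}
        vectorizer = TfidfVectorizer(
            analyzer=_NgramAnalyzer(self.ngram_length),
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
            lowercase=False,
        )
        vectorizer.fit(np.concatenate([uniq_a, self.names_b_]))
        mat_a = vectorizer.transform(uniq_a).tocsr()
        mat_b = vectorizer.transform(self.names_b_).tocsr().T.tocsc()

        def _chunk(start: int, stop: int) -> dict[str, list[str]]:
            found: dict[str, list[str]] = {}
            sims = (mat_a[start:stop] @ mat_b).tocsr()
            for r in range(stop - start):
                lo, hi = sims.indptr[r], sims.indptr[r + 1]
                cols = sims.indices[lo:hi]
                vals = sims.data[lo:hi]
                keep = vals >= self.min_sim
                cols, vals = cols[keep], vals[keep]
                if len(cols) == 0:
                    continue
                if len(cols) > self.top_k:
                    kth = np.partition(vals, -self.top_k)[-self.top_k]
                    tie_keep = vals >= kth
                    cols, vals = cols[tie_keep], vals[tie_keep]
                found[uniq_a[start + r]] = sorted(self.names_b_[c] for c in cols)
            return found

        step = max(1, int(self.batch_size))
        spans = [(s, min(s + step, len(uniq_a))) for s in range(0, len(uniq_a), step)]
        if self.n_jobs == 1 or len(spans) == 1:
            chunks = [_chunk(s, e) for s, e in spans]
        else:
            chunks = Parallel(n_jobs=self.n_jobs, backend="threading")(
                delayed(_chunk)(s, e) for s, e in spans
            )
        out: dict[str, list[str]] = {}
        for found in chunks:
            out.update(found)
        return out


def tfidf_topk(
    names_a,
    names_b,
    k: int = 3,
    min_sim: float = 0.80,
    n: int = 4,
    batch_size: int = 20_000,
    n_jobs: int = 1,
) -> dict[str, list[str]]:
    """Functional wrapper over TfidfNameMatcher.fit(names_b).match(names_a)."""
    return TfidfNameMatcher(n, k, min_sim, batch_size, n_jobs).fit(names_b).match(names_a)


@dataclass
class CandidatePairSet:
    """ID pairs surviving blocking, with per-pair provenance.

    `frame` columns: id_a, id_b, matched_on in {first, last, both},
    canonically sorted by (id_a, id_b).
    """

    frame: pd.DataFrame

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["id_a"], self.frame["id_b"]))

    def __len__(self) -> int:
        return len(self.frame)


def _require_standardized(table: pd.DataFrame, which: str) -> None:
    needed = ["source_id", "first_name", "last_name", "birth_year", "birth_month"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(
            f"table_{which} lacks columns {missing}; run preprocess.standardize_table first"
        )


def _name_pair_frame(neighbors: dict[str, list[str]], col: str) -> pd.DataFrame:
    if not neighbors:
        return pd.DataFrame({f"{col}_a": [], f"{col}_b": []}, dtype=object)
    rows_a: list[str] = []
    rows_b: list[str] = []
    for a, bs in neighbors.items():
        rows_a.extend([a] * len(bs))
        rows_b.extend(bs)
    return pd.DataFrame({f"{col}_a": rows_a, f"{col}_b": rows_b})


def block(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k: int = 3,
    min_sim: float = 0.80,
    ngram_length: int = 4,
    batch_size: int = 20_000,
    n_jobs: int = 1,
) -> CandidatePairSet:
    """Blocked candidate pairs between two standardized tables.

    A pair (a, b) is included iff b's first name is a TF-IDF neighbor of
    a's first name OR b's last name is a neighbor of a's last name, AND
    the records agree exactly on birth month and birth year.  Records
    with a missing birthdate produce no pairs; records with both names
    blank are unblockable and counted in a log line.
    """
    _require_standardized(table_a, "a")
    _require_standardized(table_b, "b")

    a = table_a[["source_id", "first_name", "last_name", "birth_year", "birth_month"]].copy()
    b = table_b[["source_id", "first_name", "last_name", "birth_year", "birth_month"]].copy()
    for t, which in ((a, "A"), (b, "B")):
        unblockable = int(((t["first_name"] == "") & (t["last_name"] == "")).sum())
        no_date = int((t["birth_year"].isna() | t["birth_month"].isna()).sum())
        if unblockable or no_date:
            logger.info(
                "block: table %s has %d record(s) with both names blank and "
                "%d with missing birthdate",
                which, unblockable, no_date,
            )
    a = a.dropna(subset=["birth_year", "birth_month"])
    b = b.dropna(subset=["birth_year", "birth_month"])

    parts: dict[str, pd.DataFrame] = {}
    for col in ("first_name", "last_name"):
        matcher = TfidfNameMatcher(ngram_length, k, min_sim, batch_size, n_jobs)
        neighbors = matcher.fit(b[col]).match(a[col])
        link = _name_pair_frame(neighbors, col)
        if link.empty:
            parts[col] = pd.DataFrame({"id_a": [], "id_b": []}, dtype=object)
            continue
        left = a.merge(link, left_on=col, right_on=f"{col}_a", how="inner")
        pairs = left.merge(
            b,
            left_on=[f"{col}_b", "birth_year", "birth_month"],
            right_on=[col, "birth_year", "birth_month"],
            how="inner",
            suffixes=("", "_tb"),
        )[["source_id", "source_id_tb"]]
        pairs.columns = ["id_a", "id_b"]
        parts[col] = pairs.drop_duplicates()

    merged = parts["first_name"].merge(
        parts["last_name"], on=["id_a", "id_b"], how="outer", indicator=True
    )
    merged["matched_on"] = merged["_merge"].map(
        {"both": "both", "left_only": "first", "right_only": "last"}
    ).astype(object)
    frame = merged[["id_a", "id_b", "matched_on"]].sort_values(
        ["id_a", "id_b"], ignore_index=True
    )
    return CandidatePairSet(frame)
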