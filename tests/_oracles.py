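"""Independent brute-force reference implementations used as oracles.

These deliberately share no code with the package: n-gram counting uses
plain Counters, IDF/cosine are computed with math on dicts, and blocking
enumerates the full cross-product.
"""

from __future__ import annotations

import math
from collections import Counter


def ngram_counts(s: str, n: int = 4) -> Counter:
    if not s:
        return Counter()
    if len(s) < n:
        return Counter([s])
    return Counter(s[i : i + n] for i in range(len(s) - n + 1))


def _unique_nonblank(names) -> list[str]:
    seen = {}
    for s in names:
        s = s or ""
        if s and s not in seen:
            seen[s] = None
    return list(seen)


def tfidf_topk_bruteforce(names_a, names_b, k=3, min_sim=0.80, n=4):
    """Dense all-pairs TF-IDF cosine with top-k-plus-ties selection."""
    uniq_a = _unique_nonblank(names_a)
    uniq_b = _unique_nonblank(names_b)
    corpus = uniq_a + uniq_b
    if not uniq_a or not uniq_b:
        return {}
    total = len(corpus)
    doc_freq = Counter(g for name in corpus for g in set(ngram_counts(name, n)))
    idf = {g: math.log((1 + total) / (1 + d)) + 1.0 for g, d in doc_freq.items()}

    def vector(s):
        weights = {g: c * idf[g] for g, c in ngram_counts(s, n).items()}
        norm = math.sqrt(sum(w * w for w in weights.values()))
        return {g: w / norm for g, w in weights.items()} if norm else {}

    vec_a = {s: vector(s) for s in uniq_a}
    vec_b = {s: vector(s) for s in uniq_b}

    out = {}
    for a in uniq_a:
        va = vec_a[a]
        sims = []
        for b in uniq_b:
            s = sum(w * vec_b[b].get(g, 0.0) for g, w in va.items())
            if s >= min_sim:
                sims.append((b, s))
        if not sims:
            continue
        vals = sorted((s for _, s in sims), reverse=True)
        kth = vals[min(k, len(vals)) - 1]
        out[a] = sorted(b for b, s in sims if s >= kth)
    return out


def block_bruteforce(table_a, table_b, k=3, min_sim=0.80, n=4):
    """Cross-product blocking: name-neighbor OR-rule plus exact birth
    month/year agreement.  Returns the set of (id_a, id_b)."""
    nf = tfidf_topk_bruteforce(table_a["first_name"], table_b["first_name"], k, min_sim, n)
    nl = tfidf_topk_bruteforce(table_a["last_name"], table_b["last_name"], k, min_sim, n)
    rows_b = table_b.to_dict("records")
    pairs = set()
    for ra in table_a.to_dict("records"):
        import pandas as pd

        if pd.isna(ra["birth_year"]) or pd.isna(ra["birth_month"]):
            continue
        first_nb = set(nf.get(ra["first_name"], ()))
        last_nb = set(nl.get(ra["last_name"], ()))
        for rb in rows_b:
            if pd.isna(rb["birth_year"]) or pd.isna(rb["birth_month"]):
                continue
            if rb["birth_year"] != ra["birth_year"] or rb["birth_month"] != ra["birth_month"]:
                continue
            if rb["first_name"] in first_nb or rb["last_name"] in last_nb:
                pairs.add((ra["source_id"], rb["source_id"]))
    return pairs
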