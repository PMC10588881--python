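"""Paired synthetic administrative datasets with known ground truth.

The simulator emulates person-level records of the kind held by state
health and human-services agencies (names, birthdate, address, ZIP) and
produces them in *pairs* of tables that share a controlled fraction of
identical individuals (the overlap), after which a controlled fraction of
rows in each table is independently degraded with realistic data-entry
errors.  The set of true cross-table pairs (the truth map) is retained so
downstream linkage can be scored against ground truth.

Three parameters define a scenario: row count, overlap fraction and
error-rate fraction.  The benchmark study grid crosses sizes
{10,000, 50,000, 100,000} with overlaps {1..50%} and error rates
{0..40%}, 168 configurations in total (`study_grid`).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._names import CA_ZIP_CODES, name_pools

SCHEMA_COLUMNS = [
    "source_id", "first_name", "middle_name", "last_name",
    "birthdate", "street", "city", "state", "zip",
]

CORRUPTION_TYPES = (
    "month_resample",
    "both_name_typo",
    "single_name_typo",
    "day_resample",
    "address_resample",
    "middle_name_blank",
)

GRID_SIZES = (10_000, 50_000, 100_000)
GRID_OVERLAPS = (0.01, 0.03, 0.05, 0.10, 0.20, 0.40, 0.50)
GRID_ERROR_RATES = (0.00, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40)

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_ID_ALPHABET = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"))
_ID_WIDTH = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset pair."""

    n_rows: int
    overlap: float
    error_rate: float
    birth_year: int = 2016
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_rows, (int, np.integer)) and self.n_rows >= 1):
            raise ValueError(f"n_rows must be a positive integer, got {self.n_rows!r}")
        for name in ("overlap", "error_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v!r}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed!r}")

    @property
    def n_overlap(self) -> int:
        return int(round(self.overlap * self.n_rows))


@dataclass(frozen=True)
class CorruptionSpec:
    """Mixture over corruption types applied to a degraded row.

    The default weights put 0.65 of the mass on the two corruption types
    that break the blocking stage (a resampled birth month, or typos in
    both names), matching the calibration that blocking retention decays
    as 1 - (2e - e^2) * 0.65 with the per-table error rate e.
    """

    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "month_resample": 0.45,
            "both_name_typo": 0.20,
            "single_name_typo": 0.10,
            "day_resample": 0.10,
            "address_resample": 0.10,
            "middle_name_blank": 0.05,
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CORRUPTION_TYPES)
        if unknown:
            raise ValueError(f"unknown corruption types: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("corruption weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"corruption weights must sum to 1, got {total}")

    def probabilities(self) -> np.ndarray:
        return np.array([self.weights.get(t, 0.0) for t in CORRUPTION_TYPES])


DEFAULT_CORRUPTION = CorruptionSpec()


@dataclass
class DatasetPair:
    """Two record tables plus the ground-truth set of true match pairs."""

    table_a: pd.DataFrame
    table_b: pd.DataFrame
    truth_map: set[tuple[str, str]]
    config: SimulationConfig | None = None


@dataclass
class TrainingPairs:
    """Labeled record pairs for classifier training.

    `frame` has columns id_a, id_b, label with label in {match, nonmatch};
    labels are consistent with the truth map they were drawn from.
    """

    frame: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return (self.frame["label"] == "match").to_numpy()


def study_grid(
    sizes: Sequence[int] = GRID_SIZES,
    overlaps: Sequence[float] = GRID_OVERLAPS,
    error_rates: Sequence[float] = GRID_ERROR_RATES,
    birth_year: int = 2016,
    base_seed: int = 0,
) -> list[SimulationConfig]:
    """Enumerate the full benchmark grid (3 x 7 x 8 = 168 configurations
    with the defaults), one deterministic child seed per cell."""
    configs = []
    for i, n in enumerate(sizes):
        for j, ov in enumerate(overlaps):
            for k, er in enumerate(error_rates):
                seed = base_seed + 10_000 * i + 100 * j + k
                configs.append(SimulationConfig(n, ov, er, birth_year, seed))
    return configs


# ---------------------------------------------------------------------------
# record generation


def _make_source_ids(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random fixed-width alphanumeric IDs, unique within the table."""
    chars = _ID_ALPHABET[rng.integers(0, len(_ID_ALPHABET), size=(n, _ID_WIDTH))]
    ids = np.array(["".join(row) for row in chars])
    while True:
        dup = pd.Index(ids).duplicated()
        if not dup.any():
            return ids
        k = int(dup.sum())
        chars = _ID_ALPHABET[rng.integers(0, len(_ID_ALPHABET), size=(k, _ID_WIDTH))]
        ids[dup] = ["".join(row) for row in chars]


def _generate_individuals(n: int, birth_year: int, rng: np.random.Generator) -> pd.DataFrame:
    """Fresh individuals (no source IDs yet), uniform over the pools."""
    pools = name_pools()
    n_days = 366 if calendar.isleap(birth_year) else 365
    day_of_year = rng.integers(0, n_days, size=n)
    dates = pd.Timestamp(f"{birth_year}-01-01") + pd.to_timedelta(day_of_year, unit="D")
    number = rng.integers(1, 10_000, size=n)
    street = np.char.add(
        np.char.add(number.astype("U5"), " "), rng.choice(pools["street"], size=n)
    )
    return pd.DataFrame(
        {
            "first_name": rng.choice(pools["first"], size=n),
            "middle_name": rng.choice(pools["first"], size=n),
            "last_name": rng.choice(pools["surname"], size=n),
            "birthdate": dates.strftime("%Y-%m-%d"),
            "street": street,
            "city": rng.choice(pools["city"], size=n),
            "state": "CALIFORNIA",
            "zip": rng.choice(np.array(CA_ZIP_CODES), size=n),
        }
    )


# ---------------------------------------------------------------------------
# degradation


def _substitute(s: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(s)))
    c = _LETTERS[int(rng.integers(26))]
    while c == s[i]:
        c = _LETTERS[int(rng.integers(26))]
    return s[:i] + c + s[i + 1:]


def _one_edit(s: str, rng: np.random.Generator) -> str:
    op = int(rng.integers(3))
    if op == 2:  # transpose an adjacent unequal pair
        positions = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
        if positions:
            i = positions[int(rng.integers(len(positions)))]
            return s[:i] + s[i + 1] + s[i] + s[i + 2:]
        op = 0
    if op == 1 and len(s) > 2:  # delete
        i = int(rng.integers(len(s)))
        return s[:i] + s[i + 1:]
    return _substitute(s, rng)


def typo(name: str, rng: np.random.Generator) -> str:
    """Inject a realistic misspelling: one edit for short names, two for
    longer ones (substitute / delete / transpose), never a no-op.

    Two edits on long names reflect that a lone edit at the very edge of a
    long name barely perturbs its character-n-gram profile; misspellings
    that survive fuzzy blocking would defeat the purpose of simulating
    blocking-breaking errors.
    """
    out = name
    n_edits = 1 if len(name) <= 5 else 2
    for _ in range(n_edits):
        out = _one_edit(out, rng)
    if out == name:
        out = _substitute(out, rng)
    return out


def _parse_date(iso: str) -> tuple[int, int, int]:
    y, m, d = iso.split("-")
    return int(y), int(m), int(d)


def degrade_record(
    record: Mapping[str, str],
    spec: CorruptionSpec = DEFAULT_CORRUPTION,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Apply exactly one corruption drawn from `spec` to a copy of `record`.

    The output always differs from the input in at least one field; a
    drawn corruption that would be a no-op (e.g. blanking an already-blank
    middle name) is redrawn.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not record.get("first_name") or not record.get("last_name"):
        raise ValueError("degrade_record requires non-blank first and last names")
    y, m, d = _parse_date(record["birthdate"])

    out = dict(record)
    probs = spec.probabilities()
    while True:
        kind = CORRUPTION_TYPES[int(rng.choice(len(CORRUPTION_TYPES), p=probs))]
        if kind == "month_resample":
            months = [mm for mm in range(1, 13) if mm != m]
            new_m = months[int(rng.integers(11))]
            new_d = min(d, calendar.monthrange(y, new_m)[1])
            out["birthdate"] = f"{y:04d}-{new_m:02d}-{new_d:02d}"
        elif kind == "both_name_typo":
            out["first_name"] = typo(record["first_name"], rng)
            out["last_name"] = typo(record["last_name"], rng)
        elif kind == "single_name_typo":
            which = "first_name" if rng.integers(2) == 0 else "last_name"
            out[which] = typo(record[which], rng)
        elif kind == "day_resample":
            n_days = calendar.monthrange(y, m)[1]
            days = [dd for dd in range(1, n_days + 1) if dd != d]
            new_d = days[int(rng.integers(len(days)))]
            out["birthdate"] = f"{y:04d}-{m:02d}-{new_d:02d}"
        elif kind == "address_resample":
            pools = name_pools()
            while True:
                street = f"{int(rng.integers(1, 10_000))} {rng.choice(pools['street'])}"
                if street != record["street"]:
                    break
            out["street"] = street
            out["city"] = str(rng.choice(pools["city"]))
            out["zip"] = str(rng.choice(np.array(CA_ZIP_CODES)))
        elif kind == "middle_name_blank":
            if not record.get("middle_name"):
                continue  # no-op: redraw another corruption type
            out["middle_name"] = ""
        if out != dict(record):
            return out


def apply_error_rate(
    table: pd.DataFrame,
    error_rate: float,
    spec: CorruptionSpec = DEFAULT_CORRUPTION,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Corrupt exactly round(error_rate * n) distinct rows of a copy of
    `table`; every other row is returned bit-identical."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate!r}")
    if rng is None:
        rng = np.random.default_rng()
    n = len(table)
    k = int(round(error_rate * n))
    out = table.copy()
    if k == 0:
        return out
    idx = np.sort(rng.choice(n, size=k, replace=False))
    records = out.iloc[idx].to_dict("records")
    degraded = [degrade_record(r, spec, rng) for r in records]
    repl = pd.DataFrame(degraded)[out.columns]
    out.iloc[idx] = repl.to_numpy()
    return out


# ---------------------------------------------------------------------------
# dataset pairs


def generate_dataset_pair(
    config: SimulationConfig,
    spec: CorruptionSpec = DEFAULT_CORRUPTION,
) -> DatasetPair:
    """Generate two tables of `config.n_rows` records sharing exactly
    round(overlap * n_rows) field-identical individuals (distinct source
    IDs per table), then degrade each table independently at
    `config.error_rate`.  Deterministic given the config seed."""
    n = config.n_rows
    n_overlap = config.n_overlap
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_people, rng_ida, rng_idb, rng_perm, rng_ea, rng_eb = (
        np.random.Generator(np.random.PCG64(s)) for s in seeds
    )

    people = _generate_individuals(2 * n - n_overlap, config.birth_year, rng_people)
    table_a = people.iloc[:n].reset_index(drop=True).copy()
    table_b = pd.concat(
        [people.iloc[:n_overlap], people.iloc[n:]], ignore_index=True
    ).copy()

    ids_a = _make_source_ids(n, rng_ida)
    ids_b = _make_source_ids(n, rng_idb)
    table_a.insert(0, "source_id", ids_a)
    table_b.insert(0, "source_id", ids_b)
    truth = set(zip(ids_a[:n_overlap], ids_b[:n_overlap]))

    perm = rng_perm.permutation(n)
    table_b = table_b.take(perm).reset_index(drop=True)

    table_a = apply_error_rate(table_a, config.error_rate, spec, rng_ea)
    table_b = apply_error_rate(table_b, config.error_rate, spec, rng_eb)
    return DatasetPair(table_a, table_b, truth, config)


def generate_training_pairs(
    pair: DatasetPair,
    n_match: int = 3000,
    n_nonmatch: int = 2771,
    rng: np.random.Generator | None = None,
    candidates=None,
) -> TrainingPairs:
    """Sample a labeled training set from a simulated pair.

    Matches are drawn from the truth map (so they span clean and degraded
    prototypes in proportion to the pair's error rate).  Nonmatches aim at
    an even split of hard negatives (blocked pairs that are not true
    matches; capped at availability) and easy negatives (random cross
    pairs); labels are correct by construction.
    """
    if rng is None:
        rng = np.random.default_rng()
    truth = sorted(pair.truth_map)
    if n_match > len(truth):
        raise ValueError(
            f"requested {n_match} matches but the pair has only {len(truth)} truth pairs"
        )
    n_universe = len(pair.table_a) * len(pair.table_b) - len(truth)
    if n_nonmatch > n_universe:
        raise ValueError(
            f"requested {n_nonmatch} nonmatches but only {n_universe} cross pairs exist"
        )

    if candidates is None and n_nonmatch > 0:
        from .blocking import block
        from .preprocess import standardize_table

        candidates = block(standardize_table(pair.table_a), standardize_table(pair.table_b))

    chosen_matches = [truth[i] for i in rng.choice(len(truth), size=n_match, replace=False)]

    truth_set = pair.truth_map
    hard_pool = sorted(set(candidates.pairs) - truth_set) if n_nonmatch else []
    n_hard = min(n_nonmatch // 2, len(hard_pool))
    n_easy = n_nonmatch - n_hard
    chosen_hard = [hard_pool[i] for i in rng.choice(len(hard_pool), size=n_hard, replace=False)]

    ids_a = pair.table_a["source_id"].to_numpy()
    ids_b = pair.table_b["source_id"].to_numpy()
    chosen_easy: list[tuple[str, str]] = []
    seen = truth_set | set(chosen_hard)
    while len(chosen_easy) < n_easy:
        a = ids_a[int(rng.integers(len(ids_a)))]
        b = ids_b[int(rng.integers(len(ids_b)))]
        if (a, b) not in seen:
            chosen_easy.append((a, b))
            seen.add((a, b))

    frame = pd.DataFrame(
        chosen_matches + chosen_hard + chosen_easy, columns=["id_a", "id_b"]
    )
    frame["label"] = ["match"] * n_match + ["nonmatch"] * n_nonmatch
    frame = frame.take(rng.permutation(len(frame))).reset_index(drop=True)
    return TrainingPairs(frame)


# ---------------------------------------------------------------------------
# I/O


def write_dataset_pair(pair: DatasetPair, outdir: str | Path) -> dict[str, Path]:
    """Write table_a.csv, table_b.csv and truth_map.csv under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table_a": outdir / "table_a.csv",
        "table_b": outdir / "table_b.csv",
        "truth_map": outdir / "truth_map.csv",
    }
    pair.table_a.to_csv(paths["table_a"], index=False)
    pair.table_b.to_csv(paths["table_b"], index=False)
    pd.DataFrame(sorted(pair.truth_map), columns=["id_a", "id_b"]).to_csv(
        paths["truth_map"], index=False
    )
    return paths


def read_record_table(path: str | Path) -> pd.DataFrame:
    """Read a record table CSV with all fields as text."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table {path} is missing columns: {missing}")
    return df


def read_truth_map(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return set(zip(df["id_a"], df["id_b"]))
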