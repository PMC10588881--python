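"""End-to-end orchestration: simulate/read, clean, block, featurize,
train, score, link, evaluate — one reproducible run driven by a config
mapping (YAML-friendly) with a manifest sufficient to replay the run.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocking import block
from .evaluate import confusion_metrics, simulation_grid_report, threshold_sweep
from .features import build_matrix
from .preprocess import standardize_table
from .scoring import MatchScorer, ModelSpec, classify
from .simulate import (
    DatasetPair,
    SimulationConfig,
    generate_dataset_pair,
    generate_training_pairs,
    read_record_table,
    read_truth_map,
    study_grid,
)

logger = logging.getLogger(__name__)

#: Scenario used to synthesize the default training set: a mid-sized pair
#: with substantial overlap and a 20% error rate, so sampled match
#: prototypes span clean rows and every corruption type.
DEFAULT_TRAINING_SIM = {"n_rows": 20_000, "overlap": 0.5, "error_rate": 0.2}
DEFAULT_TRAINING_SIZES = {"n_match": 3000, "n_nonmatch": 2771}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "threshold": 0.80,
    "batch_size": 20_000,
    "n_jobs": 1,
    "output_dir": None,
    "inputs": {"table_a": None, "table_b": None, "truth_map": None, "training_pairs": None},
    "simulation": {"n_rows": 1000, "overlap": 0.2, "error_rate": 0.1, "birth_year": 2016},
    "blocking": {"k": 3, "min_sim": 0.80, "ngram_length": 4},
    "features": {"chunk_size": None},
    "model": {"algorithm": "gradient_boosted_trees", "grid": None, "cv_folds": 5},
    "training": dict(DEFAULT_TRAINING_SIZES),
    "thresholds": {"sweep": [round(t, 2) for t in np.arange(0.40, 0.951, 0.05)]},
}


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override map."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically with the
    same code version: config snapshot, seeds, stage counts, artifacts."""

    config: dict
    seed: int
    version: str = __version__
    stage_counts: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def train_default_scorer(
    seed: int = 0,
    model_spec: ModelSpec | None = None,
    n_match: int = 3000,
    n_nonmatch: int = 2771,
    sim: Mapping[str, Any] | None = None,
) -> MatchScorer:
    """Train the study's shared scorer on simulator-generated labeled
    pairs (`DEFAULT_TRAINING_SIM` scenario, ~5,771 pairs by default)."""
    sim = dict(DEFAULT_TRAINING_SIM, **(sim or {}))
    config = SimulationConfig(seed=seed, **sim)
    pair = generate_dataset_pair(config)
    ta, tb = standardize_table(pair.table_a), standardize_table(pair.table_b)
    candidates = block(ta, tb)
    rng = np.random.Generator(np.random.PCG64(seed + 1))
    training = generate_training_pairs(pair, n_match, n_nonmatch, rng, candidates=candidates)
    matrix = build_matrix(training.frame, ta, tb)
    # build_matrix sorts canonically; align labels to the sorted pair order
    labels = (
        training.frame.set_index(["id_a", "id_b"])["label"]
        .loc[pd.MultiIndex.from_frame(matrix.pair_frame)]
        .to_numpy()
    )
    spec = model_spec or ModelSpec(seed=seed)
    scorer = MatchScorer(
        algorithm=spec.algorithm,
        param_grid=spec.grid,
        cv_folds=spec.cv_folds,
        random_state=spec.seed,
    )
    return scorer.fit(matrix, labels)


def run_linkage(config: Mapping | str | Path | None = None, **overrides):
    """Execute the full pipeline per config; returns (manifest, result).

    Inputs are either file paths (`inputs:` section) or a simulated pair
    (`simulation:` section, the default).  Stage counts are logged and
    recorded in the manifest; artifacts are persisted when `output_dir`
    is set.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config, overrides)
    else:
        cfg = _deep_update(load_config(), dict(config or {}))
        if overrides:
            cfg = _deep_update(cfg, overrides)

    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed)
    inputs = cfg["inputs"]

    truth = None
    if inputs.get("table_a") and inputs.get("table_b"):
        table_a = read_record_table(inputs["table_a"])
        table_b = read_record_table(inputs["table_b"])
        if inputs.get("truth_map"):
            truth = read_truth_map(inputs["truth_map"])
        pair = DatasetPair(table_a, table_b, truth or set())
    else:
        sim_cfg = SimulationConfig(seed=seed, **cfg["simulation"])
        pair = generate_dataset_pair(sim_cfg)
        truth = pair.truth_map
    manifest.stage_counts["records_a"] = len(pair.table_a)
    manifest.stage_counts["records_b"] = len(pair.table_b)

    ta = standardize_table(pair.table_a)
    tb = standardize_table(pair.table_b)

    bcfg = cfg["blocking"]
    candidates = block(
        ta, tb,
        k=int(bcfg["k"]), min_sim=float(bcfg["min_sim"]),
        ngram_length=int(bcfg["ngram_length"]), batch_size=int(cfg["batch_size"]),
        n_jobs=int(cfg.get("n_jobs", 1)),
    )
    manifest.stage_counts["candidate_pairs"] = len(candidates)
    logger.info("blocking produced %d candidate pairs", len(candidates))

    matrix = build_matrix(
        candidates, ta, tb,
        chunk_size=cfg["features"]["chunk_size"], n_jobs=int(cfg.get("n_jobs", 1)),
    )
    manifest.stage_counts["feature_rows"] = len(matrix.frame)

    mcfg = cfg["model"]
    spec = ModelSpec(
        algorithm=mcfg["algorithm"], grid=mcfg.get("grid"),
        cv_folds=int(mcfg["cv_folds"]), seed=seed,
    )
    if inputs.get("training_pairs"):
        tp = pd.read_csv(inputs["training_pairs"], dtype=str, keep_default_na=False)
        train_matrix = build_matrix(tp[["id_a", "id_b"]], ta, tb)
        labels = (
            tp.set_index(["id_a", "id_b"])["label"]
            .loc[pd.MultiIndex.from_frame(train_matrix.pair_frame)]
            .to_numpy()
        )
        scorer = MatchScorer(
            algorithm=spec.algorithm, param_grid=spec.grid,
            cv_folds=spec.cv_folds, random_state=seed,
        ).fit(train_matrix, labels)
    elif truth:
        tcfg = cfg["training"]
        n_match = min(int(tcfg["n_match"]), len(truth))
        n_universe = len(pair.table_a) * len(pair.table_b) - len(truth)
        n_nonmatch = min(int(tcfg["n_nonmatch"]), n_universe)
        rng = np.random.Generator(np.random.PCG64(seed + 1))
        training = generate_training_pairs(pair, n_match, n_nonmatch, rng, candidates=candidates)
        train_matrix = build_matrix(training.frame, ta, tb)
        labels = (
            training.frame.set_index(["id_a", "id_b"])["label"]
            .loc[pd.MultiIndex.from_frame(train_matrix.pair_frame)]
            .to_numpy()
        )
        scorer = MatchScorer(
            algorithm=spec.algorithm, param_grid=spec.grid,
            cv_folds=spec.cv_folds, random_state=seed,
        ).fit(train_matrix, labels)
    else:
        raise ValueError(
            "no training labels available: provide inputs.training_pairs or a truth map"
        )
    manifest.stage_counts["training_pairs"] = len(labels)

    scored = scorer.score_pairs(matrix, chunk_size=cfg["features"]["chunk_size"])
    result = classify(scored, float(cfg["threshold"]))
    manifest.stage_counts["matched_pairs"] = len(result)
    logger.info("linkage matched %d pairs at threshold %.2f", len(result), result.threshold)

    report = confusion_metrics(result, truth, candidates) if truth else None

    outdir = cfg.get("output_dir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scored.frame.to_csv(outdir / "scores.csv", index=False)
        candidates.frame.to_csv(outdir / "candidate_pairs.csv", index=False)
        pd.DataFrame(sorted(result.matched), columns=["id_a", "id_b"]).to_csv(
            outdir / "matched_pairs.csv", index=False
        )
        scorer.save(outdir / "scorer.joblib")
        if truth:
            sweep = threshold_sweep(scored, truth, candidates, cfg["thresholds"]["sweep"])
            sweep.to_csv(outdir / "threshold_sweep.csv", index=False)
        manifest.artifacts = {p.name: str(p) for p in outdir.iterdir()}
        manifest.write(outdir / "manifest.json")

    return manifest, result, report


def run_simulation_study(
    sizes=(10_000,),
    overlaps=None,
    error_rates=None,
    scorer: MatchScorer | None = None,
    threshold: float = 0.80,
    base_seed: int = 0,
    model_spec: ModelSpec | None = None,
):
    """Grid of simulated linkages scored with one shared model.

    The full benchmark grid is sizes (10k, 50k, 100k) x 7 overlaps x 8
    error rates = 168 configurations; the defaults restrict to one size
    for desk-scale runs.
    """
    from .simulate import GRID_ERROR_RATES, GRID_OVERLAPS

    overlaps = GRID_OVERLAPS if overlaps is None else overlaps
    error_rates = GRID_ERROR_RATES if error_rates is None else error_rates
    configs = study_grid(sizes, overlaps, error_rates, base_seed=base_seed)
    if scorer is None:
        scorer = train_default_scorer(seed=base_seed, model_spec=model_spec)
    return simulation_grid_report(configs, scorer, threshold)


# ---------------------------------------------------------------------------
# tiny deterministic fixture pair (curated, for fast unit tests and docs)


def demo_pair() -> DatasetPair:
    """A hand-curated 20-record pair: 12 shared individuals (some with
    curated typos, month shifts, blanked middles, changed addresses) and
    8 unrelated individuals per side; truth map included.

    Distinct from the statistical simulator: values are fixed literals.
    """
    base = [
        # first, middle, last, birthdate, street, city, zip
        ("MARIA", "ELENA", "GONZALEZ", "2016-03-14", "12 OAKWOOD AVE", "RIVERTON", "90210"),
        ("JAMES", "LEE", "ANDERSON", "2016-07-02", "340 MAPLE ST", "LAKEFIELD", "90001"),
        ("SOPHIA", "ANN", "MARTINEZ", "2016-01-23", "78 SUNSET BLVD", "RIVERTON", "90502"),
        ("LIAM", "JOSEPH", "THOMPSON", "2016-11-30", "9 HARBOR WAY", "BAYWOOD", "94101"),
        ("OLIVIA", "MAE", "ROBERTSON", "2016-05-09", "455 CEDAR LN", "LAKEFIELD", "95814"),
        ("NOAH", "RAY", "WILLIAMSON", "2016-02-17", "23 PINE CT", "BAYWOOD", "92101"),
        ("EMMA", "ROSE", "FERNANDEZ", "2016-09-21", "810 ELM DR", "RIVERTON", "90210"),
        ("LUCAS", "DEAN", "HARRINGTON", "2016-04-04", "66 BIRCH RD", "GLENDALE", "91201"),
        ("MIA", "JUNE", "PATTERSON", "2016-08-15", "301 WILLOW ST", "GLENDALE", "91205"),
        ("ETHAN", "COLE", "RICHARDSON", "2016-06-27", "54 ASPEN WAY", "BAYWOOD", "94102"),
        ("AVA", "CLAIRE", "HENDERSON", "2016-10-11", "220 SPRUCE AVE", "LAKEFIELD", "95812"),
        ("MASON", "JACK", "SULLIVAN", "2016-12-05", "17 WALNUT LN", "RIVERTON", "90503"),
    ]
    extras_a = [
        ("ISABELLA", "GRACE", "MORRISON", "2016-03-03", "5 ALDER CT", "GLENDALE", "91206"),
        ("LOGAN", "PAUL", "STEVENSON", "2016-05-19", "92 LAUREL DR", "BAYWOOD", "94103"),
        ("AMELIA", "JADE", "CARPENTER", "2016-07-07", "61 POPLAR ST", "RIVERTON", "90504"),
        ("ELIJAH", "SCOTT", "MONTGOMERY", "2016-09-09", "840 HOLLY AVE", "LAKEFIELD", "95813"),
        ("HARPER", "LYNN", "DICKINSON", "2016-02-02", "33 JUNIPER WAY", "GLENDALE", "91207"),
        ("OLIVER", "TATE", "FITZGERALD", "2016-04-28", "710 MAGNOLIA RD", "BAYWOOD", "94104"),
        ("EVELYN", "PEARL", "KINGSLEY", "2016-06-16", "28 SYCAMORE LN", "RIVERTON", "90505"),
        ("HENRY", "BLAKE", "WHITFIELD", "2016-08-08", "150 REDWOOD BLVD", "LAKEFIELD", "95815"),
    ]
    extras_b = [
        ("CHLOE", "BETH", "GALLAGHER", "2016-01-12", "44 CHESTNUT ST", "GLENDALE", "91208"),
        ("DANIEL", "REED", "MACARTHUR", "2016-03-25", "67 DOGWOOD CT", "BAYWOOD", "94105"),
        ("GRACE", "FAY", "PENDLETON", "2016-05-31", "201 HICKORY DR", "RIVERTON", "90506"),
        ("SAMUEL", "TROY", "WINCHESTER", "2016-07-18", "88 COTTONWOOD AVE", "LAKEFIELD", "95816"),
        ("LILY", "HOPE", "BLACKWOOD", "2016-09-26", "9 IRONWOOD WAY", "GLENDALE", "91209"),
        ("JACKSON", "NEIL", "CROMWELL", "2016-11-14", "320 BEECH RD", "BAYWOOD", "94106"),
        ("ZOE", "SKY", "ARMSTRONG", "2016-12-22", "73 PALM LN", "RIVERTON", "90507"),
        ("OWEN", "CHASE", "LANCASTER", "2016-10-06", "510 FIR ST", "LAKEFIELD", "95817"),
    ]
    # curated degradations of the shared individuals on the B side:
    b_shared = [list(r) for r in base]
    b_shared[1][0] = "JAMSE"            # first-name transposition
    b_shared[2][3] = "2016-02-23"       # month shift (breaks blocking)
    b_shared[4][1] = ""                 # blanked middle name
    b_shared[5][4] = "907 GRANITE AVE"  # changed address
    b_shared[6][2] = "FERNANDES"        # surname substitution
    b_shared[7][3] = "2016-04-11"       # day shift
    b_shared[9][0] = "ETHN"             # first-name deletion
    b_shared[11][3] = "2016-01-05"      # month shift (breaks blocking)

    def to_frame(rows, prefix):
        recs = []
        for i, (fn, mn, ln, bd, st, ci, zp) in enumerate(rows, start=1):
            recs.append(
                {
                    "source_id": f"{prefix}{i:03d}",
                    "first_name": fn, "middle_name": mn, "last_name": ln,
                    "birthdate": bd, "street": st, "city": ci,
                    "state": "CALIFORNIA", "zip": zp,
                }
            )
        return pd.DataFrame(recs)

    table_a = to_frame(base + extras_a, "A")
    table_b = to_frame([tuple(r) for r in b_shared] + extras_b, "B")
    truth = {(f"A{i:03d}", f"B{i:03d}") for i in range(1, 13)}
    return DatasetPair(table_a, table_b, truth)
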