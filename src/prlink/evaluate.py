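"""Linkage evaluation against ground truth.

Confusion-matrix metrics are computed over the blocked, scored pairs
(what the classifier actually saw), and blocking quality is reported
separately as the proportion of true pairs retained in the block.  Two
variants of a blocking-adjusted sensitivity are reported side by side
because the notion is ambiguous: the primary counts unblocked true pairs
as misses (tp / |truth|), the alternative expresses the unblocked true
pairs as a fraction of all scored pairs.  Undefined ratios (zero
denominators) are reported as missing, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocking import CandidatePairSet
from .scoring import LinkageResult, MatchScorer, ScoredPairs, classify

DEFAULT_SWEEP_THRESHOLDS = tuple(np.round(np.arange(0.40, 0.951, 0.05), 2))


@dataclass
class ConfusionCounts:
    """Confusion counts over blocked, scored pairs plus the true matches
    lost at the blocking stage."""

    tp: int
    fp: int
    fn: int
    tn: int
    unblocked_true_matches: int

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    matches_in_block: float | None
    adjusted_sensitivity_primary: float | None
    adjusted_sensitivity_alt: float | None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "counts"}


@dataclass
class AgreementReport:
    """Set agreement between two linkage solutions' matched pairs."""

    n_a: int
    n_b: int
    n_both: int
    n_a_only: int
    n_b_only: int
    pct_both_of_a: float | None
    pct_both_of_b: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_counts(
    result: LinkageResult,
    truth: set[tuple[str, str]],
    blocked: CandidatePairSet,
) -> ConfusionCounts:
    blocked_pairs = blocked.pairs
    matched = result.matched
    outside = matched - blocked_pairs
    if outside:
        raise ValueError(
            f"{len(outside)} matched pair(s) lie outside the blocked set, e.g. "
            f"{sorted(outside)[0]}"
        )
    truth = set(truth)
    blocked_truth = blocked_pairs & truth
    tp = len(matched & truth)
    fp = len(matched) - tp
    fn = len(blocked_truth) - tp
    tn = len(blocked_pairs) - tp - fp - fn
    return ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=tn,
        unblocked_true_matches=len(truth) - len(blocked_truth),
    )


def confusion_metrics(
    result: LinkageResult,
    truth: set[tuple[str, str]],
    blocked: CandidatePairSet,
) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 over the
    blocked scored pairs, plus blocking retention and the two
    blocking-adjusted sensitivity variants."""
    c = confusion_counts(result, truth, blocked)
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    f1 = None
    if sens is not None and prec is not None and (sens + prec):
        f1 = 2 * prec * sens / (prec + sens)
    n_truth = c.tp + c.fn + c.unblocked_true_matches
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.n_scored),
        sensitivity=sens,
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=prec,
        f1=f1,
        matches_in_block=_ratio(c.tp + c.fn, n_truth),
        adjusted_sensitivity_primary=_ratio(c.tp, n_truth),
        adjusted_sensitivity_alt=_ratio(c.unblocked_true_matches, c.n_scored),
        counts=c,
    )


def blocking_retention(truth: set[tuple[str, str]], blocked: CandidatePairSet) -> float | None:
    """Proportion of true match pairs surviving blocking (a pure blocking
    property, independent of any scorer or threshold)."""
    truth = set(truth)
    return _ratio(len(blocked.pairs & truth), len(truth))


def threshold_sweep(
    scored: ScoredPairs,
    truth: set[tuple[str, str]],
    blocked: CandidatePairSet,
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
) -> pd.DataFrame:
    """One metrics row per threshold (ascending); match counts are
    non-increasing in the threshold."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds) or not all(0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must be sorted ascending and lie in (0, 1]")
    rows = []
    for t in thresholds:
        result = classify(scored, t)
        rep = confusion_metrics(result, truth, blocked)
        rows.append({"threshold": t, "n_matched": len(result), **rep.as_dict()})
    return pd.DataFrame(rows)


def agreement(result_x: LinkageResult, result_y: LinkageResult) -> AgreementReport:
    """Directional overlap between two solutions' matched-pair sets."""
    x, y = set(result_x.matched), set(result_y.matched)
    both = x & y
    return AgreementReport(
        n_a=len(x),
        n_b=len(y),
        n_both=len(both),
        n_a_only=len(x - both),
        n_b_only=len(y - both),
        pct_both_of_a=100.0 * len(both) / len(x) if x else None,
        pct_both_of_b=100.0 * len(both) / len(y) if y else None,
    )


PANEL_METRICS = (
    "accuracy", "sensitivity", "specificity", "precision", "f1",
    "matches_in_block", "adjusted_sensitivity_primary", "adjusted_sensitivity_alt",
)


def evaluate_config(config, scorer: MatchScorer, threshold: float = 0.80) -> MetricsReport:
    """Run the full pipeline on one simulated configuration and score it."""
    from .blocking import block
    from .features import build_matrix
    from .preprocess import standardize_table
    from .simulate import generate_dataset_pair

    pair = generate_dataset_pair(config)
    ta = standardize_table(pair.table_a)
    tb = standardize_table(pair.table_b)
    blocked = block(ta, tb)
    matrix = build_matrix(blocked, ta, tb)
    scored = scorer.score_pairs(matrix)
    result = classify(scored, threshold)
    return confusion_metrics(result, pair.truth_map, blocked)


def simulation_grid_report(
    configs,
    scorer: MatchScorer,
    threshold: float = 0.80,
) -> dict[str, pd.DataFrame]:
    """Per-metric panels (rows = overlap, columns = error rate) for a
    list of simulation configurations, all scored with one shared model."""
    records = []
    for config in configs:
        try:
            rep = evaluate_config(config, scorer, threshold)
        except Exception as exc:  # noqa: BLE001 - echo the failing config
            raise RuntimeError(f"simulation config failed: {config}") from exc
        row = {"n_rows": config.n_rows, "overlap": config.overlap,
               "error_rate": config.error_rate, **rep.as_dict()}
        records.append(row)
    long = pd.DataFrame(records)
    panels = {}
    for metric in PANEL_METRICS:
        panels[metric] = long.pivot_table(
            index="overlap", columns="error_rate", values=metric, aggfunc="mean"
        )
    panels["_long"] = long
    return panels


def write_panels(panels: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric, frame in panels.items():
        path = outdir / f"panel_{metric.lstrip('_')}.csv"
        frame.to_csv(path)
        paths.append(path)
    return paths
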