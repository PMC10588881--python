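"""Simulator: pair generation, truth maps, controlled degradation."""

import numpy as np
import pandas as pd
import pytest

from prlink.blocking import block
from prlink.evaluate import blocking_retention
from prlink.preprocess import standardize_table
from prlink.simulate import (
    DEFAULT_CORRUPTION,
    SCHEMA_COLUMNS,
    CorruptionSpec,
    SimulationConfig,
    apply_error_rate,
    degrade_record,
    generate_dataset_pair,
    generate_training_pairs,
    study_grid,
    typo,
)

FIELDS = [c for c in SCHEMA_COLUMNS if c != "source_id"]


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_rows": 0, "overlap": 0.5, "error_rate": 0.0},
        {"n_rows": 10, "overlap": -0.1, "error_rate": 0.0},
        {"n_rows": 10, "overlap": 0.5, "error_rate": 1.5},
        {"n_rows": 10, "overlap": float("nan"), "error_rate": 0.0},
        {"n_rows": 10, "overlap": 0.5, "error_rate": 0.0, "seed": -1},
    ],
)
def test_config_validation_rejects_bad_values(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_overlap_rows_are_field_identical_at_zero_error():
    pair = generate_dataset_pair(SimulationConfig(10, 0.5, 0.0, seed=1))
    assert len(pair.truth_map) == 5
    a = pair.table_a.set_index("source_id")
    b = pair.table_b.set_index("source_id")
    for id_a, id_b in pair.truth_map:
        assert (a.loc[id_a, FIELDS] == b.loc[id_b, FIELDS]).all()
    # non-overlap rows are distinct individuals
    assert pair.table_a["source_id"].is_unique
    assert pair.table_b["source_id"].is_unique


def test_study_grid_enumerates_full_benchmark():
    configs = study_grid()
    assert len(configs) == 168
    assert len({(c.n_rows, c.overlap, c.error_rate) for c in configs}) == 168
    assert len(study_grid(sizes=(10_000,))) == 56
    assert len(study_grid(sizes=(10_000,), error_rates=(0.0, 0.4))) == 14


@pytest.mark.parametrize("n_rows,overlap", [(100, 0.01), (250, 0.2), (99, 0.5)])
def test_truth_map_cardinality(n_rows, overlap):
    pair = generate_dataset_pair(SimulationConfig(n_rows, overlap, 0.1, seed=2))
    assert len(pair.truth_map) == int(round(overlap * n_rows))
    # each ID appears in at most one truth pair
    ids_a = [a for a, _ in pair.truth_map]
    ids_b = [b for _, b in pair.truth_map]
    assert len(set(ids_a)) == len(ids_a) and len(set(ids_b)) == len(ids_b)


def test_seeded_generation_is_reproducible():
    cfg = SimulationConfig(300, 0.3, 0.25, seed=42)
    p1, p2 = generate_dataset_pair(cfg), generate_dataset_pair(cfg)
    pd.testing.assert_frame_equal(p1.table_a, p2.table_a)
    pd.testing.assert_frame_equal(p1.table_b, p2.table_b)
    assert p1.truth_map == p2.truth_map
    p3 = generate_dataset_pair(SimulationConfig(300, 0.3, 0.25, seed=43))
    assert not p3.table_a.equals(p1.table_a)


class TestDegradeRecord:
    record = {
        "source_id": "X1", "first_name": "ANA", "middle_name": "MARIE",
        "last_name": "LOPEZ", "birthdate": "2016-05-14",
        "street": "12 OAKWOOD AVE", "city": "RIVERTON",
        "state": "CALIFORNIA", "zip": "90210",
    }

    def test_month_resample_always_changes_month(self, rng):
        spec = CorruptionSpec({"month_resample": 1.0})
        for _ in range(50):
            out = degrade_record(self.record, spec, rng)
            assert out["birthdate"][:4] == "2016"
            assert out["birthdate"][5:7] != "05"

    def test_middle_name_blank(self, rng):
        spec = CorruptionSpec({"middle_name_blank": 1.0})
        out = degrade_record(self.record, spec, rng)
        changed = {k for k in self.record if out[k] != self.record[k]}
        assert out["middle_name"] == "" and changed == {"middle_name"}

    def test_output_always_differs(self, rng):
        for _ in range(300):
            out = degrade_record(self.record, DEFAULT_CORRUPTION, rng)
            assert out != self.record

    def test_typo_is_small_edit(self, rng):
        for name in ("ANA", "ROBERT", "WILLIAMSON"):
            for _ in range(50):
                t = typo(name, rng)
                assert t != name and t
                assert abs(len(t) - len(name)) <= 2

    def test_blank_name_rejected(self, rng):
        bad = dict(self.record, first_name="")
        with pytest.raises(ValueError):
            degrade_record(bad, DEFAULT_CORRUPTION, rng)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CorruptionSpec({"month_resample": 0.5, "day_resample": 0.4})
        with pytest.raises(ValueError):
            CorruptionSpec({"month_resample": 1.5, "day_resample": -0.5})
        with pytest.raises(ValueError):
            CorruptionSpec({"not_a_type": 1.0})


class TestApplyErrorRate:
    def test_zero_rate_is_identity(self, small_pair, rng):
        out = apply_error_rate(small_pair.table_a, 0.0, DEFAULT_CORRUPTION, rng)
        pd.testing.assert_frame_equal(out, small_pair.table_a)

    def test_full_rate_touches_every_row(self, rng):
        pair = generate_dataset_pair(SimulationConfig(100, 0.0, 0.0, seed=3))
        out = apply_error_rate(pair.table_a, 1.0, DEFAULT_CORRUPTION, rng)
        differs = (out[FIELDS] != pair.table_a[FIELDS]).any(axis=1)
        assert differs.all()

    def test_exact_row_count_touched(self, rng):
        pair = generate_dataset_pair(SimulationConfig(500, 0.0, 0.0, seed=4))
        out = apply_error_rate(pair.table_a, 0.40, DEFAULT_CORRUPTION, rng)
        differs = (out[FIELDS] != pair.table_a[FIELDS]).any(axis=1)
        assert int(differs.sum()) == 200
        # untouched rows are bit-identical
        pd.testing.assert_frame_equal(out[~differs], pair.table_a[~differs])

    def test_invalid_rate_rejected(self, small_pair, rng):
        with pytest.raises(ValueError):
            apply_error_rate(small_pair.table_a, 1.2, DEFAULT_CORRUPTION, rng)


class TestTrainingPairs:
    def test_labels_consistent_with_truth(self, small_pair, small_candidates, rng):
        tp = generate_training_pairs(small_pair, 60, 80, rng, candidates=small_candidates)
        assert len(tp.frame) == 140
        for _, row in tp.frame.iterrows():
            in_truth = (row["id_a"], row["id_b"]) in small_pair.truth_map
            assert in_truth == (row["label"] == "match")
        assert int(tp.labels.sum()) == 60

    def test_zero_matches_allowed(self, small_pair, small_candidates, rng):
        tp = generate_training_pairs(small_pair, 0, 5, rng, candidates=small_candidates)
        assert len(tp.frame) == 5 and (tp.frame["label"] == "nonmatch").all()

    def test_shortfall_raises(self, small_pair, small_candidates, rng):
        with pytest.raises(ValueError, match="truth pairs"):
            generate_training_pairs(small_pair, 10**6, 10, rng, candidates=small_candidates)


def test_degraded_copy_breaks_blocking_at_calibrated_rate():
    """One-sided degradation breaks the blocking predicate for ~65% of
    records (the two blocking-breaking corruption types carry 0.65 of the
    corruption mass): Monte-Carlo over 10,000 degraded copies."""
    pair = generate_dataset_pair(SimulationConfig(10_000, 1.0, 0.0, seed=5))
    rng = np.random.default_rng(9)
    degraded_b = apply_error_rate(pair.table_b, 1.0, DEFAULT_CORRUPTION, rng)
    cand = block(standardize_table(pair.table_a), standardize_table(degraded_b))
    break_fraction = 1.0 - blocking_retention(pair.truth_map, cand)
    assert abs(break_fraction - 0.65) <= 0.02
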