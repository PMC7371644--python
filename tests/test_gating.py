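import numpy as np
import pandas as pd
import pytest

from gliaflow.cohort import gate_sample
from gliaflow.flow_io import EventTable
from gliaflow.gating import (
    Gate,
    GatingStrategy,
    absolute_count,
    apply_gate,
    classify_events,
    default_strategy,
    find_valley,
    fold_change_vs_reference,
    recovery_scores,
    run_strategy,
    singlet_mask,
    viability_mask,
)


def table_from(arrays: dict) -> EventTable:
    cols = list(arrays)
    values = np.column_stack([np.asarray(arrays[c], dtype=float) for c in cols])
    return EventTable(values, tuple(cols))


class TestGates:
    def test_rectangle_inclusive_bounds(self):
        t = table_from({"x": [0.5, 2.0, 1.0], "y": [0.5, 2.0, 1.0]})
        g = Gate("r", "rectangle", ("x", "y"), {"x": (0, 1), "y": (0, 1)})
        np.testing.assert_array_equal(apply_gate(t, g), [True, False, True])

    def test_threshold_is_strict(self):
        t = table_from({"CD45": [2.9, 3.0, 3.1]})
        g = Gate("pos", "threshold", ("CD45",), {"value": 3.0, "direction": ">"})
        np.testing.assert_array_equal(apply_gate(t, g), [False, False, True])

    def test_polygon_square_equals_rectangle(self, rng):
        pts = rng.uniform(-1, 3, size=(1000, 2))
        t = table_from({"x": pts[:, 0], "y": pts[:, 1]})
        poly = Gate("p", "polygon", ("x", "y"),
                    {"vertices": [(0, 0), (2, 0), (2, 2), (0, 2)]})
        rect = Gate("r", "rectangle", ("x", "y"), {"x": (0, 2), "y": (0, 2)})
        np.testing.assert_array_equal(apply_gate(t, poly), apply_gate(t, rect))

    def test_polygon_boundary_included(self):
        t = table_from({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 2.0]})
        poly = Gate("p", "polygon", ("x", "y"),
                    {"vertices": [(0, 0), (2, 0), (2, 2), (0, 2)]})
        assert apply_gate(t, poly).all()

    def test_collinear_polygon_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            Gate("p", "polygon", ("x", "y"),
                 {"vertices": [(0, 0), (1, 1), (2, 2)]})

    def test_missing_channel_named_in_error(self):
        t = table_from({"x": [1.0]})
        g = Gate("named_gate", "threshold", ("CD45",), {"value": 0.0})
        with pytest.raises(KeyError, match="named_gate"):
            apply_gate(t, g)

    def test_gate_idempotent(self, rng):
        t = table_from({"x": rng.normal(size=500), "y": rng.normal(size=500)})
        g = Gate("r", "rectangle", ("x", "y"), {"x": (-1, 1), "y": (-1, 1)})
        once = apply_gate(t, g)
        twice = apply_gate(t, g, once)
        np.testing.assert_array_equal(once, twice)


class TestSingletViability:
    def test_singlet_band_examples(self):
        t = table_from({"FSC-A": [100.0, 200.0, -5.0], "FSC-H": [95.0, 100.0, 90.0]})
        mask = singlet_mask(t, (0.75, 1.1))
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_bad_band_rejected(self):
        t = table_from({"FSC-A": [1.0], "FSC-H": [1.0]})
        with pytest.raises(ValueError, match="lo < hi"):
            singlet_mask(t, (1.1, 0.75))

    def test_doublet_exclusion_on_synthetic_sample(self, sham_sample):
        table, manifest = sham_sample
        mask = singlet_mask(table)
        doublets = manifest.labels == "doublet"
        assert (~mask[doublets]).mean() >= 0.95

    def test_valley_threshold_keeps_live(self, cci_sample):
        table, manifest = cci_sample
        t, _ = gate_sample(table, None)
        live = viability_mask(t)
        truly_live = ~np.isin(manifest.labels, ["dead"])
        assert live[manifest.labels == "microglia"].mean() >= 0.98
        assert (~live[manifest.labels == "dead"]).mean() >= 0.98

    def test_all_live_with_high_threshold(self):
        t = table_from({"Viability": np.linspace(0, 1, 50)})
        assert viability_mask(t, threshold=2.0).all()

    def test_dead_only_sample(self):
        t = table_from({"Viability": np.full(50, 5.0)})
        assert not viability_mask(t, threshold=2.0).any()

    def test_unimodal_falls_back(self, rng, caplog):
        vals = rng.normal(0.5, 0.1, size=2000)
        with pytest.raises(ValueError):
            find_valley(vals)
        t = table_from({"Viability": vals})
        mask = viability_mask(t, fallback=2.0)  # falls back, logged
        assert mask.all()


class TestStrategy:
    def test_duplicate_names_rejected(self):
        g = Gate("a", "threshold", ("x",), {"value": 0})
        with pytest.raises(ValueError, match="unique"):
            GatingStrategy(((g, None), (g, None)))

    def test_parent_must_precede_child(self):
        g1 = Gate("a", "threshold", ("x",), {"value": 0})
        g2 = Gate("b", "threshold", ("x",), {"value": 0})
        with pytest.raises(ValueError, match="parent"):
            GatingStrategy(((g2, "a"), (g1, None)))

    def test_round_trip_serialization(self):
        s = default_strategy()
        s2 = GatingStrategy.from_dict(s.to_dict())
        assert s2.names == s.names

    def test_masks_strictly_nested(self, cci_sample):
        table, _ = cci_sample
        t, res = gate_sample(table, None)
        order = dict(default_strategy().nodes and
                     [(g.name, p) for g, p in default_strategy().nodes])
        for name, parent in order.items():
            if parent is not None:
                child, par = res.masks[name], res.masks[parent]
                assert not (child & ~par).any()

    def test_empty_table_gives_zero_populations(self):
        channels = ("FSC-A", "FSC-H", "SSC-A", "Viability", "CD45",
                    "CD11b/c", "P2y12", "BeadID")
        t = EventTable(np.empty((0, len(channels))), channels)
        res = run_strategy(t, default_strategy())
        assert (res.table["events"] == 0).all()

    def test_microglia_recovery_within_5pct(self, sham_sample):
        table, manifest = sham_sample
        _, res = gate_sample(table, None)
        recovered = int(res.masks["microglia"].sum())
        truth = manifest.counts["microglia"]
        assert abs(recovered - truth) / truth <= 0.05

    def test_classification_f1(self, cci_sample):
        table, manifest = cci_sample
        _, res = gate_sample(table, None)
        scores = recovery_scores(classify_events(res), manifest.labels)
        assert (scores["f1"] >= 0.95).all()


class TestQuantification:
    def test_worked_example(self):
        r = absolute_count(5000, 1000, 10_000, 50.0)
        assert r.cells_per_mg == 1000.0

    def test_zero_events(self):
        assert absolute_count(0, 1000, 10_000, 50.0).cells_per_mg == 0.0

    def test_linearity(self):
        base = absolute_count(5000, 1000, 10_000, 50.0).cells_per_mg
        assert absolute_count(10_000, 1000, 10_000, 50.0).cells_per_mg == 2 * base
        assert absolute_count(5000, 1000, 20_000, 50.0).cells_per_mg == 2 * base
        assert absolute_count(5000, 2000, 10_000, 50.0).cells_per_mg == base / 2
        assert absolute_count(5000, 1000, 10_000, 100.0).cells_per_mg == base / 2

    def test_zero_beads_rejected(self):
        with pytest.raises(ValueError, match="bead_events"):
            absolute_count(5000, 0, 10_000, 50.0)

    def test_fold_change_worked_example(self):
        counts = {"CCI-ipsi": 1600.0, "sham-ipsi": 100.0,
                  "sham-contra": 100.0, "CCI-contra": 100.0}
        ref = ["sham-ipsi", "sham-contra", "CCI-contra"]
        assert fold_change_vs_reference(counts, ref, "CCI-ipsi") == 16.0

    def test_fold_change_all_equal(self):
        counts = {c: 5.0 for c in ("a", "b", "t")}
        assert fold_change_vs_reference(counts, ["a", "b"], "t") == 1.0

    def test_fold_change_empty_reference(self):
        with pytest.raises(ValueError, match="non-empty"):
            fold_change_vs_reference({"t": 1.0}, [], "t")
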