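"""Phase-mapper unit and property tests."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from geoparticle import phasemap as pm
from oracles import majority_vote_3x3, min_area_claimant_labels, pixelwise_median


def _stack(maps, **kw):
    return pm.ElementMapStack(maps=maps, **kw)


class TestElementMapStack:
    def test_direct_construction(self):
        maps = {el: np.zeros((64, 64)) for el in ("Si", "Ca", "Fe")}
        stack = _stack(maps)
        assert stack.elements == {"Si", "Ca", "Fe"}
        assert stack.width == stack.height == 64

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            _stack({"Si": np.zeros((4, 4)), "Ca": np.zeros((5, 4))})

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="no element maps"):
            _stack({})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _stack({"Si": np.full((3, 3), -1.0)})


class TestLoadElementMaps:
    def test_roundtrip_from_directory(self, tmp_path):
        import tifffile

        for el, val in (("Si", 10), ("Ca", 20), ("Fe", 30)):
            tifffile.imwrite(tmp_path / f"{el}.tif", np.full((64, 64), val, dtype=np.uint8))
        stack = pm.load_element_maps(tmp_path)
        assert stack.elements == {"Si", "Ca", "Fe"}
        assert stack.shape == (64, 64)
        assert stack.maps["Ca"][0, 0] == 20

    def test_mismatched_files_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "Si.tif", np.zeros((8, 8), dtype=np.uint8))
        tifffile.imwrite(tmp_path / "Ca.tif", np.zeros((9, 8), dtype=np.uint8))
        with pytest.raises(ValueError, match="dimension mismatch"):
            pm.load_element_maps(tmp_path)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no element maps found"):
            pm.load_element_maps(tmp_path)


class TestFlattenMedian:
    def test_single_element_is_identity(self):
        si = np.arange(16.0).reshape(4, 4)
        stack = _stack({"Si": si, "Ca": np.zeros((4, 4))})
        np.testing.assert_array_equal(pm.flatten_median(stack, {"Si"}), si)

    def test_constant_rasters_scalar_median(self):
        stack = _stack({e: np.full((3, 3), v) for e, v in (("A", 1.0), ("B", 5.0), ("C", 9.0))})
        np.testing.assert_array_equal(pm.flatten_median(stack, {"A", "B", "C"}), np.full((3, 3), 5.0))

    def test_matches_pixelwise_sort_oracle(self, rng):
        maps = {e: rng.integers(0, 100, size=(4, 4)).astype(float) for e in ("Si", "Al", "Ca")}
        stack = _stack(maps)
        flat = pm.flatten_median(stack, {"Si", "Al", "Ca"})
        np.testing.assert_allclose(flat, pixelwise_median(list(maps.values())))

    def test_unknown_element_named_in_error(self):
        stack = _stack({"Si": np.zeros((2, 2))})
        with pytest.raises(KeyError, match="Xx"):
            pm.flatten_median(stack, {"Si", "Xx"})


class TestMakePhaseMask:
    def test_uniform_pass_and_fail(self):
        flat = np.full((5, 7), 10.0)
        passing = pm.make_phase_mask(flat, pm.PhaseDefinition("p", {"Si"}, 5, denoise_radius=0))
        failing = pm.make_phase_mask(flat, pm.PhaseDefinition("p", {"Si"}, 20, denoise_radius=0))
        assert passing.area_px == 35 and passing.mask.all()
        assert failing.area_px == 0

    def test_threshold_is_inclusive(self):
        flat = np.full((2, 2), 7.0)
        mask = pm.make_phase_mask(flat, pm.PhaseDefinition("p", {"Si"}, 7.0, denoise_radius=0))
        assert mask.mask.all()

    def test_radius1_despeckle_matches_majority_vote_oracle(self, rng):
        flat = rng.integers(0, 2, size=(9, 9)).astype(float) * 10
        d = pm.PhaseDefinition("p", {"Si"}, 5, denoise_radius=1)
        got = pm.make_phase_mask(flat, d).mask
        np.testing.assert_array_equal(got, majority_vote_3x3(flat >= 5))

    def test_isolated_pixel_removed(self):
        flat = np.zeros((9, 9))
        flat[4, 4] = 10
        mask = pm.make_phase_mask(flat, pm.PhaseDefinition("p", {"Si"}, 5, denoise_radius=1))
        assert mask.area_px == 0

    def test_radius0_is_identity(self, rng):
        flat = rng.uniform(0, 100, size=(12, 12))
        d0 = pm.PhaseDefinition("p", {"Si"}, 50, denoise_radius=0)
        np.testing.assert_array_equal(pm.make_phase_mask(flat, d0).mask, flat >= 50)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError, match="denoise_radius"):
            pm.PhaseDefinition("p", {"Si"}, 5, denoise_radius=-1)


def _defs(names):
    return [pm.PhaseDefinition(n, {"Si"}, 0, denoise_radius=0) for n in names]


class TestAssemblePhaseMap:
    def test_single_full_coverage_phase(self):
        mask = pm.PhaseMask("all", np.ones((10, 10), dtype=bool))
        result = pm.assemble_phase_map([mask], _defs(["all"]))
        assert result.legend[0][0] == "all"
        assert result.legend[0][3] == 100.0
        assert result.unassigned_pct == 0.0

    def test_smaller_phase_wins_overlap(self):
        big = np.zeros((10, 20), dtype=bool)
        big[:, :15] = True  # 150 px
        small = np.zeros((10, 20), dtype=bool)
        small[4:6, 5:10] = True  # 10 px, inside big
        result = pm.assemble_phase_map(
            [pm.PhaseMask("A", big), pm.PhaseMask("B", small)], _defs(["A", "B"])
        )
        names = dict(zip(result.phase_names, range(1, 3)))
        got_b = result.labels == [i + 1 for i, r in enumerate(result.legend) if r[0] == "B"][0]
        np.testing.assert_array_equal(got_b, small)
        fractions = {r[0]: r[3] for r in result.legend}
        assert fractions["B"] == pytest.approx(100 * 10 / 200)
        assert fractions["A"] == pytest.approx(100 * 140 / 200)

    def test_disjoint_phases_additive(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:3, :] = True  # 30%
        b = np.zeros((10, 10), dtype=bool)
        b[5:7, :] = True  # 20%
        result = pm.assemble_phase_map([pm.PhaseMask("a", a), pm.PhaseMask("b", b)], _defs(["a", "b"]))
        fractions = {r[0]: r[3] for r in result.legend}
        assert fractions == {"a": pytest.approx(30.0), "b": pytest.approx(20.0)}
        assert result.unassigned_pct == pytest.approx(50.0)

    def test_matches_min_area_claimant_oracle(self, rng):
        masks = {n: rng.random((16, 16)) < p for n, p in (("a", 0.5), ("b", 0.3), ("c", 0.2))}
        result = pm.assemble_phase_map(
            [pm.PhaseMask(n, m) for n, m in masks.items()], _defs(list(masks))
        )
        expected = min_area_claimant_labels(masks)
        name_of = {i + 1: r[0] for i, r in enumerate(result.legend)}
        name_of[0] = ""
        got = np.vectorize(name_of.get)(result.labels)
        np.testing.assert_array_equal(got.astype(object), expected)

    def test_order_invariance(self, rng):
        masks = [pm.PhaseMask(n, rng.random((12, 12)) < 0.4) for n in ("x", "y", "z")]
        defs = _defs(["x", "y", "z"])
        base = pm.assemble_phase_map(masks, defs)
        perm = pm.assemble_phase_map(masks[::-1], defs[::-1])
        np.testing.assert_array_equal(base.labels, perm.labels)
        assert base.legend == perm.legend

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            pm.assemble_phase_map(
                [pm.PhaseMask("a", np.ones((3, 3), bool)), pm.PhaseMask("b", np.ones((4, 3), bool))],
                _defs(["a", "b"]),
            )


class TestAreaFractions:
    def test_direct_count(self):
        labels = np.zeros((10, 10), dtype=int)
        labels.ravel()[:46] = 1
        result = pm.PhaseMap(labels=labels, legend=(("silica", frozenset({"Si"}), (255, 0, 0), 46.0),))
        table = pm.measure_area_fractions(result)
        assert table.rows["silica"] == pytest.approx(46.0)

    def test_empty_labeling_all_unassigned(self):
        table = pm.measure_area_fractions(pm.PhaseMap(labels=np.zeros((5, 5), int), legend=()))
        assert table.unassigned_pct == 100.0

    def test_conservation_sums_to_100(self, rng):
        masks = [pm.PhaseMask(n, rng.random((20, 20)) < 0.4) for n in ("a", "b", "c", "d")]
        table = pm.measure_area_fractions(pm.assemble_phase_map(masks, _defs(["a", "b", "c", "d"])))
        assert sum(table.rows.values()) + table.unassigned_pct == pytest.approx(100.0, abs=0.01)

    def test_calibrated_total_area(self):
        labels = np.ones((10, 10), dtype=int)
        result = pm.PhaseMap(labels=labels, legend=(("p", frozenset({"Si"}), (1, 2, 3), 100.0),))
        table = pm.measure_area_fractions(result, pixel_size=0.5)
        assert table.total_area_quantified == pytest.approx(25.0)
        assert table.area_unit == "um2"

    def test_quantified_normalization(self):
        labels = np.zeros((10, 10), dtype=int)
        labels.ravel()[:30] = 1
        labels.ravel()[30:50] = 2
        result = pm.PhaseMap(
            labels=labels,
            legend=(
                ("a", frozenset({"Si"}), (1, 1, 1), 30.0),
                ("b", frozenset({"Ca"}), (2, 2, 2), 20.0),
            ),
        )
        table = pm.measure_area_fractions(result)
        assert table.rows_of_quantified["a"] == pytest.approx(60.0)
        assert table.rows_of_quantified["b"] == pytest.approx(40.0)


def _table(rows):
    unassigned = 100.0 - sum(rows.values())
    return pm.PhaseProportionTable(
        rows=rows, unassigned_pct=unassigned, total_area_quantified=100.0, area_unit="px"
    )


class TestCompareAnalysts:
    def test_identity(self):
        t = _table({"q": 46.0, "f": 31.0})
        diff = pm.compare_analysts(t, t)
        assert all(v == 0 for v in diff.per_phase_abs_diff.values())

    def test_known_differences(self):
        a = _table({"q": 46.0, "f": 31.0})
        b = _table({"q": 45.9, "f": 36.3})
        diff = pm.compare_analysts(a, b)
        assert diff.per_phase_abs_diff["q"] == pytest.approx(0.1)
        assert diff.per_phase_abs_diff["f"] == pytest.approx(5.3)

    def test_symmetry_and_asymmetric_support(self):
        a = _table({"q": 40.0, "extra": 5.0})
        b = _table({"q": 42.0})
        d_ab, d_ba = pm.compare_analysts(a, b), pm.compare_analysts(b, a)
        assert d_ab.per_phase_abs_diff == d_ba.per_phase_abs_diff
        assert d_ab.phases_only_in_one == frozenset({"extra"})
        assert "extra" not in d_ab.per_phase_abs_diff


class TestRecipesAndRendering:
    def test_recipe_yaml_roundtrip(self, tmp_path):
        recipe = {
            "phases": {
                "quartz": {"elements": ["Si"], "threshold": 120, "color": [230, 60, 60]},
                "calcite": {"elements": ["Ca"], "threshold": 110, "denoise_radius": 2},
            }
        }
        path = tmp_path / "recipe.yaml"
        path.write_text(yaml.safe_dump(recipe))
        defs = pm.load_recipe(path)
        by_name = {d.name: d for d in defs}
        assert by_name["quartz"].color == (230, 60, 60)
        assert by_name["calcite"].denoise_radius == 2
        assert by_name["calcite"].denoise_radius == 2

    def test_presets_available(self):
        presets = pm.load_presets()
        assert set(presets["plagioclase feldspar"]) == {"Al", "Si", "Ca", "Na"}

    def test_legend_rows_ordered_by_descending_area(self, rng):
        masks = [
            pm.PhaseMask("small", rng.random((20, 20)) < 0.1),
            pm.PhaseMask("large", rng.random((20, 20)) < 0.6),
            pm.PhaseMask("mid", rng.random((20, 20)) < 0.3),
        ]
        result = pm.assemble_phase_map(masks, _defs(["small", "large", "mid"]))
        fracs = [r[3] for r in result.legend]
        assert fracs == sorted(fracs, reverse=True)

    def test_render_deterministic_and_single_phase(self, tmp_path):
        mask = pm.PhaseMask("only", np.ones((8, 8), dtype=bool))
        result = pm.assemble_phase_map([mask], _defs(["only"]))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        pm.render_legend(result, p1)
        pm.render_legend(result, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rgb_colors_bit_exact(self):
        d = pm.PhaseDefinition("p", {"Si"}, 0, color=(12, 200, 7), denoise_radius=0)
        result = pm.assemble_phase_map([pm.PhaseMask("p", np.ones((4, 4), bool))], [d])
        rgb = pm.phase_map_to_rgb(result)
        assert tuple(rgb[0, 0]) == (12, 200, 7)
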