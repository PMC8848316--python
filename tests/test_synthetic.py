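"""Layout, light map, morphotypes, rendering and experiment generation."""

import math

import numpy as np
import pandas as pd
import pytest

from phenograd.gradient import fit_descriptor_gradient
from phenograd.synthetic import (
    EffectCurve,
    GradientConfig,
    LayoutConfig,
    RenderConfig,
    RenderError,
    build_layout,
    build_light_map,
    default_morphotypes,
    default_schedule,
    generate_experiment,
    make_morphotype,
    render_scene,
    simulate_descriptor_table,
)
from phenograd.synthetic.light import LightPoint, column_log_ratios

SEVEN = {
    "rosette": 4, "caulescent": 3, "bush-spurge": 3, "bush-herb": 3,
    "grass-temperate": 3, "grass-erect": 3, "grass-c4": 3,
}


class TestLayout:
    def test_per_species_pot_counts(self):
        layout = build_layout(LayoutConfig(species_rows=dict(SEVEN)), seed=0)
        counts = pd.Series([p.species for p in layout.pots]).value_counts()
        assert counts["rosette"] == 48
        for sp, n in SEVEN.items():
            if sp != "rosette":
                assert counts[sp] == 36

    def test_uids_unique_and_within_grid(self):
        cfg = LayoutConfig(species_rows=dict(SEVEN))
        layout = build_layout(cfg, seed=5)
        uids = layout.pot_uids
        assert len(uids) == len(set(uids)) == 264
        for p in layout.pots:
            assert 0 <= p.row < cfg.rows_per_room
            assert 0 <= p.column < cfg.columns_per_room

    def test_blocks_contiguous_rows_single_room(self):
        layout = build_layout(LayoutConfig(species_rows=dict(SEVEN)), seed=2)
        for sp in SEVEN:
            pots = layout.pots_of(sp)
            assert len({p.room for p in pots}) == 1
            rows = sorted({p.row for p in pots})
            assert rows == list(range(rows[0], rows[0] + SEVEN[sp]))

    def test_deterministic_given_seed(self):
        cfg = LayoutConfig(species_rows=dict(SEVEN))
        assert build_layout(cfg, 9).pots == build_layout(cfg, 9).pots
        a = build_layout(cfg, 1).pots
        b = build_layout(cfg, 2).pots
        assert [p.replicate for p in a] != [p.replicate for p in b]

    def test_capacity_error(self):
        cfg = LayoutConfig(species_rows={f"s{i}": 3 for i in range(30)},
                           room_labels=("A",))
        with pytest.raises(ValueError, match="capacity"):
            build_layout(cfg, 0)

    def test_oversized_block_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_layout(LayoutConfig(species_rows={"x": 11}), 0)


class TestLightMap:
    def test_log_ratio_monotone_across_columns(self):
        ln = column_log_ratios(GradientConfig(), 12)
        assert (np.diff(ln) > 0).all()
        assert ln[0] == pytest.approx(math.log(0.1))
        assert ln[-1] == pytest.approx(math.log(10.0))

    def test_zero_noise_hits_setpoints(self, small_layout):
        cfg = GradientConfig(ratio_noise_sd=0.0)
        pts = build_light_map(small_layout, cfg, seed=1)
        ln = column_log_ratios(cfg, 12)
        by_uid = {p.uid: p for p in small_layout.pots}
        for lp in pts:
            assert math.log(lp.ratio) == pytest.approx(
                ln[by_uid[lp.pot_uid].column], abs=1e-12)

    def test_degenerate_gradient_single_ratio(self, small_layout):
        cfg = GradientConfig(min_ratio=2.0, max_ratio=2.0, ratio_noise_sd=0.0)
        pts = build_light_map(small_layout, cfg, seed=1)
        assert {round(p.ratio, 12) for p in pts} == {2.0}

    def test_ratio_consistent_with_pfd_and_ppfd_in_band(self, small_light):
        for lp in small_light:
            assert lp.ratio == pytest.approx(lp.red_pfd / lp.blue_pfd)
            assert 100.0 <= lp.ppfd <= 150.0

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            GradientConfig(min_ratio=0.0)

    def test_deterministic(self, small_layout):
        cfg = GradientConfig()
        assert build_light_map(small_layout, cfg, 7) == build_light_map(
            small_layout, cfg, 7)


class TestEffectCurve:
    def test_zero_before_onset(self):
        c = EffectCurve(40, onset_day=5, peak_day=15)
        assert c.percent(0) == 0.0 and c.percent(5) == 0.0

    def test_peak_at_peak_day(self):
        c = EffectCurve(40, onset_day=0, peak_day=14, decay=1.5)
        days = np.arange(0, 40, 0.5)
        vals = [c.percent(d) for d in days]
        assert days[int(np.argmax(vals))] == pytest.approx(14, abs=0.5)
        assert max(vals) == pytest.approx(40)

    def test_decay_zero_is_sustained(self):
        c = EffectCurve(40, onset_day=0, peak_day=14, decay=0.0)
        assert c.percent(14) == 40 and c.percent(50) == 40
        assert c.percent(7) == pytest.approx(20)


class TestMorphotypeMeans:
    def test_day_zero_independent_of_ratio(self, morphotypes):
        m = morphotypes["caulescent"]
        lo = m.descriptor_mean("side_HeightMax", 0, math.log(0.1),
                               math.log(0.1), math.log(10))
        hi = m.descriptor_mean("side_HeightMax", 0, math.log(10),
                               math.log(0.1), math.log(10))
        assert lo == hi

    def test_programmed_percent_across_span(self, morphotypes):
        m = morphotypes["caulescent"]
        day = 14  # peak of its transient height response (+40%)
        lo = m.descriptor_mean("side_HeightMax", day, math.log(0.1),
                               math.log(0.1), math.log(10))
        hi = m.descriptor_mean("side_HeightMax", day, math.log(10),
                               math.log(0.1), math.log(10))
        assert 100 * (hi - lo) / lo == pytest.approx(40.0, rel=1e-9)

    def test_growth_monotone(self, morphotypes):
        m = morphotypes["grass-erect"]
        g = [m.growth_scale(d) for d in (0, 7, 14, 28)]
        assert g == sorted(g) and 0 < g[0] < 1


class TestRenderScene:
    def test_deterministic_pixels(self, morphotypes):
        lp = LightPoint("A:00:00", 50, 10, 5.0, 120)
        a = render_scene(morphotypes["grass-erect"], lp, 14, seed=3)
        b = render_scene(morphotypes["grass-erect"], lp, 14, seed=3)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.pixels, rb.pixels)

    def test_seed_changes_only_noise(self, morphotypes):
        lp = LightPoint("A:00:00", 50, 10, 5.0, 120)
        m = morphotypes["caulescent"]
        heights = [render_scene(m, lp, 14, seed=s).targets["height_mm"]
                   for s in range(20)]
        mean_target = m.descriptor_mean(
            "side_HeightMax", 14, math.log(5.0), math.log(0.1), math.log(10))
        # 20 draws at noise CV 10%: mean within ~4 SE, spread below 4 sigma
        assert np.mean(heights) == pytest.approx(mean_target, rel=0.10)
        assert np.std(heights) < 0.4 * mean_target

    def test_true_masks_match_plant_pixels(self, caulescent_scene):
        # plant pixels differ from the uniform background exactly on the mask
        rec = caulescent_scene.record("side", 2)
        mask = caulescent_scene.true_masks[("side", 2)]
        bg = rec.pixels[~mask].astype(float).mean(axis=0)
        assert bg.mean() > 230  # back-lit white
        plant = rec.pixels[mask].astype(float).mean(axis=0)
        assert plant[1] > plant[0] and plant[1] > plant[2]  # green

    def test_side_and_top_backgrounds(self, caulescent_scene):
        side = caulescent_scene.record("side", 0)
        top = caulescent_scene.record("top")
        smask = caulescent_scene.true_masks[("side", 0)]
        tmask = caulescent_scene.true_masks[("top", 0)]
        assert side.pixels[~smask].mean() > 200
        assert top.pixels[~tmask].mean() < 50

    def test_oversized_plant_raises_not_clips(self, morphotypes):
        lp = LightPoint("A:00:00", 50, 10, 5.0, 120)
        big = make_morphotype("big", "caulescent", height_mm=900,
                              spread_mm=200, color=(60, 130, 60))
        with pytest.raises(RenderError, match="frame"):
            render_scene(big, lp, 28, seed=0)

    def test_negative_day_rejected(self, morphotypes):
        lp = LightPoint("A:00:00", 50, 10, 5.0, 120)
        with pytest.raises(ValueError):
            render_scene(morphotypes["rosette"], lp, -1, seed=0)

    def test_zero_effects_ground_truth_independent_of_ratio(self):
        """With all effect curves removed, fitted slope CI covers 0."""
        m = make_morphotype("null", "caulescent", height_mm=200,
                            spread_mm=140, color=(60, 130, 60))
        rng = np.random.default_rng(8)
        ratios = np.exp(rng.uniform(math.log(0.1), math.log(10), 36))
        heights = []
        for i, r in enumerate(ratios):
            lp = LightPoint(f"A:00:{i:02d}", 4 * r, 4.0, float(r), 120.0)
            heights.append(render_scene(m, lp, 21, seed=100 + i)
                           .targets["height_mm"])
        fit = fit_descriptor_gradient(heights, ratios)
        t = 2.03  # ~t(34) 97.5%
        assert abs(fit.slope) <= t * fit.slope_se


class TestSchedule:
    def test_twice_weekly_session_count(self):
        days = default_schedule(treatment_days=30, sessions_per_week=2)
        assert days[0] == 0 and days == sorted(days)
        assert 8 <= len(days) <= 9

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            default_schedule(sessions_per_week=0)


class TestGenerateExperiment(object):
    def test_file_count_and_determinism(self, tmp_path, morphotypes):
        layout = build_layout(LayoutConfig(
            species_rows={"caulescent": 1}, columns_per_room=6), seed=1)
        light = build_light_map(layout, GradientConfig(), seed=2)
        morphs = {"caulescent": morphotypes["caulescent"]}
        days = [0, 14]
        p1 = generate_experiment(layout, light, morphs, days, 3,
                                 tmp_path / "run1")
        files = sorted(f.name for f in p1["images"].iterdir())
        assert len(files) == 6 * len(days) * 7  # pots x days x (6 side + top)
        meta = pd.read_csv(p1["metadata"])
        assert list(meta.columns[:8]) == [
            "pot_uid", "species", "room", "row", "column", "ratio", "ppfd",
            "day"]
        p2 = generate_experiment(layout, light, morphs, days, 3,
                                 tmp_path / "run2")
        assert (p1["metadata"].read_bytes() == p2["metadata"].read_bytes())
        assert (p1["ground_truth"].read_bytes()
                == p2["ground_truth"].read_bytes())

    def test_empty_schedule_rejected(self, small_layout, small_light,
                                     morphotypes, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            generate_experiment(small_layout, small_light, morphotypes, [],
                                0, tmp_path)

    def test_failure_carries_pot_uid(self, tmp_path, morphotypes):
        layout = build_layout(LayoutConfig(
            species_rows={"big": 1}, columns_per_room=2), seed=1)
        light = build_light_map(layout, GradientConfig(), seed=2)
        big = make_morphotype("big", "caulescent", height_mm=900,
                              spread_mm=200, color=(60, 130, 60))
        with pytest.raises(RuntimeError, match=r"pot .*:00"):
            generate_experiment(layout, light, {"big": big}, [28], 0,
                                tmp_path / "x")


class TestSimulatedTable:
    def test_schema_and_determinism(self, small_layout, small_light,
                                    morphotypes):
        from phenograd.descriptors import DESCRIPTOR_COLUMNS

        morphs = {"caulescent": morphotypes["caulescent"]}
        t1 = simulate_descriptor_table(small_layout, small_light, morphs,
                                       [0, 14], seed=4)
        t2 = simulate_descriptor_table(small_layout, small_light, morphs,
                                       [0, 14], seed=4)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(DESCRIPTOR_COLUMNS) <= set(t1.columns)
        assert len(t1) == 36 * 2

    def test_indices_consistent_with_simulated_rgb(self, small_layout,
                                                   small_light, morphotypes):
        from phenograd.descriptors import color_indices

        morphs = {"caulescent": morphotypes["caulescent"]}
        t = simulate_descriptor_table(small_layout, small_light, morphs,
                                      [14], seed=5)
        row = t.iloc[0]
        idx = color_indices(row["top_RedMean"], row["top_GreenMean"],
                            row["top_BlueMean"])
        assert row["top_GLI"] == pytest.approx(idx["GLI"])
        assert row["top_Chl_predicted"] == pytest.approx(idx["Chl_predicted"])
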