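"""Generator contracts: panel layout, determinism, prevalence, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hybridcyc as h
from hybridcyc.errors import DimensionError, GenerationError
from hybridcyc.synthetic import marker_column

from conftest import disk_labels


PANEL_BY_ROUND = {
    1: ["ECAD", "EpCAM", "panCK", "CD45"],
    2: ["CK19", "Ki67", "pAKT", "CD44"],
    3: ["CK8", "VIM", "EGFR"],
    4: ["CK7", "aSMA", "VWF"],
}


class TestLayout:
    def test_default_panel_matches_four_round_design(self, layout):
        assert len(layout.marker_names) == 14
        for r, markers in PANEL_BY_ROUND.items():
            assert [m.name for m in layout.markers_in_round(r)] == markers

    def test_gating_markers_required(self):
        from hybridcyc.layout import MarkerSpec, RoundLayout
        from hybridcyc.errors import LayoutError

        with pytest.raises(LayoutError, match="gating markers"):
            RoundLayout(markers=[MarkerSpec("ECAD", 1, "AF488")])

    def test_yaml_round_trip(self, layout, tmp_path):
        p = tmp_path / "layout.yaml"
        layout.to_yaml(p)
        back = h.RoundLayout.from_yaml(p)
        assert back.to_dict() == layout.to_dict()


class TestGeneratePopulation:
    def test_table_has_all_panel_marker_columns(self, layout):
        table, _ = h.generate_cell_population(h.tissue_population_config(n_cells=50, seed=0))
        for m in layout.marker_names:
            for comp in ("whole_cell", "nucleus", "cytoplasm"):
                assert marker_column(m, comp) in table.columns

    def test_zero_hybrid_fraction_yields_no_hybrid_truth_rows(self):
        cfg = h.tissue_population_config(n_cells=400, hybrid_fraction=0.0, seed=1)
        _, truth = h.generate_cell_population(cfg)
        assert (truth["true_class"] == "hybrid").sum() == 0

    def test_seeded_class_sampling_reproducible_by_independent_redraw(self):
        """The class assignment is the generator's first seeded draw, so an
        independent rng with the same seed reproduces the hybrid count."""
        cfg = h.tissue_population_config(n_cells=1000, hybrid_fraction=0.10, seed=42)
        _, truth = h.generate_cell_population(cfg)
        rng = np.random.default_rng(42)
        classes = ["epithelial", "leukocyte", "stromal", "hybrid"]
        p = np.array([cfg.class_fractions[c] for c in classes])
        redraw = rng.choice(classes, size=1000, p=p)
        assert (truth["true_class"] == "hybrid").sum() == (redraw == "hybrid").sum()
        assert list(truth["true_class"]) == list(redraw)

    def test_determinism_bit_identical_tables(self):
        cfg = h.tissue_population_config(n_cells=200, seed=5)
        t1, tr1 = h.generate_cell_population(cfg)
        t2, tr2 = h.generate_cell_population(h.tissue_population_config(n_cells=200, seed=5))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_truth_aligned_and_subpop_only_for_hybrids(self):
        cfg = h.tissue_population_config(n_cells=500, hybrid_fraction=0.2, seed=2)
        table, truth = h.generate_cell_population(cfg)
        assert list(table["cell_id"]) == list(truth["cell_id"])
        assert truth["cell_id"].is_unique
        is_h = truth["true_class"] == "hybrid"
        assert (truth.loc[is_h, "true_subpop"] != "").all()
        assert (truth.loc[~is_h, "true_subpop"] == "").all()

    def test_marker_mismatch_raises_dimension_error(self, layout):
        cfg = h.tissue_population_config(n_cells=10, seed=0)
        cfg.base_log_means = cfg.base_log_means.iloc[:, :-1]
        cfg.subpop_log_means = cfg.subpop_log_means.iloc[:, :-1]
        with pytest.raises(DimensionError):
            h.generate_cell_population(cfg, layout)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(GenerationError, match="sum"):
            h.PopulationConfig(
                n_cells=10,
                specimen_type="tissue",
                class_fractions={"epithelial": 0.5, "leukocyte": 0.2, "stromal": 0.2, "hybrid": 0.2},
                base_log_means=h.tissue_population_config(n_cells=1).base_log_means,
                subpop_log_means=h.tissue_population_config(n_cells=1).subpop_log_means,
            )

    def test_prevalence_binomial_coverage(self):
        """Realized hybrid fraction is binomial around the configured one:
        the 95% CI at n=10,000 should contain the target in >=95% of seeds."""
        target = 0.01
        n, covered, n_seeds = 10_000, 0, 100
        for seed in range(n_seeds):
            cfg = h.tissue_population_config(n_cells=n, hybrid_fraction=target, seed=seed)
            _, truth = h.generate_cell_population(cfg)
            k = int((truth["true_class"] == "hybrid").sum())
            lo, hi = stats.binom.interval(0.95, n, target)
            covered += lo <= k <= hi
        assert covered >= 95


class TestValidationSpecimen:
    def test_is_only_condition_has_no_population_contrast(self, layout):
        table, _ = h.generate_validation_specimen(
            "EpCAM", "cancer", "is_only", layout, n_cancer=300, n_pbmc=300, seed=0
        )
        col = marker_column("EpCAM", "whole_cell")
        cancer = table.loc[table["population_label"] == "cancer", col].mean()
        pbmc = table.loc[table["population_label"] == "pbmc", col].mean()
        assert abs(cancer / pbmc - 1) < 0.1

    def test_stained_condition_shows_configured_contrast(self, layout):
        table, truth = h.generate_validation_specimen(
            "EpCAM", "cancer", "aboligo_is", layout, n_cancer=300, n_pbmc=300, contrast=5.0, seed=1
        )
        col = marker_column("EpCAM", "whole_cell")
        cancer = table.loc[table["population_label"] == "cancer", col].mean()
        pbmc = table.loc[table["population_label"] == "pbmc", col].mean()
        assert cancer / pbmc == pytest.approx(5.0, rel=0.15)
        assert truth["is_positive"].sum() == 300

    def test_unstained_marker_has_no_positive_cells(self, layout):
        table, truth = h.generate_validation_specimen("VWF", "none", "aboligo_is", layout, seed=2)
        assert truth["is_positive"].sum() == 0
        col = marker_column("VWF", "whole_cell")
        cancer = table.loc[table["population_label"] == "cancer", col].mean()
        pbmc = table.loc[table["population_label"] == "pbmc", col].mean()
        assert abs(cancer / pbmc - 1) < 0.2


class TestPlacement:
    def test_minimum_spacing_and_margin(self):
        rc = h.RenderConfig(image_shape=(200, 200), cell_radius=8, nucleus_radius=4, seed=1)
        centers = h.place_cells(40, rc)
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * rc.cell_radius
        assert centers.min() >= rc.cell_radius
        assert (centers[:, 0] <= 200 - rc.cell_radius).all()

    def test_overpacked_frame_raises(self):
        rc = h.RenderConfig(image_shape=(64, 64), cell_radius=9, nucleus_radius=4, seed=1)
        with pytest.raises(GenerationError, match="place"):
            h.place_cells(50, rc)


class TestRendering:
    def test_noise_free_nucleus_mean_equals_assigned_dapi(self, layout, small_scene):
        stacks, channels = small_scene["stacks"], small_scene["channels"]
        truth, table, rc = small_scene["truth"], small_scene["table"], small_scene["rc"]
        dapi = stacks[1][channels[1].index("DAPI")]
        labels = disk_labels(rc.image_shape, truth[["y", "x"]].to_numpy(), rc.nucleus_radius)
        for i, val in enumerate(table["dapi_mean"], start=1):
            assert np.mean(dapi[labels == i]) == pytest.approx(val, abs=1e-6)

    def test_round0_contains_only_autofluorescence_channels(self, layout, small_scene):
        assert small_scene["channels"][0] == ["DAPI", "background"]

    def test_zero_residual_fraction_gives_no_carryover(self, layout):
        cfg = h.tissue_population_config(n_cells=5, seed=4)
        table, truth = h.generate_cell_population(cfg, layout)
        rc = h.RenderConfig(image_shape=(120, 120), residual_signal_fraction=0.0, seed=9)
        stacks, channels = h.render_image_rounds(table, truth, layout, rc)
        # with carryover, round 2's AF488 channel would add ECAD (round 1 AF488)
        ck19 = stacks[2][channels[2].index("AF488")]
        labels = disk_labels(rc.image_shape, truth[["y", "x"]].to_numpy(), rc.cell_radius)
        for i, val in enumerate(table[marker_column("CK19", "whole_cell")], start=1):
            assert np.mean(ck19[labels == i]) == pytest.approx(val, abs=1e-6)

    def test_residual_fraction_carries_previous_round_signal(self, layout):
        cfg = h.tissue_population_config(n_cells=5, seed=4)
        table, truth = h.generate_cell_population(cfg, layout)
        rc = h.RenderConfig(image_shape=(120, 120), residual_signal_fraction=0.25, seed=9)
        stacks, channels = h.render_image_rounds(table, truth, layout, rc)
        ch = channels[2].index("AF488")
        labels = disk_labels(rc.image_shape, truth[["y", "x"]].to_numpy(), rc.cell_radius)
        ck19 = table[marker_column("CK19", "whole_cell")].to_numpy()
        ecad = table[marker_column("ECAD", "whole_cell")].to_numpy()
        for i in range(len(table)):
            expected = ck19[i] + 0.25 * ecad[i]
            assert np.mean(stacks[2][ch][labels == i + 1]) == pytest.approx(expected, rel=1e-9)

    def test_determinism_bit_identical_stacks(self, layout):
        cfg = h.tissue_population_config(n_cells=10, seed=6)
        out = []
        for _ in range(2):
            table, truth = h.generate_cell_population(cfg, layout)
            rc = h.RenderConfig(image_shape=(128, 128), noise_model="gaussian", seed=11)
            stacks, _ = h.render_image_rounds(table, truth, layout, rc)
            out.append(stacks)
        for r in out[0]:
            assert np.array_equal(out[0][r], out[1][r])

    def test_image_round_trip_io(self, layout, small_scene, tmp_path):
        from hybridcyc.synthetic import read_image_rounds, write_image_rounds

        write_image_rounds(tmp_path, small_scene["stacks"], small_scene["channels"])
        stacks, channels = read_image_rounds(tmp_path)
        assert channels == small_scene["channels"]
        for r in stacks:
            assert np.allclose(stacks[r], small_scene["stacks"][r])
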