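"""Population statistics, significance tests and the error budget."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import strobomech as sm


def exact_mannwhitney_p(a, b):
    """Oracle: exact two-sided Mann-Whitney p by enumerating all splits."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        sa = [pooled[i] for i in idx_a]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in sa for y in sb)
        return u

    u_obs = u_stat(tuple(range(n_a)))
    n_bb = len(pooled) - n_a
    mid = n_a * n_bb / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = u_stat(idx)
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


def make_table(values_by_label, **extra):
    rows = []
    for label, vals in values_by_label.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "box_row": i,
                    "box_col": hash(label) % 97,
                    "x_um": float(i),
                    "y_um": 0.0,
                    "label": label,
                    "g_abs": float(v),
                    "g_storage": float(v) * 0.7,
                    "g_loss": float(v) * 0.7,
                    "edge_dist_um": extra.get("edge", {}).get(label, [np.nan] * len(vals))[i],
                    "cell_id": extra.get("cell_ids", {}).get(label, [0] * len(vals))[i],
                }
            )
    return pd.DataFrame(rows)


class TestMannWhitney:
    def test_disjoint_small_samples_match_exact_enumeration(self):
        a, b = [1, 2, 3], [4, 5, 6]
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)
        assert exact_mannwhitney_p(a, b) == pytest.approx(0.1)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_scipy_matches_enumeration_for_tiny_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(20)[:4].tolist()
        b = (rng.permutation(20)[:5] + 0.5).tolist()  # offset avoids ties
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(exact_mannwhitney_p(a, b), rel=1e-9)

    def test_identical_groups_are_indistinguishable(self):
        vals = list(range(1, 41))
        table = make_table({"a": vals, "b": vals})
        out = sm.population_stats(table)
        assert out["tests"]["a vs b"]["g_abs"]["p"] >= 0.99

    def test_populations_with_paperlike_contrast_separate(self):
        rng = np.random.default_rng(0)
        soft = 4400.0 * np.exp(0.35 * rng.standard_normal(800))
        stiff = 6300.0 * np.exp(0.35 * rng.standard_normal(800))
        table = make_table({"soft": soft, "stiff": stiff})
        out = sm.population_stats(table)
        assert out["tests"]["soft vs stiff"]["g_abs"]["p"] < 1e-3


class TestPopulationStats:
    def test_summary_fields_and_nonnormality(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.standard_normal(500))
        out = sm.population_stats(make_table({"only": vals}))
        entry = out["groups"]["only"]["g_abs"]
        assert entry["q1"] < entry["median"] < entry["q3"]
        assert entry["shapiro_p"] < 1e-3  # lognormal data: clearly non-normal
        assert out["tests"] == {}  # single group: tests skipped

    def test_small_groups_are_summarized_but_not_tested(self):
        table = make_table({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = sm.population_stats(table, min_group_size=20)
        assert set(out["groups"]) == {"a", "b"}
        assert out["tests"] == {}


class TestEdgeProfile:
    def test_flat_modulus_gives_flat_profile(self):
        rng = np.random.default_rng(2)
        n = 400
        vals = 5000 + 50 * rng.standard_normal(n)
        edge = {"a": rng.uniform(0, 12, n).tolist()}
        prof = sm.edge_profile(make_table({"a": vals}, edge=edge), bin_width_um=3.0)
        means = prof["mean"].to_numpy()
        sems = prof["sem"].to_numpy()
        assert np.all(np.abs(means - means.mean()) < 4 * sems)

    def test_soft_centre_profile_decreases_inward(self):
        rng = np.random.default_rng(3)
        n = 600
        edge_d = rng.uniform(0, 10, n)
        vals = 6000 - 300 * edge_d + 100 * rng.standard_normal(n)
        prof = sm.edge_profile(make_table({"a": vals}, edge={"a": edge_d.tolist()}), 2.0)
        means = prof.sort_values("bin_center_um")["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_empty_group_gives_empty_profile(self):
        prof = sm.edge_profile(make_table({"a": [1.0, 2.0]}), 2.0)  # edge distances NaN
        assert prof.empty


class TestLossVsStorage:
    def test_identity_line_population(self):
        vals = np.linspace(100, 1000, 50)
        df = make_table({"a": vals})  # g_storage == g_loss by construction
        out = sm.loss_vs_storage(df)
        assert np.allclose(out["g_storage"], out["g_loss"])
        assert np.all(np.isfinite(out["density"]))

    def test_tiny_sample_does_not_fail(self):
        out = sm.loss_vs_storage(make_table({"a": [1.0, 2.0]}))
        assert len(out) == 2
        assert np.all(np.isfinite(out["density"]))


class TestBlankStrainNoise:
    def make_strains(self, amp_cells, amp_blank, n=30):
        gamma = np.zeros((n, n), complex)
        cells = np.zeros((n, n), bool)
        blank = np.zeros((n, n), bool)
        cells[:, : n // 2] = True
        blank[:, n // 2 :] = True
        gamma[cells] = amp_cells
        gamma[blank] = amp_blank
        return (
            sm.StrainMaps(
                gamma_p=gamma,
                gamma_s=gamma,
                ddx_dx=gamma,
                ddx_dy=gamma,
                ddy_dx=gamma,
                ddy_dy=gamma,
                valid=np.ones((n, n), bool),
                spacing_um=2.57,
            ),
            blank,
            cells,
        )

    def test_noise_free_blank_is_zero(self):
        strains, blank, cells = self.make_strains(0.01, 0.0)
        assert sm.blank_strain_noise(strains, blank, cells) == 0.0

    def test_ratio_value(self):
        strains, blank, cells = self.make_strains(0.01, 0.0005)
        assert sm.blank_strain_noise(strains, blank, cells) == pytest.approx(0.05)

    def test_overlapping_blank_rejected(self):
        strains, blank, cells = self.make_strains(0.01, 0.0005)
        with pytest.raises(ValueError, match="overlap"):
            sm.blank_strain_noise(strains, blank | cells, cells)

    def test_too_small_blank_rejected(self):
        strains, blank, cells = self.make_strains(0.01, 0.0005, n=10)
        with pytest.raises(ValueError, match="blank region"):
            sm.blank_strain_noise(strains, blank, cells)


class TestErrorBudget:
    def test_quadrature_propagation_reported_values(self):
        # flow 30% and strain 5% combine to "of the order of 30%"
        assert sm.propagate_errors(0.30, 0.05) == pytest.approx(0.30414, abs=5e-5)

    def test_propagation_limits(self):
        assert sm.propagate_errors(0.123, 0.0) == pytest.approx(0.123)
        assert sm.propagate_errors(0.3, 0.4) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a=st.floats(0, 1), b=st.floats(0, 1), c=st.floats(0, 1)
    )
    def test_propagation_symmetric_and_monotone(self, a, b, c):
        assert sm.propagate_errors(a, b) == pytest.approx(sm.propagate_errors(b, a))
        assert sm.propagate_errors(a + c, b) >= sm.propagate_errors(a, b)

    def test_depth_of_field_bound(self):
        # +-0.87 um depth of field over R_b = 1.5 um: ~60% systematic bound
        assert sm.depth_of_field_bias(0.87, 1.5) == pytest.approx(0.58)
        assert sm.depth_of_field_bias(0.0, 1.5) == 0.0
        assert sm.depth_of_field_bias(1.5, 1.5) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sm.propagate_errors(-0.1, 0.2)
        with pytest.raises(ValueError):
            sm.depth_of_field_bias(0.87, 0.0)


class TestPlots:
    def test_figures_render_and_save(self, tmp_path):
        from strobomech import plots

        rng = np.random.default_rng(4)
        n = 120
        table = make_table(
            {"green": 4000 + 500 * rng.standard_normal(n),
             "orange": 6000 + 500 * rng.standard_normal(n)},
            edge={"green": rng.uniform(0, 8, n).tolist(),
                  "orange": rng.uniform(0, 8, n).tolist()},
        )
        plots.modulus_boxplots(table, tmp_path / "box.png")
        plots.loss_storage_scatter(table, tmp_path / "scatter.png")
        plots.edge_profile_plot(table, path=tmp_path / "profile.png")
        for name in ("box.png", "scatter.png", "profile.png"):
            assert (tmp_path / name).stat().st_size > 0


class TestCellBasedTable:
    def test_collapses_boxes_to_cells(self):
        table = make_table(
            {"a": [1.0, 2.0, 3.0, 10.0, 20.0]},
            cell_ids={"a": [1, 1, 1, 2, 2]},
        )
        cells = sm.cell_based_table(table)
        assert len(cells) == 2
        assert cells.set_index("cell_id").loc[1, "g_abs"] == pytest.approx(2.0)
        assert cells.set_index("cell_id").loc[2, "g_abs"] == pytest.approx(15.0)

    def test_unassigned_boxes_are_ignored(self):
        table = make_table({"unassigned": [5.0, 6.0]}, cell_ids={"unassigned": [3, 3]})
        assert sm.cell_based_table(table).empty
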