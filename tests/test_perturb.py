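"""Filtering, normalization, OLS effect estimation, cell cycle, jackknife."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from traitgraph.perturb import (
    EmptyDataError,
    assign_cell_cycle_phase,
    estimate_effects,
    filter_cells_genes,
    lognormalize,
    phase_fractions_jackknife,
)
from traitgraph.synthetic import CellData


def _make_cells(counts, perturbation=None, batch=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "perturbation": perturbation or [CellData.NON_TARGETING] * n_cells,
            "batch": batch or ["b0"] * n_cells,
            "n_genes": (counts > 0).sum(axis=0),
            "pct_mito": np.zeros(n_cells),
        },
        index=pd.Index(cells, name="cell"),
    )
    return CellData(sparse.csr_matrix(counts), genes, cells, obs)


def brute_force_filter(counts, min_genes, min_cells):
    """Independent two-pass reference: rows are genes, columns cells."""
    counts = np.asarray(counts)
    keep_cells = [(counts[:, j] > 0).sum() >= min_genes
                  for j in range(counts.shape[1])]
    stage = counts[:, keep_cells]
    keep_genes = [(stage[i] > 0).sum() >= min_cells
                  for i in range(stage.shape[0])]
    return stage[keep_genes].shape


class TestFilter:
    def test_zero_thresholds_are_identity(self, small_cells):
        out = filter_cells_genes(small_cells, 0, 0)
        assert out.counts.shape == small_cells.counts.shape

    def test_toy_cell_below_threshold_dropped(self):
        counts = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 0]])
        data = _make_cells(counts)
        out = filter_cells_genes(data, min_genes_per_cell=2, min_cells_per_gene=0)
        assert out.cells == ["c0", "c1"]

    def test_matches_brute_force_reference(self, small_cells):
        out = filter_cells_genes(small_cells, 30, 40)
        expected = brute_force_filter(
            np.asarray(small_cells.counts.todense()), 30, 40
        )
        assert out.counts.shape == expected

    def test_all_cells_removed_raises(self):
        data = _make_cells(np.zeros((3, 3), dtype=int))
        with pytest.raises(EmptyDataError):
            filter_cells_genes(data, min_genes_per_cell=1, min_cells_per_gene=0)


class TestLognormalize:
    def test_zero_count_maps_to_zero(self):
        data = _make_cells([[0, 2], [3, 1]])
        X = lognormalize(data)
        assert X[0, 0] == 0.0

    def test_closed_form_value(self):
        col = np.zeros((100, 1), dtype=int)
        col[0] = 10
        col[1:] = 0
        col[1] = 9990  # total 10,000
        X = lognormalize(_make_cells(col), scale=10_000)
        assert X[0, 0] == pytest.approx(np.log(11), rel=1e-12)

    def test_depth_invariance(self):
        a = _make_cells([[2], [8]])
        b = _make_cells([[4], [16]])
        np.testing.assert_allclose(lognormalize(a), lognormalize(b))

    def test_zero_total_cell_raises_with_cell_name(self):
        data = _make_cells([[0, 1], [0, 1]])
        with pytest.raises(EmptyDataError, match="c0"):
            lognormalize(data)


class TestEstimateEffects:
    def test_no_covariate_signal_equals_group_mean_difference(self, rng):
        n_pert, n_nt = 30, 50
        resp = rng.normal(0, 1, n_pert + n_nt)
        counts = np.ones((2, n_pert + n_nt), dtype=int)
        labels = ["gX"] * n_pert + [CellData.NON_TARGETING] * n_nt
        data = _make_cells(counts, perturbation=labels)
        # constant covariates -> dropped internally; beta = mean difference
        responses = pd.DataFrame({"r": resp}, index=data.cells)
        table = estimate_effects(data, responses, fdr_family="per_response")
        beta = table.loc[table["response"] == "r", "beta"].item()
        assert beta == pytest.approx(
            resp[:n_pert].mean() - resp[n_pert:].mean(), abs=1e-10
        )

    def test_planted_halving_recovers_minus_log2(self):
        # knockdown halves gene 0's expression; depth fixed so logFC is exact
        n = 200
        counts = np.zeros((3, 2 * n), dtype=int)
        counts[0, :n] = 50       # perturbed cells
        counts[0, n:] = 100      # non-targeting
        counts[1] = 500
        counts[2, :n] = 450
        counts[2, n:] = 400
        labels = ["g0"] * n + [CellData.NON_TARGETING] * n
        data = _make_cells(counts, perturbation=labels)
        X = lognormalize(data, scale=1000)
        responses = pd.DataFrame(X.T, index=data.cells, columns=data.genes)
        table = estimate_effects(data, responses, fdr_family="per_perturbation")
        beta = table.loc[table["response"] == "g0", "beta"].item()
        assert beta == pytest.approx(np.log(51 / 101), abs=0.01)
        assert table.loc[table["response"] == "g0", "self_response"].item()

    def test_constant_response_is_zero_effect_p_one(self):
        counts = np.ones((2, 40), dtype=int)
        labels = ["g0"] * 20 + [CellData.NON_TARGETING] * 20
        data = _make_cells(counts, perturbation=labels)
        responses = pd.DataFrame({"flat": np.ones(40)}, index=data.cells)
        table = estimate_effects(data, responses)
        assert table["beta"].item() == 0.0
        assert table["p_value"].item() == 1.0

    def test_insufficient_cells_target_skipped_not_crashed(self, rng):
        counts = rng.poisson(5, (3, 30))
        labels = ["g0"] * 2 + [CellData.NON_TARGETING] * 28
        data = _make_cells(counts, perturbation=labels)
        responses = pd.DataFrame({"r": rng.normal(size=30)}, index=data.cells)
        table = estimate_effects(data, responses)
        assert table["status"].str.startswith("skipped").all()

    def test_null_relabeling_calibrated_type_one_error(self, rng):
        # non-targeting cells relabeled into fake targets: p ~ Uniform
        n_cells = 2100
        counts = rng.poisson(20, (30, n_cells))
        labels = [CellData.NON_TARGETING] * n_cells
        for t in range(100):
            for j in range(15):
                labels[t * 15 + j] = f"fake{t:03d}"
        batch = list(rng.choice(["b0", "b1"], n_cells))
        data = _make_cells(counts, perturbation=labels, batch=batch)
        X = lognormalize(data)
        responses = pd.DataFrame(
            X[:25].T, index=data.cells, columns=data.genes[:25]
        )
        table = estimate_effects(data, responses, fdr_family="per_perturbation")
        pvals = table.loc[table["status"] == "ok", "p_value"].to_numpy()
        assert len(pvals) == 2500
        rate = (pvals < 0.05).mean()
        assert 0.03 <= rate <= 0.07
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bh_fdr_is_monotone_step_function(self, rng):
        counts = rng.poisson(10, (20, 300))
        labels = ["gA"] * 150 + [CellData.NON_TARGETING] * 150
        data = _make_cells(counts, perturbation=labels)
        X = lognormalize(data)
        responses = pd.DataFrame(X.T, index=data.cells, columns=data.genes)
        table = estimate_effects(data, responses, fdr_family="per_perturbation")
        ok = table[table["status"] == "ok"].sort_values("p_value")
        assert (ok["fdr"].to_numpy()[1:] - ok["fdr"].to_numpy()[:-1] >= -1e-12).all()
        assert (ok["fdr"] >= ok["p_value"] - 1e-12).all()


class TestCellCycle:
    def _phase_data(self):
        # g0/g1: S markers, g2/g3: G2M markers, g4: background
        counts = np.array(
            [
                [9, 0, 1],
                [9, 0, 1],
                [0, 9, 1],
                [0, 9, 1],
                [2, 2, 16],
            ]
        )
        return _make_cells(counts)

    def test_marker_dominated_cells_get_their_phase(self):
        data = self._phase_data()
        phase = assign_cell_cycle_phase(data, {"g0", "g1"}, {"g2", "g3"})
        assert phase["c0"] == "S"
        assert phase["c1"] == "G2M"

    def test_flat_expression_defaults_to_g1(self):
        data = _make_cells(np.ones((4, 3), dtype=int) * 5)
        phase = assign_cell_cycle_phase(data, {"g0"}, {"g1"})
        assert (phase == "G1").all()

    def test_missing_markers_raise(self):
        data = self._phase_data()
        with pytest.raises(ValueError):
            assign_cell_cycle_phase(data, {"nope"}, {"g2"})


class TestJackknife:
    def test_single_phase_group_has_zero_se(self):
        phases = pd.Series(["S", "S", "S"], index=["a", "b", "c"])
        groups = pd.Series(["g", "g", "g"], index=["a", "b", "c"])
        out = phase_fractions_jackknife(phases, groups)
        row = out[(out["phase"] == "S")].iloc[0]
        assert row["fraction"] == 1.0 and row["se"] == 0.0

    def test_two_cell_split_gives_half_and_half_se(self):
        phases = pd.Series(["S", "G1"], index=["a", "b"])
        groups = pd.Series(["g", "g"], index=["a", "b"])
        out = phase_fractions_jackknife(phases, groups)
        row = out[out["phase"] == "S"].iloc[0]
        assert row["fraction"] == 0.5
        assert row["se"] == pytest.approx(0.5)

    def test_four_cells_matches_hand_enumerated_loo(self):
        phases = pd.Series(["S", "G1", "G1", "G1"], index=list("abcd"))
        groups = pd.Series(["g"] * 4, index=list("abcd"))
        out = phase_fractions_jackknife(phases, groups)
        row = out[out["phase"] == "S"].iloc[0]
        # leave-one-out fractions: drop S cell -> 0/3; drop others -> 1/3
        f = np.array([0 / 3, 1 / 3, 1 / 3, 1 / 3])
        expected = np.sqrt(3 / 4 * ((f - f.mean()) ** 2).sum())
        assert row["fraction"] == 0.25
        assert row["se"] == pytest.approx(expected, rel=1e-12)

    def test_groups_below_two_cells_excluded(self):
        phases = pd.Series(["S", "S", "G1"], index=["a", "b", "c"])
        groups = pd.Series(["big", "big", "lone"], index=["a", "b", "c"])
        out = phase_fractions_jackknife(phases, groups)
        assert set(out["group"]) == {"big"}


def test_variance_moderation_keeps_betas_and_shrinks_se_spread(rng):
    counts = rng.poisson(10, (25, 300))
    labels = ["gA"] * 150 + [CellData.NON_TARGETING] * 150
    data = _make_cells(counts, perturbation=labels)
    X = lognormalize(data)
    responses = pd.DataFrame(X.T, index=data.cells, columns=data.genes)
    plain = estimate_effects(data, responses)
    mod = estimate_effects(data, responses, moderate_variance=True,
                           moderate_prior_df=50.0)
    np.testing.assert_allclose(plain["beta"], mod["beta"])
    # squeezing variances toward the mean reduces their spread
    assert mod["se"].std() < plain["se"].std()
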