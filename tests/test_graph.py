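"""Best-subset selection, sign assignment, validation, serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from traitgraph.graph import (
    ContentSelection,
    RegulatorSelection,
    TraitGraph,
    assign_gene_signs,
    build_graph,
    concordance_fisher,
    crossval_variance_explained,
    loocv_evaluate,
    permutation_test,
    select_content_programs,
    select_regulator_programs,
)


def _inputs(rng, n=200, k=4, noise=0.0, weights=None):
    genes = [f"g{i:03d}" for i in range(n)]
    cols = [f"P{j}" for j in range(k)]
    B = pd.DataFrame(rng.normal(0, 1, (n, k)), index=genes, columns=cols)
    shet = pd.Series(rng.uniform(0, 1, n), index=genes)
    weights = weights if weights is not None else {}
    gamma = pd.Series(np.zeros(n), index=genes)
    for p, w in weights.items():
        gamma += w * B[p]
    if noise:
        gamma += rng.normal(0, noise, n)
    return gamma, B, shet


def brute_force_best_subsets(gamma, B, shet, sizes):
    """Independent enumeration with statsmodels-free OLS per subset."""
    y = gamma.to_numpy()
    out = {}
    for s in sizes:
        best = None
        for subset in itertools.combinations(B.columns, s):
            X = np.column_stack(
                [np.ones(len(y)), shet.to_numpy()]
                + [B[p].to_numpy() for p in subset]
            )
            beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1 - (resid**2).sum() / ss_tot
            if best is None or r2 > best[0]:
                best = (r2, subset)
        out[s] = best
    return out


class TestSelectRegulatorPrograms:
    def test_single_noise_free_program_chosen_with_correct_sign(self, rng):
        gamma, B, shet = _inputs(rng, weights={"P2": -0.8})
        sel = select_regulator_programs(gamma, B, shet, max_subset=3)
        assert sel.programs == ["P2"]
        assert sel.weights["P2"] == pytest.approx(-0.8, abs=1e-10)

    def test_null_gamma_keeps_shet_only_model(self, rng):
        gamma, B, shet = _inputs(rng)
        gamma = pd.Series(rng.normal(0, 1, len(gamma)), index=gamma.index)
        sel = select_regulator_programs(gamma, B, shet, max_subset=3)
        r2 = sel.r2_path.set_index("size")["r2"]
        assert (r2.max() - r2.min()) < 0.05

    def test_max_subset_zero_gives_empty_program_list(self, rng):
        gamma, B, shet = _inputs(rng, weights={"P0": 1.0})
        sel = select_regulator_programs(gamma, B, shet, max_subset=0)
        assert sel.programs == []
        assert sel.weights == {}

    def test_matches_brute_force_enumeration_for_k8(self, rng):
        gamma, B, shet = _inputs(
            rng, n=250, k=8, noise=0.3,
            weights={"P1": 0.5, "P4": -0.4, "P6": 0.3},
        )
        sel = select_regulator_programs(gamma, B, shet, max_subset=5)
        oracle = brute_force_best_subsets(gamma, B, shet, range(6))
        path = sel.r2_path.set_index("size")
        for s in range(6):
            r2_o, subset_o = oracle[s]
            assert path.loc[s, "r2"] == pytest.approx(r2_o, abs=1e-10)
            assert tuple(path.loc[s, "programs"].split(",") if s else ()) == subset_o

    def test_model_budget_enforced(self, rng):
        gamma, B, shet = _inputs(rng, k=8)
        with pytest.raises(ValueError, match="budget"):
            select_regulator_programs(
                gamma, B, shet, max_subset=5, model_budget=10
            )

    def test_collinear_column_skipped_not_crashed(self, rng):
        gamma, B, shet = _inputs(rng, weights={"P0": 1.0})
        B = B.copy()
        B["P3"] = B["P0"]  # exact duplicate
        sel = select_regulator_programs(gamma, B, shet, max_subset=2)
        assert any(
            set(sub) >= {"P0", "P3"} for sub in sel.skipped_subsets
        )


class TestSelectContentPrograms:
    def test_planted_content_program_ranked_first(self, rng):
        n = 300
        genes = [f"g{i:03d}" for i in range(n)]
        loadings = pd.DataFrame(
            rng.uniform(0, 1, (n, 3)), index=genes, columns=["P0", "P1", "P2"]
        )
        gamma = pd.Series(rng.normal(0, 0.1, n), index=genes)
        shet = pd.Series(rng.uniform(0, 1, n), index=genes)
        top = sorted(genes, key=lambda g: (-loadings["P1"][g], g))[:40]
        gamma.loc[top] += 0.5
        sel = select_content_programs(
            gamma, loadings, shet, n_top=40, n_perm=1000, seed=3
        )
        assert sel.table.iloc[0]["program"] == "P1"
        assert sel.signs.get("P1") == 1

    def test_keep_zero_returns_empty(self, rng):
        n = 100
        genes = [f"g{i}" for i in range(n)]
        loadings = pd.DataFrame({"P0": rng.uniform(0, 1, n)}, index=genes)
        gamma = pd.Series(rng.normal(size=n), index=genes)
        shet = pd.Series(rng.uniform(size=n), index=genes)
        sel = select_content_programs(
            gamma, loadings, shet, n_top=10, n_perm=100, n_programs_keep=0
        )
        assert sel.programs == []

    def test_deterministic_under_fixed_seed(self, rng):
        n = 150
        genes = [f"g{i}" for i in range(n)]
        loadings = pd.DataFrame(
            rng.uniform(0, 1, (n, 2)), index=genes, columns=["P0", "P1"]
        )
        gamma = pd.Series(rng.normal(size=n), index=genes)
        shet = pd.Series(rng.uniform(size=n), index=genes)
        a = select_content_programs(gamma, loadings, shet, n_top=20,
                                    n_perm=200, seed=9)
        b = select_content_programs(gamma, loadings, shet, n_top=20,
                                    n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


def _toy_model(weights, content_programs=None, content_signs=None):
    reg = RegulatorSelection(
        programs=list(weights), weights=weights, shet_coef=0.0,
        intercept=0.0, r2_path=pd.DataFrame(),
    )
    content_programs = content_programs or []
    content_signs = content_signs or {}
    table = pd.DataFrame(
        {"program": content_programs,
         "mean_gamma": [content_signs[p] for p in content_programs],
         "p_value": 0.001, "sign": [content_signs[p] for p in content_programs],
         "chosen": True}
    )
    content = ContentSelection(
        table=table, programs=content_programs, signs=content_signs
    )
    return reg, content


class TestAssignGeneSigns:
    def test_single_path_sign_is_w_times_beta(self):
        reg, content = _toy_model({"P0": -0.5})
        effects = pd.DataFrame({"P0": [2.0]}, index=["gA"])
        fdrs = pd.DataFrame({"P0": [0.001]}, index=["gA"])
        loadings = pd.DataFrame({"P0": [0.0]}, index=["gA"])
        out = assign_gene_signs(reg, content, effects, fdrs, loadings)
        assert out.loc["gA", "predicted_sign"] == -1
        assert out.loc["gA", "total_effect"] == pytest.approx(-1.0)

    def test_exact_cancellation_is_unassigned(self):
        reg, content = _toy_model({"P0": 0.2, "P1": -0.2})
        effects = pd.DataFrame({"P0": [1.0], "P1": [1.0]}, index=["gA"])
        fdrs = pd.DataFrame({"P0": [0.001], "P1": [0.001]}, index=["gA"])
        loadings = pd.DataFrame({"P0": [0.0], "P1": [0.0]}, index=["gA"])
        out = assign_gene_signs(reg, content, effects, fdrs, loadings)
        assert out.loc["gA", "predicted_sign"] == 0

    def test_master_regulator_concordant_paths_agree(self):
        # three paths all pushing the same direction (w_p * beta > 0)
        reg, content = _toy_model({"P0": 0.5, "P1": -0.5, "P2": 0.4})
        effects = pd.DataFrame(
            {"P0": [1.0], "P1": [-1.0], "P2": [0.5]}, index=["gM"]
        )
        fdrs = pd.DataFrame(
            {"P0": [0.001], "P1": [0.001], "P2": [0.001]}, index=["gM"]
        )
        loadings = pd.DataFrame(
            {"P0": [0.0], "P1": [0.0], "P2": [0.0]}, index=["gM"]
        )
        out = assign_gene_signs(reg, content, effects, fdrs, loadings)
        singles = [np.sign(0.5 * 1.0), np.sign(-0.5 * -1.0), np.sign(0.4 * 0.5)]
        assert out.loc["gM", "predicted_sign"] == 1
        assert set(singles) == {1}
        assert out.loc["gM", "programs"] == "P0,P1,P2"

    def test_program_gene_role_takes_precedence(self):
        reg, content = _toy_model(
            {"P0": 1.0}, content_programs=["P1"], content_signs={"P1": -1}
        )
        effects = pd.DataFrame({"P0": [1.0]}, index=["gA"])
        fdrs = pd.DataFrame({"P0": [0.001]}, index=["gA"])
        loadings = pd.DataFrame({"P0": [0.0], "P1": [5.0]}, index=["gA"])
        out = assign_gene_signs(reg, content, effects, fdrs, loadings, n_top=1)
        assert out.loc["gA", "role"] == "program_gene"
        assert out.loc["gA", "predicted_sign"] == -1


class TestValidation:
    def _planted(self, rng, n=300):
        gamma, B, shet = _inputs(
            rng, n=n, k=3, noise=0.02, weights={"P0": 0.6, "P1": -0.5}
        )
        fdrs = pd.DataFrame(1.0, index=B.index, columns=B.columns)
        # regulators = genes with large |beta| on the causal programs
        for p in ("P0", "P1"):
            strong = B[p].abs().nlargest(80).index
            fdrs.loc[strong, p] = 0.001
        loadings = pd.DataFrame(
            rng.uniform(0, 1, B.shape), index=B.index, columns=B.columns
        )
        return gamma, B, fdrs, loadings, shet

    def test_loocv_on_planted_truth_enriches_correct_predictions(self, rng):
        gamma, B, fdrs, loadings, shet = self._planted(rng)
        orr, p, per_gene = loocv_evaluate(
            gamma, B, fdrs, loadings, shet, n_regulator=2, n_content=0,
            high_threshold=0.3, low_threshold=0.15, n_top=20,
        )
        assert orr > 1
        assert p < 0.05

    def test_loocv_high_threshold_above_max_gamma_raises(self, rng):
        gamma, B, fdrs, loadings, shet = self._planted(rng)
        with pytest.raises(ValueError):
            loocv_evaluate(
                gamma, B, fdrs, loadings, shet, n_regulator=2, n_content=0,
                high_threshold=1e6,
            )

    def test_permutation_p_bounds_and_power(self, rng):
        gamma, B, fdrs, loadings, shet = self._planted(rng)
        from traitgraph.graph import _fit_once

        assignments = _fit_once(
            gamma, B, fdrs, loadings, shet, 2, 0, 20, 0.05
        )
        _, obs_p, _ = concordance_fisher(assignments, gamma, 0.3, 0.15)
        perm_p, nulls = permutation_test(
            gamma, B, fdrs, loadings, shet, n_regulator=2, n_content=0,
            observed_fisher_p=obs_p, n_perm=100, seed=5,
            high_threshold=0.3, low_threshold=0.15, n_top=20,
        )
        assert 1 / 101 <= perm_p <= 1.0
        assert perm_p <= 0.05
        assert len(nulls) == 100

    def test_null_permutation_p_is_moderate(self, rng):
        # observed data drawn from the permutation null itself
        gamma, B, fdrs, loadings, shet = self._planted(rng)
        gamma = pd.Series(
            rng.permutation(gamma.to_numpy()), index=gamma.index
        )
        from traitgraph.graph import _fit_once

        assignments = _fit_once(gamma, B, fdrs, loadings, shet, 2, 0, 20, 0.05)
        try:
            _, obs_p, _ = concordance_fisher(assignments, gamma, 0.3, 0.15)
        except ValueError:
            obs_p = 1.0
        perm_p, _ = permutation_test(
            gamma, B, fdrs, loadings, shet, n_regulator=2, n_content=0,
            observed_fisher_p=obs_p, n_perm=60, seed=6,
            high_threshold=0.3, low_threshold=0.15, n_top=20,
        )
        assert perm_p > 0.05


class TestCrossval:
    def test_noise_free_multi_program_r2_near_one(self, rng):
        gamma, B, shet = _inputs(
            rng, n=300, k=3, weights={"P0": 0.5, "P1": -0.5, "P2": 0.3}
        )
        out = crossval_variance_explained(
            gamma, B, shet,
            {"multi": ["P0", "P1", "P2"], "single_P0": ["P0"], "baseline": []},
            n_splits=5, seed=0,
        ).set_index("set")
        assert out.loc["multi", "mean_r2"] > 0.999
        assert out.loc["single_P0", "mean_r2"] < out.loc["multi", "mean_r2"]

    def test_pure_noise_r2_near_zero(self, rng):
        gamma, B, shet = _inputs(rng, n=400, k=3)
        gamma = pd.Series(rng.normal(0, 1, 400), index=gamma.index)
        out = crossval_variance_explained(
            gamma, B, shet, {"all": ["P0", "P1", "P2"]}, n_splits=10, seed=1
        )
        assert out["mean_r2"].iloc[0] <= 0.02

    def test_degenerate_split_raises(self, rng):
        gamma, B, shet = _inputs(rng, n=50)
        with pytest.raises(ValueError):
            crossval_variance_explained(
                gamma, B, shet, {"all": ["P0"]}, split=1.0
            )


class TestTraitGraph:
    def _graph(self, rng):
        gamma, B, shet = _inputs(rng, n=100, k=2, weights={"P0": 0.5})
        reg, content = _toy_model({"P0": 0.5})
        fdrs = pd.DataFrame(1.0, index=B.index, columns=B.columns)
        strong = B["P0"].abs().nlargest(30).index
        fdrs.loc[strong, "P0"] = 0.001
        loadings = pd.DataFrame(
            rng.uniform(0, 1, B.shape), index=B.index, columns=B.columns
        )
        assignments = assign_gene_signs(reg, content, B, fdrs, loadings)
        return build_graph(
            "traitX", reg, content, assignments, gamma, effects_wide=B,
            validation={"loocv_p": 0.01}, high_threshold=0.2,
        ), gamma, assignments

    def test_json_round_trip_is_byte_identical(self, rng):
        g, _, _ = self._graph(rng)
        text = g.to_json()
        assert TraitGraph.from_json(text).to_json() == text

    def test_discordant_high_gamma_gene_excluded(self, rng):
        g, gamma, assignments = self._graph(rng)
        for gene, entry in g.gene_assignments.items():
            assert entry["predicted_sign"] == np.sign(gamma[gene])
            assert abs(gamma[gene]) > 0.2
        # every concordant high-|gamma| assigned gene is included
        for gene, row in assignments.iterrows():
            if (
                abs(gamma.get(gene, 0)) > 0.2
                and row["predicted_sign"] == np.sign(gamma[gene])
                and row["predicted_sign"] != 0
            ):
                assert gene in g.gene_assignments

    def test_planted_edges_restricted_to_high_gamma_regulators(self, rng):
        g, gamma, _ = self._graph(rng)
        edges = g.edges()
        reg_edges = edges[edges["kind"] == "regulates"]
        assert set(reg_edges["source"]) == set(g.gene_assignments)
        assert (reg_edges["target"] == "P0").all()

    def test_networkx_export_has_trait_sink(self, rng):
        g, _, _ = self._graph(rng)
        nxg = g.to_networkx()
        assert "traitX" in nxg
        assert nxg.out_degree("traitX") == 0
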