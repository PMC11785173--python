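"""Five-step construction of the gene -> program -> trait graph.

Step 1 selects programs whose *regulators* explain the burden effects:
exhaustive best-subset regression of gamma on the knockdown effects
beta[x -> p] (shet always included as a covariate), with the subset
size chosen where the R^2 gain flattens. The OLS coefficients w_p of
the winning subset are the program -> trait path weights.

Step 2 selects programs whose *content* carries the burden signal:
programs ranked by the constraint-matched permutation p of their
program burden effect; the retained programs carry the sign of their
top-gene mean gamma.

Step 3 predicts a sign for every gene in the model: significant
regulators of selected programs get sign(sum_p w_p * beta[x -> p]);
top-loading genes of selected content programs get the program's
content sign, which takes precedence when a gene plays both roles.

Step 4 validates: leave-one-out cross-validation with Fisher's exact
enrichment of correct predictions among high-|gamma| genes vs
minimal-|gamma| genes, and a label-permutation test that reruns the
whole selection (with fixed subset sizes and a fast Mann-Whitney
content ranking) on permuted gamma.

Step 5 serializes the graph: high-|gamma| genes whose predicted sign is
concordant with observed gamma, all their program paths, the program
weights, and the validation summary, as lossless JSON plus a flat edge
table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .association import program_burden_effect

__all__ = [
    "RegulatorSelection",
    "ContentSelection",
    "TraitGraph",
    "select_regulator_programs",
    "select_content_programs",
    "assign_gene_signs",
    "concordance_fisher",
    "loocv_evaluate",
    "permutation_test",
    "crossval_variance_explained",
    "build_graph",
]


@dataclass
class RegulatorSelection:
    programs: list[str]
    weights: dict[str, float]  # w_p from the joint regression
    shet_coef: float
    intercept: float
    r2_path: pd.DataFrame  # per-size best R^2
    skipped_subsets: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class ContentSelection:
    table: pd.DataFrame  # program, mean_gamma, p_value, sign, chosen
    programs: list[str]
    signs: dict[str, int]


def _r2(y: np.ndarray, X: np.ndarray) -> float | None:
    """R^2 of OLS with intercept; None when the design is collinear."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / ss_tot)


def select_regulator_programs(
    gamma: pd.Series,
    effects_wide: pd.DataFrame,
    shet: pd.Series,
    max_subset: int = 5,
    model_budget: int = 2_000_000,
    gain_fraction: float = 0.10,
    subset_size: int | None = None,
) -> RegulatorSelection:
    """Exhaustive best-subset regression of gamma on program effects.

    For each subset size s <= max_subset every program subset is scored
    by the R^2 of gamma ~ intercept + shet + {beta[x -> p]}. The final
    size is the smallest s whose marginal R^2 gain falls below
    ``gain_fraction`` of the total gain from s=0 to max_subset (pass
    ``subset_size`` to fix it instead, as the leave-one-out and
    permutation reruns do). Collinear subsets are skipped and recorded.
    """
    candidates = list(effects_wide.columns)
    K = len(candidates)
    if subset_size is not None:
        max_subset = subset_size  # only sizes up to the fixed size are needed
    max_subset = min(max_subset, K)
    total_models = sum(comb(K, s) for s in range(max_subset + 1))
    if total_models > model_budget:
        raise ValueError(
            f"{total_models} candidate models exceed the budget "
            f"{model_budget}; reduce max_subset"
        )
    df = pd.concat(
        [gamma.rename("gamma"), shet.rename("shet"), effects_wide], axis=1
    ).dropna()
    y = df["gamma"].to_numpy(float)
    base = np.column_stack([np.ones(len(df)), df["shet"].to_numpy(float)])
    B = df[candidates].to_numpy(float)
    col = {p: i for i, p in enumerate(candidates)}

    skipped: list[tuple[str, ...]] = []
    best_by_size: dict[int, tuple[float, tuple[str, ...]]] = {}
    for s in range(max_subset + 1):
        best = None
        for subset in combinations(candidates, s):
            X = (
                base
                if not subset
                else np.column_stack([base, B[:, [col[p] for p in subset]]])
            )
            r2 = _r2(y, X)
            if r2 is None:
                skipped.append(subset)
                continue
            if best is None or r2 > best[0] or (
                r2 == best[0] and subset < best[1]
            ):
                best = (r2, subset)
        if best is None:
            raise ValueError(f"every size-{s} subset was collinear")
        best_by_size[s] = best

    r2_path = pd.DataFrame(
        [
            dict(size=s, r2=best_by_size[s][0], programs=",".join(best_by_size[s][1]))
            for s in sorted(best_by_size)
        ]
    )
    if subset_size is None:
        total_gain = best_by_size[max_subset][0] - best_by_size[0][0]
        chosen_size = max_subset
        for s in range(1, max_subset + 1):
            gain = best_by_size[s][0] - best_by_size[s - 1][0]
            if gain < gain_fraction * max(total_gain, 0.0):
                chosen_size = s - 1
                break
    else:
        chosen_size = min(subset_size, max_subset)

    chosen = list(best_by_size[chosen_size][1])
    X = (
        base
        if not chosen
        else np.column_stack([base, B[:, [col[p] for p in chosen]]])
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    weights = {p: float(coef[2 + i]) for i, p in enumerate(chosen)}
    return RegulatorSelection(
        programs=chosen,
        weights=weights,
        shet_coef=float(coef[1]),
        intercept=float(coef[0]),
        r2_path=r2_path,
        skipped_subsets=skipped,
    )


def _mwu_content_p(gamma: pd.Series, top: list[str]) -> float:
    """Two-sided Mann-Whitney of top-loading genes' gamma vs the rest."""
    top_set = set(top)
    x = gamma.loc[list(top)].to_numpy(float)
    y = gamma.loc[[g for g in gamma.index if g not in top_set]].to_numpy(float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def select_content_programs(
    gamma: pd.Series,
    loadings: pd.DataFrame,
    shet: pd.Series,
    n_top: int = 200,
    n_perm: int = 10_000,
    n_programs_keep: int | None = None,
    seed: int = 0,
    method: str = "permutation",
) -> ContentSelection:
    """Rank programs by program burden effect significance; keep the top.

    ``method="permutation"`` uses the constraint-matched permutation p
    (the default for observed data); ``method="mwu"`` uses the fast
    two-sided Mann-Whitney ranking of top-gene gamma vs the rest (used
    inside permutation reruns). ``n_programs_keep`` defaults to the
    count of Bonferroni-significant programs under the chosen ranking.
    """
    rows = []
    for j, program in enumerate(loadings.columns):
        top = sorted(
            loadings.index, key=lambda g: (-loadings[program][g], g)
        )[:n_top]
        mean_gamma = float(gamma.loc[top].mean())
        if method == "permutation":
            mean_gamma, signed_p = program_burden_effect(
                gamma, loadings, shet, program,
                n_top=n_top, n_perm=n_perm, seed=seed + j,
            )
            p = abs(signed_p)
        elif method == "mwu":
            p = _mwu_content_p(gamma, top)
        else:
            raise ValueError(f"unknown content ranking method {method!r}")
        rows.append(
            dict(
                program=program,
                mean_gamma=mean_gamma,
                p_value=p,
                sign=1 if mean_gamma >= 0 else -1,
            )
        )
    table = pd.DataFrame(rows).sort_values(
        ["p_value", "program"], kind="stable", ignore_index=True
    )
    K = len(table)
    if n_programs_keep is None:
        n_programs_keep = int((table["p_value"] * K < 0.05).sum())
    n_programs_keep = min(n_programs_keep, K)
    table["chosen"] = False
    if n_programs_keep > 0:
        table.loc[: n_programs_keep - 1, "chosen"] = True
    chosen = table.loc[table["chosen"], "program"].tolist()
    signs = {
        r.program: int(r.sign) for r in table.itertuples() if r.chosen
    }
    return ContentSelection(table=table, programs=chosen, signs=signs)


def assign_gene_signs(
    regulator_selection: RegulatorSelection,
    content_selection: ContentSelection,
    effects_wide: pd.DataFrame,
    fdr_wide: pd.DataFrame,
    loadings: pd.DataFrame,
    fdr: float = 0.05,
    n_top: int = 200,
    tol: float = 1e-12,
) -> pd.DataFrame:
    """Predict a trait-effect sign for every gene touched by the model.

    Regulators: genes significant (FDR < ``fdr``) on >= 1 selected
    regulator program; total_effect = sum over those programs of
    w_p * beta[x -> p]; predicted sign is its sign (0 / unassigned on
    cancellation below ``tol``). Program genes: the top ``n_top``
    loading genes of each selected content program inherit the program's
    content sign, which wins when a gene holds both roles.
    """
    weights = regulator_selection.weights
    rows: dict[str, dict] = {}
    if weights:
        progs = list(weights)
        for gene in effects_wide.index:
            total = 0.0
            touched = []
            for p in progs:
                f = fdr_wide.at[gene, p] if p in fdr_wide.columns else np.nan
                if np.isfinite(f) and f < fdr:
                    total += weights[p] * float(effects_wide.at[gene, p])
                    touched.append(p)
            if touched:
                sign = 0 if abs(total) < tol else (1 if total > 0 else -1)
                rows[gene] = dict(
                    gene=gene,
                    role="regulator",
                    programs=",".join(touched),
                    predicted_sign=sign,
                    total_effect=total,
                )
    for program in content_selection.programs:
        csign = content_selection.signs[program]
        top = sorted(
            loadings.index, key=lambda g: (-loadings[program][g], g)
        )[:n_top]
        for gene in top:
            prev = rows.get(gene)
            if prev is not None and prev["role"] == "program_gene":
                prev["programs"] += f",{program}"
                continue
            # program-gene sign takes precedence over the regulator role
            rows[gene] = dict(
                gene=gene,
                role="program_gene",
                programs=program,
                predicted_sign=csign,
                total_effect=float(csign),
            )
    out = pd.DataFrame(rows.values())
    if out.empty:
        out = pd.DataFrame(
            columns=["gene", "role", "programs", "predicted_sign", "total_effect"]
        )
    return out.set_index("gene")


def concordance_fisher(
    assignments: pd.DataFrame,
    gamma: pd.Series,
    high_threshold: float = 0.1,
    low_threshold: float = 0.01,
) -> tuple[float, float, pd.DataFrame]:
    """Fisher enrichment of correct sign predictions in high- vs low-|gamma| genes.

    A gene counts as correct when it has a nonzero predicted sign equal
    to sign(gamma); unassigned genes count as not-correct. The 2x2 table
    is [high |gamma| > high_threshold vs low |gamma| < low_threshold] x
    [correct vs not]. Returns (odds_ratio, p, per-gene table).
    """
    g = gamma.dropna()
    if (g.abs() > high_threshold).sum() == 0:
        raise ValueError(
            f"no genes with |gamma| > high_threshold={high_threshold}"
        )
    if (g.abs() < low_threshold).sum() == 0:
        raise ValueError(f"no genes with |gamma| < low_threshold={low_threshold}")
    pred = assignments["predicted_sign"].reindex(g.index).fillna(0).astype(int)
    correct = (pred != 0) & (pred == np.sign(g).astype(int))
    per_gene = pd.DataFrame(
        {"gamma": g, "predicted_sign": pred, "correct": correct}
    )
    high = g.abs() > high_threshold
    low = g.abs() < low_threshold
    a = int((high & correct).sum())
    b = int((high & ~correct).sum())
    c = int((low & correct).sum())
    d = int((low & ~correct).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p), per_gene


def _fit_once(
    gamma: pd.Series,
    effects_wide: pd.DataFrame,
    fdr_wide: pd.DataFrame,
    loadings: pd.DataFrame,
    shet: pd.Series,
    n_regulator: int,
    n_content: int,
    n_top: int,
    fdr: float,
    content_method: str = "mwu",
    seed: int = 0,
    n_perm_content: int = 2000,
) -> pd.DataFrame:
    """One full selection + sign assignment at fixed subset sizes."""
    reg = select_regulator_programs(
        gamma, effects_wide.loc[gamma.index.intersection(effects_wide.index)],
        shet, subset_size=n_regulator,
    )
    content = select_content_programs(
        gamma, loadings.loc[gamma.index.intersection(loadings.index)], shet,
        n_top=min(n_top, len(gamma)), n_perm=n_perm_content,
        n_programs_keep=n_content, seed=seed, method=content_method,
    )
    return assign_gene_signs(
        reg, content, effects_wide, fdr_wide, loadings, fdr=fdr,
        n_top=min(n_top, len(gamma)),
    )


def loocv_evaluate(
    gamma: pd.Series,
    effects_wide: pd.DataFrame,
    fdr_wide: pd.DataFrame,
    loadings: pd.DataFrame,
    shet: pd.Series,
    n_regulator: int,
    n_content: int,
    high_threshold: float = 0.1,
    low_threshold: float = 0.01,
    n_top: int = 200,
    fdr: float = 0.05,
    content_method: str = "mwu",
) -> tuple[float, float, pd.DataFrame]:
    """Leave-one-gene-out sign prediction with Fisher validation.

    Each gene is dropped, programs are re-selected on the remaining
    genes (with the subset sizes fixed to the full-data fit, and the
    fast Mann-Whitney content ranking by default), and the held-out
    gene's sign is predicted from its own effects/loadings. Returns
    (odds_ratio, fisher_p, per-gene predictions).
    """
    if high_threshold > gamma.abs().max():
        raise ValueError(
            f"high_threshold={high_threshold} exceeds max |gamma|"
        )
    preds = {}
    for gene in gamma.index:
        rest = gamma.drop(index=gene)
        reg = select_regulator_programs(
            rest, effects_wide.loc[rest.index], shet.loc[rest.index],
            subset_size=n_regulator,
        )
        content = select_content_programs(
            rest, loadings.loc[rest.index], shet.loc[rest.index],
            n_top=min(n_top, len(rest)), n_programs_keep=n_content,
            method=content_method,
        )
        single = assign_gene_signs(
            reg, content,
            effects_wide.loc[[gene]],
            fdr_wide.loc[[gene]],
            loadings,
            fdr=fdr,
            n_top=min(n_top, len(gamma)),
        )
        if gene in single.index:
            preds[gene] = int(single.at[gene, "predicted_sign"])
        else:
            preds[gene] = 0
    pred_df = pd.DataFrame(
        {"predicted_sign": pd.Series(preds)},
    )
    orr, p, per_gene = concordance_fisher(
        pred_df, gamma, high_threshold, low_threshold
    )
    return orr, p, per_gene


def permutation_test(
    gamma: pd.Series,
    effects_wide: pd.DataFrame,
    fdr_wide: pd.DataFrame,
    loadings: pd.DataFrame,
    shet: pd.Series,
    n_regulator: int,
    n_content: int,
    observed_fisher_p: float,
    n_perm: int = 20_000,
    seed: int = 0,
    high_threshold: float = 0.1,
    low_threshold: float = 0.01,
    n_top: int = 200,
    fdr: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Label-permutation null for the whole selection + prediction pipeline.

    Each permutation shuffles gamma over gene labels, reruns Step 1
    (fixed subset size), Step 2 (fast Mann-Whitney ranking, fixed
    count), and Step 3, and records the Fisher concordance p.
    Returns ``((1 + #{perm p <= observed}) / (n_perm + 1), null p array)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    values = gamma.to_numpy(float)
    null_ps = np.empty(n_perm)
    for i in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=gamma.index)
        assignments = _fit_once(
            perm, effects_wide, fdr_wide, loadings, shet,
            n_regulator, n_content, n_top, fdr, content_method="mwu",
        )
        try:
            _, p, _ = concordance_fisher(
                assignments, perm, high_threshold, low_threshold
            )
        except ValueError:
            p = 1.0
        null_ps[i] = p
    perm_p = (1 + int((null_ps <= observed_fisher_p).sum())) / (n_perm + 1)
    return float(perm_p), null_ps


def crossval_variance_explained(
    gamma: pd.Series,
    effects_wide: pd.DataFrame,
    shet: pd.Series,
    chosen_sets: dict[str, list[str]],
    split: float = 0.8,
    n_splits: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-sample R^2 of gamma ~ beta(set) + shet per program set.

    Genes are split train/test (``split`` fraction train) ``n_splits``
    times; each set's model is fit on train and scored on test (R^2
    relative to the test-set mean). The empty set is the shet-only
    baseline. Returns a table (set, mean_r2, sd_r2).
    """
    df = pd.concat(
        [gamma.rename("gamma"), shet.rename("shet"), effects_wide], axis=1
    ).dropna()
    n = len(df)
    n_train = int(round(split * n))
    if n_train <= 2 or n_train >= n:
        raise ValueError(f"degenerate split: {n_train} train of {n} genes")
    rng = np.random.default_rng(seed)
    y = df["gamma"].to_numpy(float)
    results = {name: [] for name in chosen_sets}
    for _ in range(n_splits):
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        for name, progs in chosen_sets.items():
            cols = ["shet"] + list(progs)
            X = np.column_stack([np.ones(n), df[cols].to_numpy(float)])
            coef, _, _, _ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
            resid = y[te] - X[te] @ coef
            ss_tot = ((y[te] - y[te].mean()) ** 2).sum()
            results[name].append(
                1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
            )
    return pd.DataFrame(
        [
            dict(set=name, mean_r2=float(np.mean(v)), sd_r2=float(np.std(v)))
            for name, v in results.items()
        ]
    )


@dataclass
class TraitGraph:
    """Signed gene -> program -> trait graph with validation summary."""

    trait: str
    regulator_programs: list[tuple[str, float]]  # (program, w_p)
    content_programs: list[tuple[str, int]]  # (program, content sign)
    gene_assignments: dict[str, dict]  # gene -> role/programs/sign/total_effect
    validation: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "regulator_programs": [[p, w] for p, w in self.regulator_programs],
            "content_programs": [[p, s] for p, s in self.content_programs],
            "gene_assignments": self.gene_assignments,
            "validation": self.validation,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "TraitGraph":
        return cls(
            trait=d["trait"],
            regulator_programs=[(p, float(w)) for p, w in d["regulator_programs"]],
            content_programs=[(p, int(s)) for p, s in d["content_programs"]],
            gene_assignments=d["gene_assignments"],
            validation=d["validation"],
        )

    @classmethod
    def from_json(cls, text: str) -> "TraitGraph":
        return cls.from_dict(json.loads(text))

    def edges(self) -> pd.DataFrame:
        """Flat edge table: source, target, kind, sign, weight."""
        rows = []
        weights = dict(self.regulator_programs)
        for program, w in sorted(self.regulator_programs):
            rows.append(
                dict(
                    source=program, target=self.trait, kind="affects",
                    sign=1 if w >= 0 else -1, weight=w,
                )
            )
        for program, s in sorted(self.content_programs):
            rows.append(
                dict(
                    source=program, target=self.trait, kind="affects",
                    sign=s, weight=float(s),
                )
            )
        for gene in sorted(self.gene_assignments):
            a = self.gene_assignments[gene]
            progs = a["programs"].split(",") if a["programs"] else []
            if a["role"] == "regulator":
                for p in progs:
                    beta_w = a.get("path_effects", {}).get(p)
                    rows.append(
                        dict(
                            source=gene, target=p, kind="regulates",
                            sign=a["predicted_sign"] if beta_w is None
                            else (1 if beta_w >= 0 else -1),
                            weight=float("nan") if beta_w is None else beta_w,
                        )
                    )
            else:
                for p in progs:
                    rows.append(
                        dict(
                            source=gene, target=p, kind="member_of",
                            sign=a["predicted_sign"], weight=1.0,
                        )
                    )
        return pd.DataFrame(rows)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for row in self.edges().itertuples(index=False):
            g.add_edge(row.source, row.target, kind=row.kind, sign=row.sign,
                       weight=row.weight)
        return g


def build_graph(
    trait: str,
    regulator_selection: RegulatorSelection,
    content_selection: ContentSelection,
    assignments: pd.DataFrame,
    gamma: pd.Series,
    effects_wide: pd.DataFrame | None = None,
    validation: dict[str, float] | None = None,
    high_threshold: float = 0.1,
) -> TraitGraph:
    """Assemble the serializable graph from the fitted components.

    Only high-|gamma| genes whose predicted sign is concordant with
    observed gamma enter the graph; multi-program regulators keep every
    path. Per-path effects w_p * beta[x -> p] are attached when
    ``effects_wide`` is given.
    """
    gene_assignments: dict[str, dict] = {}
    for gene, a in assignments.iterrows():
        gval = gamma.get(gene, np.nan)
        if not np.isfinite(gval) or abs(gval) <= high_threshold:
            continue
        if a["predicted_sign"] == 0 or a["predicted_sign"] != np.sign(gval):
            continue
        entry = dict(
            role=a["role"],
            programs=a["programs"],
            predicted_sign=int(a["predicted_sign"]),
            total_effect=float(a["total_effect"]),
            gamma=float(gval),
        )
        if a["role"] == "regulator" and effects_wide is not None:
            weights = regulator_selection.weights
            entry["path_effects"] = {
                p: float(weights[p] * effects_wide.at[gene, p])
                for p in a["programs"].split(",")
                if p in weights
            }
        gene_assignments[gene] = entry
    return TraitGraph(
        trait=trait,
        regulator_programs=sorted(regulator_selection.weights.items()),
        content_programs=sorted(content_selection.signs.items()),
        gene_assignments=gene_assignments,
        validation=validation or {},
    )
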