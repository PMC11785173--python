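"""Covariate-adjusted perturbation effect estimation from single-cell data.

Estimates the effect of knocking down gene x on each response -- either
single-gene log-normalized expression (beta[x -> y]) or program usage
(beta[x -> P]) -- by per-response ordinary least squares on the cells
carrying perturbation x plus the non-targeting controls:

    response ~ intercept + is_perturbed + batch + n_genes + pct_mito

with batch one-hot encoded (first level dropped). The ``is_perturbed``
coefficient is the effect estimate, with an exact two-sided t-test and
Benjamini-Hochberg FDR within a declared family (across responses per
perturbation, or across perturbations per response).

Also provides the standard cell/gene filters, log-normalization,
S/G2M cell-cycle phase assignment from marker-gene z-scores, and
per-perturbation phase fractions with leave-one-out jackknife SEs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CellData

__all__ = [
    "filter_cells_genes",
    "lognormalize",
    "estimate_effects",
    "assign_cell_cycle_phase",
    "phase_fractions_jackknife",
]


class EmptyDataError(ValueError):
    pass


def filter_cells_genes(
    data: CellData,
    min_genes_per_cell: int = 500,
    min_cells_per_gene: int = 500,
) -> CellData:
    """Drop low-complexity cells, then rarely-expressed genes (one pass).

    Cells expressing fewer than ``min_genes_per_cell`` genes are removed
    first; genes expressed in fewer than ``min_cells_per_gene`` of the
    surviving cells are removed second. Perturbation labels and
    covariates are carried through unchanged.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    X = sparse.csc_matrix(data.counts)  # genes x cells
    genes_per_cell = (X > 0).sum(axis=0).A1
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise EmptyDataError("all cells removed by min_genes_per_cell filter")
    X = X[:, keep_cells]
    cells_per_gene = (X > 0).sum(axis=1).A1
    keep_genes = cells_per_gene >= min_cells_per_gene
    cells = [c for c, k in zip(data.cells, keep_cells) if k]
    genes = [g for g, k in zip(data.genes, keep_genes) if k]
    return CellData(
        counts=sparse.csr_matrix(X[keep_genes]),
        genes=genes,
        cells=cells,
        obs=data.obs.loc[cells].copy(),
    )


def lognormalize(data: CellData, scale: float = 1e4) -> np.ndarray:
    """ln(1 + count * scale / cell_total), dense genes x cells."""
    X = np.asarray(data.counts.todense(), dtype=float)
    totals = X.sum(axis=0)
    if (totals == 0).any():
        bad = [data.cells[i] for i in np.where(totals == 0)[0][:5]]
        raise EmptyDataError(f"zero-total cells present (e.g. {bad}); filter first")
    return np.log1p(X * (scale / totals)[None, :])


def _design_matrix(obs: pd.DataFrame, perturbed: np.ndarray) -> np.ndarray:
    batches = pd.Categorical(obs["batch"])
    cols = [np.ones(len(obs)), perturbed.astype(float)]
    for level in batches.categories[1:]:  # first level dropped
        cols.append((batches == level).astype(float))
    cols.append(obs["n_genes"].to_numpy(float))
    cols.append(obs["pct_mito"].to_numpy(float))
    return np.column_stack(cols)


def estimate_effects(
    data: CellData,
    responses: pd.DataFrame,
    targets: list[str] | None = None,
    fdr_family: str = "per_perturbation",
    min_cells: int = 10,
    moderate_variance: bool = False,
    moderate_prior_df: float = 10.0,
) -> pd.DataFrame:
    """OLS perturbation effects on each response, with covariate adjustment.

    ``responses`` is cells x responses (rows aligned to ``data.cells``);
    columns may be gene ids (log-normalized expression) or program
    labels (usages). For each target x, cells {perturbation == x} are
    compared with the non-targeting pool. Self-knockdown rows (response
    id == perturbed gene) are flagged ``self_response`` for downstream
    exclusion. Targets with fewer than ``min_cells`` perturbed cells, or
    with a rank-deficient design, are recorded with status != "ok"
    rather than raising.

    ``moderate_variance`` applies a simplified empirical-Bayes squeeze
    of the per-response residual variances toward their mean (prior
    degrees of freedom ``moderate_prior_df``), leaving point estimates
    identical; off by default.

    Returns a long table: perturbed_gene, response, beta, se, p_value,
    fdr, self_response, status.
    """
    if fdr_family not in ("per_perturbation", "per_response"):
        raise ValueError("fdr_family must be per_perturbation or per_response")
    obs = data.obs
    resp = responses.loc[data.cells]
    nt_mask = (obs["perturbation"] == CellData.NON_TARGETING).to_numpy()
    if targets is None:
        targets = sorted(set(obs["perturbation"]) - {CellData.NON_TARGETING})
    if nt_mask.sum() < min_cells:
        raise EmptyDataError(
            f"only {nt_mask.sum()} non-targeting cells; need >= {min_cells}"
        )

    Y_all = resp.to_numpy(float)
    rows = []
    for target in targets:
        pert_mask = (obs["perturbation"] == target).to_numpy()
        n_pert = int(pert_mask.sum())
        if n_pert < min_cells:
            rows.append(
                dict(
                    perturbed_gene=target, response=None, beta=np.nan, se=np.nan,
                    p_value=np.nan, status=f"skipped: {n_pert} cells",
                )
            )
            continue
        use = pert_mask | nt_mask
        X = _design_matrix(obs.loc[use], pert_mask[use])
        Y = Y_all[use]
        nobs, k = X.shape
        XtX = X.T @ X
        rank = np.linalg.matrix_rank(XtX)
        if rank < k:
            # drop constant/collinear covariate columns, keep is_perturbed
            keep = [0, 1]
            for j in range(2, k):
                if np.linalg.matrix_rank(XtX[np.ix_(keep + [j], keep + [j])]) == len(keep) + 1:
                    keep.append(j)
            X = X[:, keep]
            XtX = X.T @ X
            k = X.shape[1]
            if np.linalg.matrix_rank(XtX) < k:
                rows.append(
                    dict(
                        perturbed_gene=target, response=None, beta=np.nan,
                        se=np.nan, p_value=np.nan,
                        status="failed: rank-deficient design",
                    )
                )
                continue
        XtX_inv = np.linalg.inv(XtX)
        coefs = XtX_inv @ (X.T @ Y)  # k x n_responses
        resid = Y - X @ coefs
        dof = nobs - k
        sigma2 = (resid**2).sum(axis=0) / dof
        if moderate_variance and len(sigma2) > 1:
            # empirical-Bayes squeeze of the residual variances toward
            # their across-response mean; the point estimates are
            # untouched, only SEs and degrees of freedom change
            s0 = sigma2[sigma2 > 0].mean() if (sigma2 > 0).any() else 0.0
            sigma2 = (moderate_prior_df * s0 + dof * sigma2) / (
                moderate_prior_df + dof
            )
            dof = dof + moderate_prior_df
        beta = coefs[1]
        var_beta = XtX_inv[1, 1] * sigma2
        se = np.sqrt(var_beta)
        resp_sd = Y.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        # degenerate (constant) responses: beta 0, p 1 by convention
        const = resp_sd == 0
        beta = np.where(const, 0.0, beta)
        pvals = np.where(const | (se == 0), 1.0, pvals)
        for j, rname in enumerate(resp.columns):
            rows.append(
                dict(
                    perturbed_gene=target,
                    response=rname,
                    beta=float(beta[j]),
                    se=float(se[j]),
                    p_value=float(min(max(pvals[j], np.nextafter(0, 1)), 1.0)),
                    status="ok",
                )
            )
    table = pd.DataFrame(rows)
    table["self_response"] = table["perturbed_gene"] == table["response"]
    ok = table["status"] == "ok"
    table["fdr"] = np.nan
    if ok.any():
        sub = table.loc[ok]
        key = "perturbed_gene" if fdr_family == "per_perturbation" else "response"
        fdr = pd.Series(index=sub.index, dtype=float)
        for _, grp in sub.groupby(key):
            fdr.loc[grp.index] = multipletests(grp["p_value"], method="fdr_bh")[1]
        table.loc[ok, "fdr"] = fdr
    return table


def assign_cell_cycle_phase(
    data: CellData,
    s_markers: set[str],
    g2m_markers: set[str],
    logexpr: np.ndarray | None = None,
) -> pd.Series:
    """Assign G1 / S / G2M per cell from marker-gene z-score means.

    Scores are the mean over marker genes of expression z-scored across
    cells; a cell is called S or G2M when the larger of the two scores
    is positive, else G1.
    """
    if not s_markers or not g2m_markers:
        raise ValueError("marker sets must be non-empty")
    gene_index = {g: i for i, g in enumerate(data.genes)}
    s_idx = [gene_index[g] for g in sorted(s_markers) if g in gene_index]
    g2m_idx = [gene_index[g] for g in sorted(g2m_markers) if g in gene_index]
    if not s_idx or not g2m_idx:
        raise ValueError("marker sets do not intersect the data genes")
    X = lognormalize(data) if logexpr is None else logexpr
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    s_score = Z[s_idx].mean(axis=0)
    g2m_score = Z[g2m_idx].mean(axis=0)
    phase = np.where(
        np.maximum(s_score, g2m_score) > 0,
        np.where(s_score >= g2m_score, "S", "G2M"),
        "G1",
    )
    return pd.Series(phase, index=data.cells, name="phase")


def phase_fractions_jackknife(
    phases: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Per-group phase fractions with leave-one-cell-out jackknife SEs.

    SE = sqrt((n-1)/n * sum_i (f_i - mean(f_loo))^2) where f_i are the
    leave-one-out fractions. Groups with < 2 cells are excluded.
    Returns a table (group, phase, fraction, se, n_cells).
    """
    phases, groups = phases.align(groups, join="inner")
    rows = []
    for group in sorted(set(groups)):
        ph = phases[groups == group]
        n = len(ph)
        if n < 2:
            continue
        for phase in ("G1", "S", "G2M"):
            k = int((ph == phase).sum())
            frac = k / n
            # closed-form leave-one-out fractions
            f_in = (k - 1) / (n - 1)  # dropping a cell in this phase (k cells)
            f_out = k / (n - 1)  # dropping any other cell (n - k cells)
            f_loo = np.concatenate([np.full(k, f_in), np.full(n - k, f_out)])
            se = np.sqrt((n - 1) / n * ((f_loo - f_loo.mean()) ** 2).sum())
            rows.append(
                dict(group=group, phase=phase, fraction=frac, se=float(se), n_cells=n)
            )
    return pd.DataFrame(rows)
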