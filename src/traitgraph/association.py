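"""Program-trait and regulator-trait association statistics.

Two complementary statistics connect a co-expression program to a
quantitative trait:

* **Program burden effect** -- the mean burden effect gamma of the
  program's top-loading genes. Because NMF loadings are non-negative,
  the sign of this mean is directly interpretable (negative = the
  program promotes the trait). Significance comes from a permutation
  null of random gene sets matched *exactly* on the observed set's
  composition across 10 selection-constraint (shet) bins, since
  constraint and |gamma| are correlated and highly constrained programs
  would otherwise look enriched for free.

* **Regulator-burden correlation** -- the coefficient of gamma regressed
  on the knockdown effects beta[x -> P] across perturbed genes x, with
  shet as a covariate. A positive coefficient means up-regulating the
  program promotes the trait.

Also provides a two-sided QQ construction for signed -log10 p values
and Fisher's exact enrichment of a hit set among the top of a ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shet_bin_indices",
    "program_burden_effect",
    "regulator_burden_correlation",
    "two_sided_qq",
    "top_hit_enrichment",
]


class BinningError(ValueError):
    pass


def shet_bin_indices(shet: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile-bin shet over the analysis universe; ties go to the lower bin."""
    shet = np.asarray(shet, dtype=float)
    edges = np.quantile(shet, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, shet, side="left")


def _top_by_loading(loading: pd.Series, n_top: int) -> list:
    order = sorted(loading.index, key=lambda g: (-loading[g], g))
    return order[:n_top]


def program_burden_effect(
    gamma: pd.Series,
    loadings: pd.DataFrame,
    shet: pd.Series,
    program: str | int,
    n_top: int = 100,
    n_perm: int = 10_000,
    seed: int = 0,
    n_bins: int = 10,
) -> tuple[float, float]:
    """Mean gamma of a program's top genes with a constraint-matched
    permutation p-value.

    The null draws ``n_perm`` random gene sets with exactly the observed
    set's gene count in each of ``n_bins`` shet quantile bins. The
    two-sided p-value is ``2 * min(#{null >= obs} + 1, #{null <= obs} + 1)
    / (n_perm + 1)``, capped at 1, and carries the sign of the observed
    mean. Returns ``(mean_gamma, signed_p)``.
    """
    if n_top > len(gamma):
        raise ValueError(f"n_top={n_top} exceeds {len(gamma)} genes")
    genes = list(gamma.index)
    col = loadings.columns[program] if isinstance(program, int) else program
    top = _top_by_loading(loadings.loc[genes, col], n_top)

    g = gamma.to_numpy(float)
    bins = shet_bin_indices(shet.loc[genes].to_numpy(float), n_bins)
    gene_pos = {gg: i for i, gg in enumerate(genes)}
    top_idx = np.array([gene_pos[gg] for gg in top])
    observed = float(g[top_idx].mean())

    rng = np.random.default_rng(seed)
    null_sums = np.zeros(n_perm)
    for b in range(n_bins):
        pool = np.where(bins == b)[0]
        need = int((bins[top_idx] == b).sum())
        if need == 0:
            continue
        if need > pool.size:
            raise BinningError(
                f"shet bin {b} offers {pool.size} genes but the observed "
                f"set needs {need}"
            )
        # n_perm independent without-replacement draws of `need` from `pool`
        pick = np.argpartition(rng.random((n_perm, pool.size)), need - 1, axis=1)[
            :, :need
        ]
        null_sums += g[pool[pick]].sum(axis=1)
    null_means = null_sums / n_top
    # tolerance so exact ties (e.g. constant gamma) are not split by
    # floating-point summation order
    eps = 1e-9 * max(1.0, abs(observed))
    n_ge = int((null_means >= observed - eps).sum())
    n_le = int((null_means <= observed + eps).sum())
    p = min(1.0, 2.0 * min(n_ge + 1, n_le + 1) / (n_perm + 1))
    signed_p = p if observed >= 0 else -p
    return observed, signed_p


def regulator_burden_correlation(
    gamma: pd.Series,
    effects: pd.Series,
    shet: pd.Series,
    exclude: str | None = None,
) -> tuple[float, float, float]:
    """OLS of gamma on [beta, shet] with intercept, across perturbed genes.

    ``exclude`` drops the focal response gene itself (its knockdown
    trivially changes its own expression). Returns
    ``(coef, se, signed_logp)`` where signed_logp = -log10(two-sided p)
    times the coefficient's sign.
    """
    df = pd.DataFrame({"gamma": gamma, "beta": effects, "shet": shet}).dropna()
    if exclude is not None:
        df = df.drop(index=exclude, errors="ignore")
    if len(df) < 10:
        raise ValueError(f"need >= 10 genes with finite values, got {len(df)}")
    if df["beta"].nunique() <= 1:
        raise ValueError("effects vector is constant; coefficient undefined")
    X = np.column_stack(
        [np.ones(len(df)), df["beta"].to_numpy(), df["shet"].to_numpy()]
    )
    y = df["gamma"].to_numpy()
    XtX_inv = np.linalg.pinv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    dof = len(df) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = float(np.sqrt(XtX_inv[1, 1] * sigma2))
    b = float(coef[1])
    if se == 0:
        logp = 300.0
    else:
        t = b / se
        # log-space survival keeps extreme signals finite
        logp = -(stats.t.logsf(abs(t), dof) + np.log(2.0)) / np.log(10.0)
        logp = float(min(logp, 300.0))
    return b, se, float(np.sign(b) * logp) if b != 0 else 0.0


def two_sided_qq(signed_logp: pd.Series | np.ndarray) -> dict[str, pd.DataFrame]:
    """Observed vs expected -log10 p per sign tail.

    Each tail's observed values are ranked descending; expected values
    are uniform order statistics ``-log10(i / (N + 1))`` scaled by the
    *total* test count N, so a null-only input lies on the diagonal in
    both tails and the two tails' lengths sum to the input length.
    """
    x = np.asarray(signed_logp, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 tests")
    n_total = x.size
    out = {}
    for name, tail in (("positive", x[x >= 0]), ("negative", -x[x < 0])):
        obs = np.sort(tail)[::-1]
        exp = -np.log10((np.arange(1, tail.size + 1)) / (n_total + 1))
        out[name] = pd.DataFrame({"expected": exp, "observed": obs})
    return out


def top_hit_enrichment(
    hits: set,
    ranking: pd.Series,
    top_n: int,
    background: set,
) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact enrichment of ``hits`` among the top of a ranking.

    The ranking is ascending (smallest value = strongest, e.g. p-values),
    ties broken by gene id; the 2x2 table is [in-top vs not] x [hit vs
    not] over ``background``. Returns (odds_ratio, (ci_lo, ci_hi), p),
    with Haldane 0.5 correction and a Woolf 95% CI when any cell is 0.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    if not set(hits) <= set(background):
        raise ValueError("hits must be a subset of background")
    if top_n > len(background):
        raise ValueError("top_n exceeds background size")
    ranked = sorted(
        (g for g in ranking.index if g in background),
        key=lambda g: (ranking[g], g),
    )
    top = set(ranked[:top_n])
    a = len(top & hits)
    b = len(top - hits)
    c = len(hits - top)
    d = len(background) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    orr = (a2 * d2) / (b2 * c2)
    log_se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci = (
        float(np.exp(np.log(orr) - 1.96 * log_se)),
        float(np.exp(np.log(orr) + 1.96 * log_se)),
    )
    return float(orr), ci, float(p)
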