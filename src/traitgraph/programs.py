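"""Consensus non-negative matrix factorization of expression programs.

Programs are recurring non-negative expression components: repeated NMF
restarts are pooled, outlier components are removed by a local-density
filter, survivors are clustered, and each cluster's elementwise median
spectrum becomes a consensus program. Cell usages are then refit by
non-negative least squares against the consensus spectra.

The input convention is cells x genes, non-negative (typically
log-normalized expression with genes scaled to unit variance without
centering, which preserves non-negativity).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

__all__ = [
    "ProgramDecomposition",
    "variance_scale",
    "run_consensus_nmf",
    "select_k",
    "choose_k",
    "top_loading_genes",
]


class DegenerateDecompositionError(RuntimeError):
    """Raised when the density filter leaves too few components to form k programs."""


@dataclass
class ProgramDecomposition:
    """Consensus spectra (gene x K), refit usages (cell x K), diagnostics."""

    loadings: pd.DataFrame  # genes x K, non-negative
    usages: pd.DataFrame  # cells x K, non-negative
    k: int
    stability: float  # mean silhouette of surviving components
    error: float  # Frobenius reconstruction error
    n_runs: int
    density_threshold: float
    n_components_kept: int = 0

    def program_labels(self) -> list[str]:
        return list(self.loadings.columns)


def variance_scale(matrix: np.ndarray) -> np.ndarray:
    """Scale genes (columns) to unit variance without centering."""
    sd = matrix.std(axis=0)
    sd[sd == 0] = 1.0
    return matrix / sd


def _spectrum_hash(spectrum: np.ndarray) -> str:
    return hashlib.sha256(np.round(spectrum, 9).tobytes()).hexdigest()


def run_consensus_nmf(
    matrix,
    k: int,
    n_runs: int = 30,
    density_threshold: float = 0.5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    init: str = "random",
) -> ProgramDecomposition:
    """Consensus NMF at a fixed number of programs k.

    ``n_runs`` factorizations with distinct seeds (random non-negative
    initialization, so restarts genuinely differ and the consensus
    ensemble is informative) are pooled; every
    component spectrum is L2-normalized; components whose mean Euclidean
    distance to their ``n_runs // 3`` nearest neighbors exceeds
    ``density_threshold`` are discarded; survivors are k-means clustered
    into k groups; the consensus spectrum of each cluster is the
    elementwise median, renormalized; usages are refit per cell by
    non-negative least squares. Program indices are assigned by
    decreasing cluster size (ties broken by spectrum hash) so numbering
    is reproducible under run reordering.
    """
    if isinstance(matrix, pd.DataFrame):
        cells = list(matrix.index)
        genes = list(matrix.columns)
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, dtype=float)
        cells = [f"cell{i}" for i in range(X.shape[0])]
        genes = [f"gene{j}" for j in range(X.shape[1])]
    if (X < 0).any():
        raise ValueError("input matrix must be non-negative")
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(matrix dims)={min(X.shape)}")

    spectra = []
    for run in range(n_runs):
        model = NMF(
            n_components=k,
            init=init,
            solver="cd",
            max_iter=max_iter,
            random_state=seed + run,
            tol=tol,
        )
        model.fit(X)
        H = model.components_  # k x genes
        norms = np.linalg.norm(H, axis=1)
        norms[norms == 0] = 1.0
        spectra.append(H / norms[:, None])
    pool = np.vstack(spectra)  # (n_runs * k) x genes

    n_neighbors = max(1, n_runs // 3)
    d = cdist(pool, pool)
    np.fill_diagonal(d, np.inf)
    knn = np.sort(d, axis=1)[:, :n_neighbors]
    mean_knn_dist = knn.mean(axis=1)
    keep = mean_knn_dist <= density_threshold
    survivors = pool[keep]
    if survivors.shape[0] < k:
        raise DegenerateDecompositionError(
            f"density filter kept {survivors.shape[0]} components; "
            f"k={k} unreachable"
        )

    km = KMeans(n_clusters=k, n_init=10, random_state=0)
    labels = km.fit_predict(survivors)
    if len(set(labels)) < k:
        raise DegenerateDecompositionError("a consensus cluster is empty")
    stability = (
        float(silhouette_score(survivors, labels)) if k > 1 else 1.0
    )

    consensus = []
    for c in range(k):
        spec = np.median(survivors[labels == c], axis=0)
        norm = np.linalg.norm(spec)
        consensus.append(spec / (norm if norm > 0 else 1.0))
    sizes = np.bincount(labels, minlength=k)
    order = sorted(
        range(k), key=lambda c: (-sizes[c], _spectrum_hash(consensus[c]))
    )
    S = np.vstack([consensus[c] for c in order])  # k x genes

    usages = np.empty((X.shape[0], k))
    St = S.T
    for i in range(X.shape[0]):
        usages[i], _ = nnls(St, X[i])
    error = float(np.linalg.norm(X - usages @ S))

    cols = [f"P{j}" for j in range(k)]
    return ProgramDecomposition(
        loadings=pd.DataFrame(S.T, index=genes, columns=cols),
        usages=pd.DataFrame(usages, index=cells, columns=cols),
        k=k,
        stability=stability,
        error=error,
        n_runs=n_runs,
        density_threshold=density_threshold,
        n_components_kept=int(keep.sum()),
    )


def select_k(
    matrix,
    k_candidates: list[int],
    n_runs: int = 30,
    density_threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability/error table over candidate k; the caller chooses.

    Output is sorted ascending by k; a k that fails (infeasible or
    degenerate) gets an ``error_message`` and NaN diagnostics while the
    others are still computed.
    """
    rows = []
    for k in sorted(k_candidates):
        try:
            dec = run_consensus_nmf(
                matrix, k, n_runs=n_runs,
                density_threshold=density_threshold, seed=seed,
            )
            rows.append(
                dict(k=k, stability=dec.stability, error=dec.error,
                     n_components_kept=dec.n_components_kept, error_message="")
            )
        except (ValueError, DegenerateDecompositionError) as exc:
            rows.append(
                dict(k=k, stability=np.nan, error=np.nan,
                     n_components_kept=0, error_message=str(exc))
            )
    return pd.DataFrame(rows)


def choose_k(table: pd.DataFrame, stability_tol: float = 0.005) -> int:
    """Error-versus-stability choice of k from a ``select_k`` table.

    Stability alone cannot separate an under-factorized k from the true
    one: merged components can be perfectly reproducible across
    restarts, leaving both silhouettes within noise of 1. Among the
    candidates whose stability is within ``stability_tol`` of the best,
    the one with the smallest reconstruction error is chosen -- more
    components always reconstruct better, so this resolves exactly the
    near-ties where stability is uninformative, while over-factorized
    k values (whose split components genuinely wander) are excluded by
    their depressed stability.
    """
    ok = table[table["error_message"] == ""] if "error_message" in table else table
    if ok.empty:
        raise ValueError("no feasible k in the selection table")
    best = ok["stability"].max()
    near = ok[ok["stability"] >= best - stability_tol]
    return int(near.loc[near["error"].idxmin(), "k"])


def top_loading_genes(
    dec: ProgramDecomposition, program: str | int, n: int
) -> list[str]:
    """Top-n genes of one program by loading, ties broken by gene id."""
    col = dec.loadings.columns[program] if isinstance(program, int) else program
    if n > dec.loadings.shape[0]:
        raise ValueError(f"n={n} exceeds {dec.loadings.shape[0]} genes")
    s = dec.loadings[col]
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return order[:n]
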