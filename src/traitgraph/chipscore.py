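"""Decay-weighted TF regulation scores from binding peaks.

A TF's regulatory potential on a gene is the sum over its peaks of the
peak strength (-log10 q-value) weighted by exponential decay in the
peak-to-TSS distance:

    S(i, j; d) = sum_k P(i, k) * exp(-x(i, j, k) / d)

with x the absolute bp distance from the peak reference point to the
gene's TSS (same chromosome only; cross-chromosome peaks contribute 0)
and d the decay length (typically 5 kb for promoter-proximal TFs or
50 kb for distal ones). The peak reference point is the summit
(narrowPeak column 10 offset, when present and >= 0), otherwise the
integer-floor midpoint of start/end. Coordinates follow the 0-based
half-open BED convention throughout.

TFs are classified as activators/inhibitors by asking whether their
scores are high over the genes that respond to their knockdown
(down-regulated DEGs -> activator; up-regulated -> inhibitor), and
programs are annotated by rank enrichment of TF scores over their
top-loading genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_chip_scores",
    "classify_tf_direction",
    "annotate_program_tfs",
]


def _peak_reference(peaks: pd.DataFrame) -> np.ndarray:
    start = peaks["start"].to_numpy(np.int64)
    end = peaks["end"].to_numpy(np.int64)
    center = (start + end) // 2
    if "summit" in peaks.columns:
        summit = peaks["summit"].to_numpy(np.int64)
        center = np.where(summit >= 0, start + summit, center)
    return center


def compute_chip_scores(
    peaks: pd.DataFrame, tss: pd.DataFrame, decay_bp: float
) -> pd.DataFrame:
    """TF x gene matrix of decay-weighted peak strengths.

    ``peaks`` columns: tf, chrom, start, end, strength (and optionally
    summit, the offset from start); ``tss`` columns: chrom, start, gene
    (BED6 dialect, TSS at ``start``). Strand is ignored for distance.
    """
    if decay_bp <= 0:
        raise ValueError("decay_bp must be positive")
    if (peaks["start"] < 0).any() or (tss["start"] < 0).any():
        raise ValueError("negative coordinates are not valid BED")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak start must be < end")
    tss = tss.reset_index(drop=True)
    tfs = sorted(peaks["tf"].unique())
    genes = list(tss["gene"])
    scores = np.zeros((len(tfs), len(genes)))
    peak_ref = _peak_reference(peaks)
    for chrom, tss_chr in tss.groupby("chrom"):
        gene_cols = tss_chr.index.to_numpy()
        gpos = tss_chr["start"].to_numpy(np.int64)
        chr_mask = (peaks["chrom"] == chrom).to_numpy()
        for ti, tf in enumerate(tfs):
            sel = chr_mask & (peaks["tf"] == tf).to_numpy()
            if not sel.any():
                continue
            centers = peak_ref[sel]
            strength = peaks.loc[sel, "strength"].to_numpy(float)
            dist = np.abs(centers[:, None] - gpos[None, :])
            contrib = strength[:, None] * np.exp(-dist / decay_bp)
            scores[ti, gene_cols] += contrib.sum(axis=0)
    out = pd.DataFrame(scores, index=tfs, columns=range(len(genes)))
    out.columns = genes
    return out


def _mwu_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney p (x stochastically greater than y)."""
    if x.size == 0 or y.size == 0:
        return 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)


def classify_tf_direction(
    scores_by_decay: dict[float, pd.DataFrame],
    deg_up: dict[str, set],
    deg_down: dict[str, set],
    background: set,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag each TF as activator and/or inhibitor against its knockdown DEGs.

    For each TF and each decay length: one-sided Mann-Whitney comparing
    the TF's scores over its down-regulated DEGs (activator test) or
    up-regulated DEGs (inhibitor test) against the background genes with
    the TF's DEGs removed. The decay with the stronger DEG
    correspondence (smaller best p) is retained per TF, then BH FDR is
    applied across TFs separately per test. A TF may carry both flags.

    Returns a table indexed by TF: chosen_decay, activator_p,
    inhibitor_p, activator_fdr, inhibitor_fdr, activator, inhibitor.
    """
    if not background:
        raise ValueError("background gene set is empty")
    decays = sorted(scores_by_decay)
    tfs = sorted(scores_by_decay[decays[0]].index)
    rows = []
    for tf in tfs:
        up = set(deg_up.get(tf, set())) & background
        down = set(deg_down.get(tf, set())) & background
        rest = sorted(background - up - down)
        best = None
        for d in decays:
            s = scores_by_decay[d].loc[tf]
            p_act = _mwu_greater(
                s.loc[sorted(down)].to_numpy(float), s.loc[rest].to_numpy(float)
            )
            p_inh = _mwu_greater(
                s.loc[sorted(up)].to_numpy(float), s.loc[rest].to_numpy(float)
            )
            cand = (min(p_act, p_inh), d, p_act, p_inh)
            if best is None or cand[0] < best[0]:
                best = cand
        _, d, p_act, p_inh = best
        rows.append(
            dict(tf=tf, chosen_decay=d, activator_p=p_act, inhibitor_p=p_inh)
        )
    out = pd.DataFrame(rows).set_index("tf")
    out["activator_fdr"] = multipletests(out["activator_p"], method="fdr_bh")[1]
    out["inhibitor_fdr"] = multipletests(out["inhibitor_p"], method="fdr_bh")[1]
    out["activator"] = out["activator_fdr"] < fdr
    out["inhibitor"] = out["inhibitor_fdr"] < fdr
    return out


def annotate_program_tfs(
    scores: pd.DataFrame,
    loadings: pd.DataFrame,
    classified_tfs: list[str],
    n_top: int = 300,
    usage_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank enrichment of each classified TF's scores over program genes.

    One-sided Mann-Whitney (program top-loading genes score higher than
    the remaining genes) per TF per program, BH FDR across all TF x
    program tests. When ``usage_effects`` (a PerturbEffectTable with
    program responses) is given, the TF's direct knockdown effect on
    each program's usage is joined in, so callers can report TFs that
    both bind program genes and shift program activity.
    """
    if not classified_tfs:
        raise ValueError("classified TF list is empty")
    if n_top > loadings.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds {loadings.shape[0]} genes")
    genes = [g for g in loadings.index if g in scores.columns]
    rows = []
    for program in loadings.columns:
        s = loadings.loc[genes, program]
        top = set(sorted(genes, key=lambda g: (-s[g], g))[:n_top])
        rest = sorted(set(genes) - top)
        top = sorted(top)
        for tf in sorted(classified_tfs):
            p = _mwu_greater(
                scores.loc[tf, top].to_numpy(float),
                scores.loc[tf, rest].to_numpy(float),
            )
            rows.append(dict(program=program, tf=tf, p_value=p))
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    if usage_effects is not None:
        eff = usage_effects[usage_effects["status"] == "ok"][
            ["perturbed_gene", "response", "beta", "fdr"]
        ].rename(
            columns={
                "perturbed_gene": "tf",
                "response": "program",
                "beta": "usage_beta",
                "fdr": "usage_fdr",
            }
        )
        out = out.merge(eff, on=["tf", "program"], how="left")
    return out
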