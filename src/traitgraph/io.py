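"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: TSV for gene-level tables and matrices,
MatrixMarket + annotation TSVs for cell data, ENCODE narrowPeak (10
column BED dialect, 0-based half-open, peak strength = -log10 q in
column 9) for TF peaks, BED6 for TSSs, and JSON for priors, ground
truth, and graphs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .burden import PriorParams
from .synthetic import CellData, GroundTruth

BURDEN_COLUMNS = ["gene", "gamma_hat", "se", "shet"]


def write_burden_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in table.columns if c in BURDEN_COLUMNS + [
        "posterior_mean", "posterior_sign_prob"]]
    table[cols].to_csv(path, sep="\t", index=False)


def read_burden_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(BURDEN_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"burden TSV missing columns: {sorted(missing)}")
    return table


def write_cells(data: CellData, outdir) -> None:
    """CellData -> matrix.mtx (genes x cells) + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(data.counts))
    pd.DataFrame({"gene": data.genes}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    obs = data.obs.reset_index()
    obs.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_cells(indir) -> CellData:
    indir = Path(indir)
    counts = sparse.csr_matrix(scipy_io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].tolist()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell")
    return CellData(counts=counts, genes=genes, cells=list(obs.index), obs=obs)


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """PeakSet -> 10-column narrowPeak; TF kept in the name column."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": [
                f"{tf}:{i}" for i, tf in enumerate(peaks["tf"])
            ],
            "score": 0,
            "strand": ".",
            "signalValue": peaks["strength"],
            "pValue": -1,
            "qValue": peaks["strength"],
            "peak": peaks.get("summit", pd.Series([-1] * len(peaks))),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_narrowpeak(path) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "signalValue", "pValue", "qValue", "peak",
    ]
    raw = pd.read_csv(path, sep="\t", header=None, names=cols)
    return pd.DataFrame(
        {
            "tf": [str(n).rsplit(":", 1)[0] for n in raw["name"]],
            "chrom": raw["chrom"],
            "start": raw["start"],
            "end": raw["end"],
            "strength": raw["qValue"],
            "summit": raw["peak"],
        }
    )


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    tss[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_tss_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_effects_tsv(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, sep="\t", index=False)


def read_effects_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), sort_keys=True) + "\n")


def read_truth_json(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_priors_json(priors: dict[str, PriorParams], path) -> None:
    payload = {
        label: {
            "p": pr.p, "alpha": pr.alpha, "theta": pr.theta,
            "feature_bin": pr.feature_bin, "loglik": pr.loglik,
            "converged": pr.converged, "p_identifiable": pr.p_identifiable,
        }
        for label, pr in priors.items()
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def read_priors_json(path) -> dict[str, PriorParams]:
    payload = json.loads(Path(path).read_text())
    return {label: PriorParams(**kw) for label, kw in payload.items()}
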