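"""Synthetic gene-program-trait data generator.

Generates a planted causal structure -- regulators that shift program
activity, member genes that carry program content, and a quantitative
trait wired to both -- together with every downstream observable the
analysis pipeline consumes: gene-level burden summary statistics,
batched single-cell Poisson counts with one perturbation per cell, and
TF binding peaks on a synthetic linear genome.

The generative model, in brief:

* Each of ``n_programs`` programs has a disjoint set of regulators and
  a disjoint set of member genes. Member genes carry non-negative
  loadings on their program; regulators carry signed effects
  ``beta[x, p]`` on program usage.
* The true burden effect of gene ``x`` is
  ``gamma[x] = sum_p w_p * beta[x, p] + content_p * 1[x member of p] + eps``
  with ``eps ~ N(0, trait_noise_sd^2)``. Regulator-path weights ``w_p``
  and member-content weights may disagree in sign, so discordant
  program/regulator associations can be planted.
* Selective constraint ``shet`` is Beta-distributed on (0, 1) and
  coupled to ``|gamma|`` through a Gaussian copula, emulating the
  empirical positive correlation between constraint and trait effect.
* Burden standard errors increase with ``shet`` (constrained genes have
  fewer LoF carriers), and observed effects are
  ``gamma_hat = gamma + N(0, se^2)`` with cohort-specific noise.
* Cells receive one perturbation each; program usage is baseline plus
  the perturbation shift plus an additive batch offset plus noise,
  truncated at zero; expression rates are ``usage @ loadings.T`` plus a
  baseline housekeeping component, scaled to ``mean_depth``; counts are
  Poisson (optionally gamma-mixed for overdispersion).

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats


class SizingError(ValueError):
    """Raised when the gene budget cannot accommodate the requested structure."""


@dataclass
class SimulationConfig:
    """Parameters of the planted gene-program-trait simulation.

    Defaults describe a small but fully structured study: 3 programs,
    8 regulators and 40 member genes each, every gene perturbed in
    ~20 cells across 2 batches -- a desk-scale analogue of a
    genome-wide CRISPRi screen (which had a median of ~166 cells per
    perturbation and ~11,500 UMIs per cell).
    """

    n_genes: int = 300
    n_programs: int = 3
    n_regulators_per_program: int = 8
    n_member_genes_per_program: int = 40
    regulator_effect_scale: float = 1.0
    content_weight_per_program: tuple[float, ...] | None = None
    regulator_path_weight_per_program: tuple[float, ...] | None = None
    trait_noise_sd: float = 0.05
    se_range: tuple[float, float] = (0.05, 0.5)
    shet_gamma_coupling: float = 0.5
    n_cells_per_perturbation: int = 20
    n_nontargeting_cells: int = 500
    n_batches: int = 2
    mean_depth: float = 2000.0
    mito_fraction_mean: float = 0.08
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.content_weight_per_program is None:
            self.content_weight_per_program = (0.4,) * self.n_programs
        if self.regulator_path_weight_per_program is None:
            self.regulator_path_weight_per_program = (0.6,) * self.n_programs
        self.content_weight_per_program = tuple(
            float(v) for v in self.content_weight_per_program
        )
        self.regulator_path_weight_per_program = tuple(
            float(v) for v in self.regulator_path_weight_per_program
        )
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_programs",
            "n_regulators_per_program",
            "n_member_genes_per_program",
            "n_cells_per_perturbation",
            "n_batches",
        ):
            if getattr(self, name) < 1:
                raise SizingError(f"{name} must be a positive count")
        planted = self.n_programs * (
            self.n_regulators_per_program + self.n_member_genes_per_program
        )
        if planted > self.n_genes:
            raise SizingError(
                f"gene budget infeasible: {planted} planted genes exceed "
                f"n_genes={self.n_genes}"
            )
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise SizingError("se_range must satisfy 0 < low <= high")
        if len(self.content_weight_per_program) != self.n_programs:
            raise SizingError("content_weight_per_program length != n_programs")
        if len(self.regulator_path_weight_per_program) != self.n_programs:
            raise SizingError("regulator_path_weight length != n_programs")
        if not 0.0 <= self.shet_gamma_coupling <= 1.0:
            raise SizingError("shet_gamma_coupling must lie in [0, 1]")
        if self.n_nontargeting_cells < 0:
            raise SizingError("n_nontargeting_cells must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure underlying all simulated observables."""

    genes: list[str]
    loadings: np.ndarray  # gene x program, non-negative
    baseline_loading: np.ndarray  # gene vector, housekeeping component
    regulator_effects: np.ndarray  # gene x program, signed beta[x -> P]
    trait_weights_regulator: np.ndarray  # w_p, program vector
    trait_weights_content: np.ndarray  # program vector
    gamma_true: np.ndarray  # per-gene true burden effect
    shet: np.ndarray  # per-gene constraint in (0, 1)
    program_membership: dict[str, int]  # member gene -> program
    regulator_of: dict[str, int]  # regulator gene -> program
    tf_assignments: dict[str, int | None]  # TF name -> program (None = background)
    mito_genes: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_programs(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "loadings": self.loadings.tolist(),
            "baseline_loading": self.baseline_loading.tolist(),
            "regulator_effects": self.regulator_effects.tolist(),
            "trait_weights_regulator": self.trait_weights_regulator.tolist(),
            "trait_weights_content": self.trait_weights_content.tolist(),
            "gamma_true": self.gamma_true.tolist(),
            "shet": self.shet.tolist(),
            "program_membership": self.program_membership,
            "regulator_of": self.regulator_of,
            "tf_assignments": self.tf_assignments,
            "mito_genes": self.mito_genes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            genes=list(d["genes"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            baseline_loading=np.asarray(d["baseline_loading"], dtype=float),
            regulator_effects=np.asarray(d["regulator_effects"], dtype=float),
            trait_weights_regulator=np.asarray(
                d["trait_weights_regulator"], dtype=float
            ),
            trait_weights_content=np.asarray(d["trait_weights_content"], dtype=float),
            gamma_true=np.asarray(d["gamma_true"], dtype=float),
            shet=np.asarray(d["shet"], dtype=float),
            program_membership={k: int(v) for k, v in d["program_membership"].items()},
            regulator_of={k: int(v) for k, v in d["regulator_of"].items()},
            tf_assignments={
                k: (None if v is None else int(v))
                for k, v in d["tf_assignments"].items()
            },
            mito_genes=list(d["mito_genes"]),
        )


@dataclass
class CellData:
    """Single-cell count data with one perturbation label per cell.

    ``counts`` is genes x cells (CSR); ``obs`` is indexed by cell id
    with columns perturbation, batch, n_genes, pct_mito.
    """

    counts: sparse.csr_matrix
    genes: list[str]
    cells: list[str]
    obs: pd.DataFrame

    NON_TARGETING = "non-targeting"

    def copy(self) -> "CellData":
        return CellData(
            counts=self.counts.copy(),
            genes=list(self.genes),
            cells=list(self.cells),
            obs=self.obs.copy(),
        )


def _gene_names(n_genes: int, n_mito: int) -> tuple[list[str], list[str]]:
    width = max(4, len(str(n_genes)))
    names = [f"G{i:0{width}d}" for i in range(n_genes)]
    mito = []
    for i in range(n_genes - n_mito, n_genes):
        names[i] = "MT-" + names[i]
        mito.append(names[i])
    return names, mito


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw a planted gene-program-trait structure.

    Deterministic given ``config.seed``. Regulator and member sets are
    disjoint across and within programs; remaining genes are unstructured
    background (a fraction of which are designated mito-like for the
    pct_mito covariate).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    P = config.n_programs
    R = config.n_regulators_per_program
    M = config.n_member_genes_per_program

    n_planted = P * (R + M)
    n_background = n - n_planted
    n_mito = min(n_background, max(3, int(round(0.02 * n)))) if n_background else 0
    genes, mito_genes = _gene_names(n, n_mito)

    # contiguous blocks: regulators first, then members, then background
    regulator_of: dict[str, int] = {}
    program_membership: dict[str, int] = {}
    for p in range(P):
        for i in range(p * R, (p + 1) * R):
            regulator_of[genes[i]] = p
        for i in range(P * R + p * M, P * R + (p + 1) * M):
            program_membership[genes[i]] = p

    gene_index = {g: i for i, g in enumerate(genes)}
    loadings = np.zeros((n, P))
    for g, p in program_membership.items():
        loadings[gene_index[g], p] = rng.uniform(1.0, 2.0)
    # faint non-negative background loadings keep the matrix realistic
    loadings += rng.uniform(0.0, 0.02, size=(n, P))

    baseline = rng.uniform(0.5, 1.5, size=n)
    if n_mito:
        # rescale mito housekeeping expression so its expected share of
        # total depth is ~ mito_fraction_mean
        mito_idx = np.array([gene_index[g] for g in mito_genes])
        other = np.ones(n, dtype=bool)
        other[mito_idx] = False
        expected_other = loadings[other].sum() + baseline[other].sum()
        m = config.mito_fraction_mean
        target_mito = m / (1.0 - m) * expected_other
        baseline[mito_idx] *= target_mito / baseline[mito_idx].sum()

    beta = np.zeros((n, P))
    for g, p in regulator_of.items():
        sign = rng.choice([-1.0, 1.0])
        beta[gene_index[g], p] = sign * config.regulator_effect_scale * rng.uniform(
            0.75, 1.25
        )

    w_reg = np.asarray(config.regulator_path_weight_per_program, dtype=float)
    w_content = np.asarray(config.content_weight_per_program, dtype=float)

    gamma = beta @ w_reg
    for g, p in program_membership.items():
        gamma[gene_index[g]] += w_content[p]
    if config.trait_noise_sd > 0:
        gamma = gamma + rng.normal(0.0, config.trait_noise_sd, size=n)

    # shet ~ Beta, coupled to |gamma| through a Gaussian copula
    c = config.shet_gamma_coupling
    abs_rank = stats.rankdata(np.abs(gamma), method="average")
    z_gamma = stats.norm.ppf((abs_rank - 0.5) / n)
    z = c * z_gamma + np.sqrt(max(0.0, 1.0 - c * c)) * rng.standard_normal(n)
    u = stats.norm.cdf(z)
    shet = stats.beta.ppf(np.clip(u, 1e-12, 1 - 1e-12), 1.2, 3.0)
    shet = np.clip(shet, 1e-6, 1 - 1e-6)

    tf_assignments: dict[str, int | None] = {f"TF{p}": p for p in range(P)}
    tf_assignments["TF_NULL"] = None

    return GroundTruth(
        genes=genes,
        loadings=loadings,
        baseline_loading=baseline,
        regulator_effects=beta,
        trait_weights_regulator=w_reg,
        trait_weights_content=w_content,
        gamma_true=gamma,
        shet=shet,
        program_membership=program_membership,
        regulator_of=regulator_of,
        tf_assignments=tf_assignments,
        mito_genes=mito_genes,
    )


def simulate_burden_stats(
    truth: GroundTruth, config: SimulationConfig, cohort_seed: int
) -> pd.DataFrame:
    """Simulate one cohort's burden summary statistics.

    SEs are a deterministic increasing function of shet over
    ``config.se_range`` (constrained genes have fewer LoF carriers, hence
    noisier estimates); observed effects add cohort-specific Normal noise.
    Two calls with different ``cohort_seed`` share ``gamma_true`` but have
    independent measurement noise, emulating a two-cohort replication
    design.
    """
    rng = np.random.default_rng([config.seed, int(cohort_seed)])
    lo, hi = config.se_range
    se = lo + (hi - lo) * truth.shet
    gamma_hat = truth.gamma_true + rng.standard_normal(truth.n_genes) * se
    return pd.DataFrame(
        {
            "gene": truth.genes,
            "gamma_hat": gamma_hat,
            "se": se,
            "shet": truth.shet,
        }
    )


def simulate_cells(truth: GroundTruth, config: SimulationConfig) -> CellData:
    """Simulate batched Poisson single-cell counts, one perturbation per cell.

    Every gene in the truth is perturbed in ``n_cells_per_perturbation``
    cells; ``n_nontargeting_cells`` cells carry the non-targeting label.
    Program usage is baseline + perturbation shift + batch offset + noise,
    truncated at 0. Expression rates ``usage @ loadings.T`` (plus the
    baseline housekeeping component) are scaled per cell to expected total
    ``mean_depth`` before Poisson sampling.
    """
    if config.n_batches < 1:
        raise SizingError("n_batches must be >= 1")
    rng = np.random.default_rng([config.seed, 7_654_321])
    n = truth.n_genes
    P = truth.n_programs

    labels = []
    for g in truth.genes:
        labels.extend([g] * config.n_cells_per_perturbation)
    labels.extend([CellData.NON_TARGETING] * config.n_nontargeting_cells)
    n_cells = len(labels)
    labels = np.asarray(labels, dtype=object)

    batches = rng.integers(0, config.n_batches, size=n_cells)
    batch_offsets = rng.normal(0.0, 0.1, size=(config.n_batches, P))

    gene_index = {g: i for i, g in enumerate(truth.genes)}
    usage = 1.0 + rng.normal(0.0, 0.3, size=(n_cells, P))
    for c, lab in enumerate(labels):
        if lab != CellData.NON_TARGETING:
            usage[c] += truth.regulator_effects[gene_index[lab]]
    usage += batch_offsets[batches]
    usage += rng.normal(0.0, 0.1, size=(n_cells, P))
    usage = np.clip(usage, 0.0, None)

    base_usage = np.clip(1.0 + rng.normal(0.0, 0.1, size=n_cells), 0.0, None)

    rate = usage @ truth.loadings.T + base_usage[:, None] * truth.baseline_loading
    totals = rate.sum(axis=1)
    totals[totals == 0] = 1.0
    rate *= (config.mean_depth / totals)[:, None]
    if config.overdispersion > 0:
        od = config.overdispersion
        rate *= rng.gamma(1.0 / od, od, size=rate.shape)
    counts = rng.poisson(rate).astype(np.int64)  # cells x genes

    mito_idx = np.array(
        [gene_index[g] for g in truth.mito_genes], dtype=int
    )
    totals_obs = counts.sum(axis=1)
    safe_tot = np.where(totals_obs == 0, 1, totals_obs)
    pct_mito = (
        100.0 * counts[:, mito_idx].sum(axis=1) / safe_tot
        if mito_idx.size
        else np.zeros(n_cells)
    )
    n_genes_expressed = (counts > 0).sum(axis=1)

    cells = [f"cell{i:06d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "perturbation": labels,
            "batch": [f"batch{b}" for b in batches],
            "n_genes": n_genes_expressed,
            "pct_mito": pct_mito,
        },
        index=pd.Index(cells, name="cell"),
    )
    return CellData(
        counts=sparse.csr_matrix(counts.T),
        genes=list(truth.genes),
        cells=cells,
        obs=obs,
    )


def simulate_chip_peaks(
    truth: GroundTruth,
    peaks_per_target: int = 3,
    strength_range: tuple[float, float] = (2.0, 10.0),
    seed: int = 0,
    window: int = 1000,
    background_peaks: int | None = None,
    tss_spacing: int = 20_000,
    peak_halfwidth: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place TF peaks near target-program member TSSs on a linear genome.

    Returns ``(peaks, tss)``. Genes sit on one synthetic chromosome with
    TSSs every ``tss_spacing`` bp (0-based). Each TF assigned to a program
    gets ``peaks_per_target`` peaks within ``window`` bp of each member
    TSS, with strengths (-log10 q analogues) uniform in
    ``strength_range``; every TF additionally gets ``background_peaks``
    peaks placed uniformly on the genome (defaults to the targeted count,
    so background-only TFs have comparable peak numbers).
    """
    if not truth.tf_assignments:
        raise ValueError("tf_assignments is empty")
    if peaks_per_target < 1:
        raise ValueError("peaks_per_target must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    n = truth.n_genes
    tss_pos = 10_000 + tss_spacing * np.arange(n)
    genome_end = int(tss_pos[-1] + tss_spacing)

    tss = pd.DataFrame(
        {
            "chrom": chrom,
            "start": tss_pos,
            "end": tss_pos + 1,
            "gene": truth.genes,
            "score": 0,
            "strand": "+",
        }
    )

    gene_index = {g: i for i, g in enumerate(truth.genes)}
    members_by_program: dict[int, list[int]] = {}
    for g, p in truth.program_membership.items():
        members_by_program.setdefault(p, []).append(gene_index[g])

    lo, hi = strength_range
    rows = []
    for tf in sorted(truth.tf_assignments):
        program = truth.tf_assignments[tf]
        n_targeted = 0
        if program is not None:
            for gi in sorted(members_by_program.get(program, [])):
                for _ in range(peaks_per_target):
                    offset = int(rng.integers(-window, window + 1)) if window else 0
                    center = max(peak_halfwidth, int(tss_pos[gi]) + offset)
                    rows.append(
                        (
                            tf,
                            chrom,
                            center - peak_halfwidth,
                            center + peak_halfwidth,
                            float(rng.uniform(lo, hi)),
                            peak_halfwidth,
                        )
                    )
                    n_targeted += 1
        n_bg = background_peaks
        if n_bg is None:
            n_bg = max(n_targeted, peaks_per_target * 20)
        for _ in range(n_bg):
            center = int(rng.integers(peak_halfwidth, genome_end))
            rows.append(
                (
                    tf,
                    chrom,
                    center - peak_halfwidth,
                    center + peak_halfwidth,
                    float(rng.uniform(lo, hi)),
                    peak_halfwidth,
                )
            )
    peaks = pd.DataFrame(
        rows, columns=["tf", "chrom", "start", "end", "strength", "summit"]
    )
    return peaks, tss
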