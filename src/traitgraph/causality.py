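"""Causal direction between program pairs from asymmetric correlations.

If program p1 causally feeds program p2, then the regulators of p1
should show correlated knockdown effects on both programs, while the
regulators of p2 (ascertained independently) need not correlate back.
For each ordered pair we compute the Spearman correlation of effect
sizes over each program's significant regulators, Fisher-z transform it
(z = arctanh(rho), approximately Normal with variance 1/(N-3)), and
compare four Gaussian models by AIC:

* M1: p1 -> p2 (Z2 = 0, Z1 free), k = 1
* M2: p2 -> p1 (Z1 = 0, Z2 free), k = 1
* M3: no relationship (Z1 = Z2 = 0), k = 0
* M4: correlation independent of ascertainment (Z1 = Z2 = Z*), k = 1

The relative likelihood r = exp((AIC_causal - AIC_noncausal)/2) of the
best causal vs best non-causal model yields a verdict; r below a
threshold (default 0.01) is called causal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CausalPairResult",
    "significant_regulators",
    "fit_four_models",
    "pair_verdict",
    "analyze_pair",
    "all_pairs",
]

_RHO_CLAMP = 1.0 - 1e-12


@dataclass
class CausalPairResult:
    p1: str
    p2: str
    n1: int
    n2: int
    rho1: float
    rho2: float
    z1: float
    z2: float
    aic: dict[str, float]
    r: float
    verdict: str  # p1_causes_p2 | p2_causes_p1 | non_causal | untestable

    def to_row(self) -> dict:
        row = dict(
            p1=self.p1, p2=self.p2, n1=self.n1, n2=self.n2,
            rho1=self.rho1, rho2=self.rho2, z1=self.z1, z2=self.z2,
            r=self.r, verdict=self.verdict,
        )
        for m, v in self.aic.items():
            row[f"aic_{m}"] = v
        return row


def significant_regulators(
    effects: pd.DataFrame, program: str, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Regulators with FDR < threshold on ``program`` (family: per response).

    Returns the matching effect rows (perturbed_gene, beta, fdr). Fewer
    than 4 significant regulators makes a pair untestable downstream,
    since the Fisher-z variance 1/(N-3) degenerates.
    """
    sub = effects[(effects["response"] == program) & (effects["status"] == "ok")]
    return sub[sub["fdr"] < fdr_threshold].copy()


def _fisher_z(rho: float) -> float:
    return float(np.arctanh(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)))


def fit_four_models(
    z1_hat: float, n1: int, z2_hat: float, n2: int
) -> pd.DataFrame:
    """Log-likelihood, parameter count and AIC of M1-M4.

    The joint likelihood is N(z1_hat; Z1, 1/(n1-3)) * N(z2_hat; Z2,
    1/(n2-3)); each model's MLE is closed-form (M4's shared value is the
    precision-weighted mean with weights n-3). AIC = 2k - 2 loglik.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n1, n2 >= 4 for the 1/(n-3) Fisher-z variance")
    s1 = 1.0 / np.sqrt(n1 - 3.0)
    s2 = 1.0 / np.sqrt(n2 - 3.0)

    def loglik(mu1: float, mu2: float) -> float:
        return float(
            stats.norm.logpdf(z1_hat, loc=mu1, scale=s1)
            + stats.norm.logpdf(z2_hat, loc=mu2, scale=s2)
        )

    zstar = ((n1 - 3.0) * z1_hat + (n2 - 3.0) * z2_hat) / (n1 + n2 - 6.0)
    rows = {
        "M1": (loglik(z1_hat, 0.0), 1),
        "M2": (loglik(0.0, z2_hat), 1),
        "M3": (loglik(0.0, 0.0), 0),
        "M4": (loglik(zstar, zstar), 1),
    }
    return pd.DataFrame(
        [
            dict(model=m, loglik=ll, k_params=k, aic=2.0 * k - 2.0 * ll)
            for m, (ll, k) in rows.items()
        ]
    ).set_index("model")


def pair_verdict(
    aic: dict[str, float] | pd.Series, threshold: float = 0.01
) -> tuple[float, str]:
    """Relative likelihood of the best causal vs best non-causal model.

    r = exp((AIC_causal - AIC_noncausal) / 2); the verdict is causal in
    the direction of the winning causal model iff r < threshold.
    """
    aic = dict(aic)
    aic_causal = min(aic["M1"], aic["M2"])
    aic_noncausal = min(aic["M3"], aic["M4"])
    r = float(np.exp((aic_causal - aic_noncausal) / 2.0))
    if r < threshold:
        verdict = "p1_causes_p2" if aic["M1"] <= aic["M2"] else "p2_causes_p1"
    else:
        verdict = "non_causal"
    return r, verdict


def analyze_pair(
    effects: pd.DataFrame,
    p1: str,
    p2: str,
    fdr_threshold: float = 0.05,
    threshold: float = 0.01,
) -> CausalPairResult:
    """Full asymmetric-correlation analysis for one program pair.

    ``effects`` is a long PerturbEffectTable whose responses include both
    programs with per-response FDR. Regulators significant for both
    programs stay in both ascertainment sets.
    """
    wide = effects[effects["status"] == "ok"].pivot_table(
        index="perturbed_gene", columns="response", values="beta"
    )
    regs1 = significant_regulators(effects, p1, fdr_threshold)["perturbed_gene"]
    regs2 = significant_regulators(effects, p2, fdr_threshold)["perturbed_gene"]
    regs1 = [g for g in regs1 if g in wide.index]
    regs2 = [g for g in regs2 if g in wide.index]
    n1, n2 = len(regs1), len(regs2)
    if n1 < 4 or n2 < 4:
        return CausalPairResult(
            p1=p1, p2=p2, n1=n1, n2=n2, rho1=np.nan, rho2=np.nan,
            z1=np.nan, z2=np.nan, aic={}, r=np.nan, verdict="untestable",
        )
    rho1 = float(stats.spearmanr(wide.loc[regs1, p1], wide.loc[regs1, p2]).statistic)
    rho2 = float(stats.spearmanr(wide.loc[regs2, p1], wide.loc[regs2, p2]).statistic)
    z1, z2 = _fisher_z(rho1), _fisher_z(rho2)
    aic_table = fit_four_models(z1, n1, z2, n2)
    aic = aic_table["aic"].to_dict()
    r, verdict = pair_verdict(aic, threshold)
    return CausalPairResult(
        p1=p1, p2=p2, n1=n1, n2=n2, rho1=rho1, rho2=rho2,
        z1=z1, z2=z2, aic=aic, r=r, verdict=verdict,
    )


def all_pairs(
    effects: pd.DataFrame,
    programs: list[str] | None = None,
    fdr_threshold: float = 0.05,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """CausalPairResult rows for every unordered program pair."""
    if programs is None:
        programs = sorted(effects["response"].dropna().unique())
    rows = []
    for p1, p2 in combinations(programs, 2):
        rows.append(
            analyze_pair(effects, p1, p2, fdr_threshold, threshold).to_row()
        )
    return pd.DataFrame(rows)
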