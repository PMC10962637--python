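"""Predicted vs observed expression across populations.

For each gene, the Spearman correlation between its predicted-expression
population medians and its observed-expression population medians measures
agreement; the summed correlation T = sum_g rho_g is tested against a
permutation null that shuffles which observed gene row is paired with which
predicted gene row, keeping every population column intact — so the
between-population covariance of each matrix is preserved exactly and only
the gene pairing is broken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PopulationExpression:
    """Aligned gene x population median matrices, predicted and observed."""

    predicted: pd.DataFrame
    observed: pd.DataFrame

    def __post_init__(self) -> None:
        pops = self.predicted.columns.intersection(self.observed.columns)
        genes = self.predicted.index.intersection(self.observed.index)
        if len(pops) < 3:
            raise ValueError("need >= 3 shared populations")
        if len(genes) == 0:
            raise ValueError("no shared genes")
        self.predicted = self.predicted.loc[genes, pops]
        self.observed = self.observed.loc[genes, pops]

    @property
    def populations(self) -> list[str]:
        return list(self.predicted.columns)


def _rowwise_spearman(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Spearman rho between matching rows; NaN for constant rows."""
    rho = np.full(pred.shape[0], np.nan)
    for i in range(pred.shape[0]):
        if np.ptp(pred[i]) == 0 or np.ptp(obs[i]) == 0:
            continue
        rho[i] = stats.spearmanr(pred[i], obs[i]).statistic
    return rho


def per_gene_spearman(pop_expr: PopulationExpression) -> pd.Series:
    """Per-gene Spearman rho across populations (average ranks for ties).

    Genes with a constant predicted or observed vector have no defined
    rank correlation and are skipped with a warning.
    """
    rho = _rowwise_spearman(
        pop_expr.predicted.to_numpy(float), pop_expr.observed.to_numpy(float)
    )
    out = pd.Series(rho, index=pop_expr.predicted.index, name="rho")
    n_bad = int(out.isna().sum())
    if n_bad:
        logger.warning("%d genes skipped (constant median vector)", n_bad)
    return out.dropna()


def permutation_pvalue(
    pop_expr: PopulationExpression, n_perm: int = 1000, seed=None
) -> dict:
    """Empirical upper-tail p for T = sum of per-gene Spearman rho.

    Null replicates permute the assignment of observed gene rows to
    predicted gene rows (population columns untouched); p uses the add-one
    correction (1 + #{T_null >= T}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pred = pop_expr.predicted.to_numpy(float)
    obs = pop_expr.observed.to_numpy(float)
    if pred.shape[0] < 2:
        raise ValueError("need >= 2 genes for the permutation test")
    rho_obs = _rowwise_spearman(pred, obs)
    T = float(np.nansum(rho_obs))
    rng = np.random.default_rng(seed)
    # ranks are permutation-invariant within rows, precompute them
    pred_r = np.apply_along_axis(stats.rankdata, 1, pred)
    obs_r = np.apply_along_axis(stats.rankdata, 1, obs)
    pred_ok = np.ptp(pred, axis=1) > 0
    obs_ok = np.ptp(obs, axis=1) > 0
    pred_z = _standardize_rows(pred_r)
    obs_z = _standardize_rows(obs_r)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pred.shape[0])
        valid = pred_ok & obs_ok[perm]
        null[b] = float(np.sum((pred_z[valid] * obs_z[perm][valid]).mean(axis=1)))
    p = (1 + int(np.sum(null >= T))) / (1 + n_perm)
    return {
        "T": T,
        "p": p,
        "n_perm": n_perm,
        "n_genes": int(np.sum(pred_ok & obs_ok)),
        "null_T": null,
    }


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    mu = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (r - mu) / sd


@dataclass
class ConcordanceResults:
    """Fitted predicted-vs-observed concordance test."""

    model: "ObservedConcordance"
    rho: pd.Series
    T: float
    p: float
    n_perm: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Predicted vs observed expression concordance",
                "=" * 48,
                f"genes compared:  {len(self.rho)}",
                f"populations:     {len(self.model.pop_expr.populations)}",
                f"sum of rho (T):  {self.T:.4f}",
                f"mean rho:        {self.rho.mean():.4f}",
                f"permutation p:   {self.p:.4g}  ({self.n_perm} permutations)",
            ]
        )

    def to_tsv(self, path: str) -> None:
        self.rho.rename("rho").rename_axis("gene").reset_index().to_csv(
            path, sep="\t", index=False
        )


class ObservedConcordance:
    """Permutation test of agreement between predicted and observed medians."""

    def __init__(self, predicted: pd.DataFrame, observed: pd.DataFrame):
        self.pop_expr = PopulationExpression(predicted=predicted, observed=observed)

    def fit(self, n_perm: int = 1000, seed=None) -> ConcordanceResults:
        rho = per_gene_spearman(self.pop_expr)
        res = permutation_pvalue(self.pop_expr, n_perm=n_perm, seed=seed)
        return ConcordanceResults(
            model=self, rho=rho, T=res["T"], p=res["p"], n_perm=n_perm
        )
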