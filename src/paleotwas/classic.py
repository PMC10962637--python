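"""Gene-level aggregation of SNP haplotype selection statistics (SDS/iHS).

Per-SNP normalized selection scores are combined over each gene's eQTL
model as z = sum_i beta_i * score_i / sqrt(sum_i beta_i^2). Because the
SNP scores are standard normal under neutrality, z is too, so two-sided
normal p-values apply, with genomic control on z^2 absorbing residual
correlation between model SNPs. Genes where fewer than half the model SNPs
have scores are removed, and the concordance of gene-level scores with the
time-series scan's slopes is summarised by sign agreement and Spearman
rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneModel
from .twss import fdr_call, genomic_control

logger = logging.getLogger(__name__)


def gene_level_score(
    model: GeneModel, scores: pd.DataFrame, denominator: str = "scored"
) -> tuple[float, float]:
    """(z, frac_scored) for one gene.

    ``scores`` has columns snp_id, score and optionally ``allele`` naming
    the allele the score's sign refers to; scores whose allele is the
    model's *other* allele are negated so every score refers to the effect
    allele. The denominator sums beta^2 over scored SNPs only by default
    (preserving the standard-normal null after masking); ``denominator=
    "all"`` uses every model SNP instead. Genes with no scored SNP (or
    zero scored weight) return z = NaN.
    """
    if denominator not in ("scored", "all"):
        raise ValueError("denominator must be 'scored' or 'all'")
    v = model.variants
    sc = scores.drop_duplicates("snp_id").set_index("snp_id")
    has_allele = "allele" in sc.columns
    num = 0.0
    ss_scored = 0.0
    n_scored = 0
    for _, row in v.iterrows():
        if row.snp_id not in sc.index:
            continue
        srow = sc.loc[row.snp_id]
        score = float(srow["score"])
        if has_allele and not pd.isna(srow["allele"]):
            if srow["allele"] == row.effect_allele:
                pass
            elif srow["allele"] == row.other_allele:
                score = -score
            else:
                logger.warning(
                    "gene %s SNP %s: score allele %s matches neither model allele; "
                    "treated as unscored",
                    model.gene_id,
                    row.snp_id,
                    srow["allele"],
                )
                continue
        num += row.weight * score
        ss_scored += row.weight**2
        n_scored += 1
    frac = n_scored / len(v)
    ss = ss_scored if denominator == "scored" else float((v["weight"] ** 2).sum())
    if n_scored == 0 or ss == 0.0:
        return float("nan"), frac
    return num / np.sqrt(ss), frac


def missing_filter(table: pd.DataFrame, min_frac: float = 0.5) -> pd.DataFrame:
    """Drop genes with frac_scored strictly below ``min_frac`` (0.5 kept)."""
    return table[table["frac_scored"] >= min_frac]


def score_pvalues(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-sided normal p for gene-level z, raw and genomic-controlled.

    Genomic control is applied to z^2 exactly as in the time-series scan.
    """
    z = np.asarray(z, float)
    p_raw = 2 * stats.norm.sf(np.abs(z))
    p_raw = np.clip(p_raw, 1e-300, 1.0)
    gc, p_gc = genomic_control(z**2)
    return p_raw, p_gc, gc.lambda_gc


@dataclass
class GeneLevelResults:
    """Fitted gene-level classic-statistic scan.

    ``table``: gene, z, frac_scored, p_raw, p_gc, q_value, significant
    (only genes passing the half-missing filter appear). ``lambda_gc`` is
    the inflation of z^2 relative to a 1-df chi-square.
    """

    model: "GeneLevelScan"
    table: pd.DataFrame
    lambda_gc: float
    q: float
    n_dropped_missing: int

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Gene-level {self.model.statistic} scan",
            "=" * 48,
            f"genes scored:       {len(t) + self.n_dropped_missing}",
            f"dropped (<50% SNPs scored): {self.n_dropped_missing}",
            f"genes tested:       {len(t)}",
            f"lambda_GC:          {self.lambda_gc:.3f}",
            f"significant genes:  {int(t['significant'].sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)


class GeneLevelScan:
    """Combine per-SNP SDS or iHS scores into gene-level Z statistics."""

    def __init__(
        self,
        models: list[GeneModel],
        scores: pd.DataFrame,
        denominator: str = "scored",
        statistic: str = "SDS",
    ):
        self.models = models
        self.scores = scores
        self.denominator = denominator
        self.statistic = statistic

    def fit(self, q: float = 0.05, min_frac: float = 0.5) -> GeneLevelResults:
        rows = []
        for m in self.models:
            z, frac = gene_level_score(m, self.scores, denominator=self.denominator)
            if np.isnan(z):
                continue
            rows.append({"gene": m.gene_id, "z": z, "frac_scored": frac})
        table = pd.DataFrame(rows).set_index("gene")
        kept = missing_filter(table, min_frac=min_frac)
        n_dropped = len(table) - len(kept)
        kept = kept.copy()
        p_raw, p_gc, lam = score_pvalues(kept["z"].to_numpy())
        kept["p_raw"] = p_raw
        kept["p_gc"] = p_gc
        q_values, reject, _ = fdr_call(p_gc, q=q)
        kept["q_value"] = q_values
        kept["significant"] = reject
        return GeneLevelResults(
            model=self, table=kept, lambda_gc=lam, q=q, n_dropped_missing=n_dropped
        )


def concordance(twss_table: pd.DataFrame, classic_table: pd.DataFrame) -> dict:
    """Agreement between time-series slopes and gene-level classic scores.

    Over genes present in both result sets, reports the Spearman rank
    correlation of beta vs z, the number jointly significant, and — among
    time-series-significant genes with scores — how many have matching
    signs of beta and z (the directional-concordance count).
    """
    shared = twss_table.index.intersection(classic_table.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two result sets")
    beta = twss_table.loc[shared, "beta"].to_numpy()
    z = classic_table.loc[shared, "z"].to_numpy()
    if len(shared) >= 2 and np.std(beta) > 0 and np.std(z) > 0:
        rho, rho_p = stats.spearmanr(beta, z)
    else:
        rho, rho_p = float("nan"), float("nan")
    twss_sig = twss_table.loc[shared, "significant"].to_numpy(bool)
    classic_sig = classic_table.loc[shared, "significant"].to_numpy(bool)
    agree = np.sign(beta) == np.sign(z)
    return {
        "n_shared": int(len(shared)),
        "n_twss_significant_with_scores": int(twss_sig.sum()),
        "n_jointly_significant": int((twss_sig & classic_sig).sum()),
        "n_sign_agree_among_twss_significant": int(agree[twss_sig].sum()),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }
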