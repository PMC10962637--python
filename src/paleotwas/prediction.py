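"""Predicted expression per individual and gene-level imputation quality.

Predicted normalized expression for an individual is the weighted sum of
effect-allele dosages over the gene's model SNPs, in expression-SD units.
The gene-level imputation quality is the |weight|-weighted average of
per-SNP imputation R^2, and the lowest-quality fraction of genes (20% by
default) is removed before the time-series scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneModel, GenotypeDataset
from .io import AlignedModel, align_alleles

logger = logging.getLogger(__name__)


@dataclass
class PredictedExpression:
    """Genes x samples predicted expression with per-gene model coverage.

    ``coverage`` is the fraction of total model weight |beta_i| attached to
    SNPs that were resolvable in the genotype dataset; genes with zero
    coverage are excluded (logged) and absent from ``matrix``.
    """

    matrix: pd.DataFrame  # index: gene_id, columns: sample_id
    coverage: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)


def predict_expression(
    dataset: GenotypeDataset,
    model: GeneModel,
    aligned: AlignedModel | None = None,
) -> tuple[np.ndarray, float]:
    """Predicted expression over samples plus the model's weight coverage.

    value = sum_i beta_i * oriented_dose_i over resolvable variants.
    Variants absent from the dataset (or with unmatched alleles) contribute
    nothing and reduce coverage. Per-sample missing doses are filled with
    twice the cohort-wide alt-allele frequency of the SNP.
    """
    if aligned is None:
        aligned = align_alleles(model, dataset)
    total_w = float(np.abs(model.variants["weight"]).sum())
    cov_w = float(np.abs(aligned.weight).sum())
    coverage = cov_w / total_w if total_w > 0 else 0.0
    if aligned.n_resolvable == 0:
        logger.warning("gene %s unpredictable: no resolvable variants", model.gene_id)
        return np.zeros(dataset.n_samples), 0.0
    doses = aligned.oriented_dosages(dataset)
    if np.isnan(doses).any():
        freq = dataset.alt_frequency()[aligned.snp_index]
        fill = np.where(aligned.flip, 2.0 * (1.0 - freq), 2.0 * freq)
        doses = np.where(np.isnan(doses), fill, doses)
    return doses @ aligned.weight, coverage


def predict_matrix(
    dataset: GenotypeDataset, models: list[GeneModel]
) -> PredictedExpression:
    """Predict expression for all models; drops zero-coverage genes."""
    rows, covs, kept = [], [], []
    for m in models:
        values, cov = predict_expression(dataset, m)
        if cov == 0.0:
            logger.warning("gene %s excluded (coverage 0)", m.gene_id)
            continue
        rows.append(values)
        covs.append(cov)
        kept.append(m.gene_id)
    matrix = pd.DataFrame(np.vstack(rows), index=kept, columns=dataset.sample_ids)
    return PredictedExpression(matrix=matrix, coverage=pd.Series(covs, index=kept))


def gene_quality(
    model: GeneModel,
    dataset: GenotypeDataset,
    aligned: AlignedModel | None = None,
) -> float:
    """Gene-level imputation quality: sum|b_i| R_i^2 / sum|b_i|.

    The sums run over variants resolvable in the dataset; the result lies
    within the convex hull of the member SNPs' R^2 values.
    """
    if aligned is None:
        aligned = align_alleles(model, dataset)
    w = np.abs(aligned.weight)
    if w.sum() == 0:
        raise ValueError(f"gene {model.gene_id}: degenerate model (sum|beta| = 0)")
    r2 = aligned.resolvable_r2(dataset)
    return float((w * r2).sum() / w.sum())


def gene_qualities(dataset: GenotypeDataset, models: list[GeneModel]) -> pd.Series:
    out = {}
    for m in models:
        aligned = align_alleles(m, dataset)
        if aligned.n_resolvable == 0 or np.abs(aligned.weight).sum() == 0:
            logger.warning("gene %s: no quality (unresolvable/degenerate)", m.gene_id)
            continue
        out[m.gene_id] = gene_quality(m, dataset, aligned)
    return pd.Series(out, name="r2_gene")


def filter_by_quality(
    qualities: pd.Series, drop_fraction: float = 0.20
) -> tuple[pd.Index, float]:
    """Drop the lowest-quality fraction of genes; ties at threshold retained.

    The threshold is the (floor(f*n)+1)-th smallest quality; genes strictly
    below it are removed, so with distinct values exactly ceil((1-f)*n)
    genes survive. Returns the retained gene index and the threshold used.
    """
    if len(qualities) == 0:
        raise ValueError("empty quality table")
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = len(qualities)
    k = math.floor(drop_fraction * n)
    if k == 0:
        return qualities.index, float("-inf")
    threshold = float(np.sort(qualities.to_numpy())[k])
    retained = qualities.index[qualities.to_numpy() >= threshold]
    return retained, threshold


def write_prediction_tsv(
    path: str,
    pred: PredictedExpression,
    models: list[GeneModel],
    qualities: pd.Series,
) -> None:
    meta = pd.DataFrame(
        {
            "gene": [m.gene_id for m in models],
            "tissue": [m.tissue for m in models],
            "training_r2": [m.training_r2 for m in models],
        }
    ).set_index("gene")
    out = meta.join(qualities.rename("r2_gene"), how="inner")
    out = out.join(pred.coverage.rename("coverage"), how="inner")
    out = out.join(pred.matrix, how="inner")
    out.reset_index(names="gene").to_csv(path, sep="\t", index=False)
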