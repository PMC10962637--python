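"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of objects around: a dosage matrix with per-SNP
imputation quality (:class:`GenotypeDataset`), dated sample metadata
(:class:`SampleTable`), and sparse per-gene cis-eQTL weight models
(:class:`GeneModel`). All are thin, validated wrappers around pandas/numpy
structures; file I/O lives in :mod:`paleotwas.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "r2"]


@dataclass
class GenotypeDataset:
    """Samples x SNPs matrix of alt-allele dosages with imputation quality.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``dosages``).
    snps
        DataFrame with columns ``snp_id, chrom, pos, ref, alt, r2``;
        ``pos`` is 1-based, ``r2`` is the per-SNP imputation quality in
        [0, 1] (1.0 when the source carries none).
    dosages
        ``(n_samples, n_snps)`` float array of alt-allele dose in [0, 2];
        missing genotypes are NaN.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table missing columns: {missing_cols}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        key = self.snps[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {tuple(dup)}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2 + 1e-9:
                raise ValueError("dosages outside [0, 2]")
        r2 = self.snps["r2"].to_numpy(float)
        if np.any((r2 < 0) | (r2 > 1) | ~np.isfinite(r2)):
            raise ValueError("imputation r2 outside [0, 1]")
        self._index_by_id = pd.Index(self.snps["snp_id"])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Positional indices of ``snp_ids``; -1 where absent."""
        return self._index_by_id.get_indexer(snp_ids)

    def alt_frequency(self) -> np.ndarray:
        """Cohort-wide alt-allele frequency per SNP (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sorted_by_position(self) -> "GenotypeDataset":
        """Canonical (chrom, pos) ordering; loading is order-independent."""
        order = self.snps.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).index.to_numpy()
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[order].reset_index(drop=True),
            dosages=self.dosages[:, order],
        )


@dataclass
class SampleTable:
    """Dated sample metadata: id, years before present, cohort label."""

    table: pd.DataFrame  # columns: sample_id, date_bp, cohort

    def __post_init__(self) -> None:
        required = {"sample_id", "date_bp", "cohort"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.table["date_bp"] < 0).any():
            raise ValueError("negative date_bp")

    def __len__(self) -> int:
        return len(self.table)

    def dates_for(self, sample_ids) -> np.ndarray:
        """date_bp aligned to ``sample_ids``; error if any id lacks a date."""
        s = self.table.set_index("sample_id")["date_bp"]
        missing = [i for i in sample_ids if i not in s.index]
        if missing:
            raise KeyError(f"samples without dates: {missing[:5]}")
        return s.loc[list(sample_ids)].to_numpy(float)

    def is_ancient(self, sample_ids) -> np.ndarray:
        s = self.table.set_index("sample_id")["cohort"]
        return (s.loc[list(sample_ids)] == "ancient").to_numpy()


@dataclass
class GeneModel:
    """Sparse linear cis-eQTL model for one gene in one tissue.

    ``variants`` has columns ``snp_id, effect_allele, other_allele, weight``;
    weights are in expression-SD per effect-allele copy. ``training_r2`` is
    the cross-validated accuracy of the model in its training tissue, used
    to select the best tissue per gene.
    """

    gene_id: str
    tissue: str
    training_r2: float
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "weight"}
        if not required.issubset(self.variants.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        if len(self.variants) == 0:
            raise ValueError(f"gene {self.gene_id}: model has no variants")
        w = self.variants["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)):
            raise ValueError(f"gene {self.gene_id}: non-finite weight")
        if self.training_r2 < 0:
            raise ValueError(f"gene {self.gene_id}: negative training_r2")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.variants)


@dataclass
class TrueArchitecture:
    """Ground truth of a simulated study, for parameter-recovery tests.

    Holds the per-gene weight assignments, the set of truly selected genes
    with their intended expression direction (+1 up / -1 down), and the
    per-SNP true selection coefficient.
    """

    gene_weights: dict[str, pd.DataFrame]
    selected_genes: dict[str, int]
    true_s: dict[str, float] = field(default_factory=dict)

    def s_for(self, snp_id: str) -> float:
        return self.true_s.get(snp_id, 0.0)
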