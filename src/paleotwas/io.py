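"""Readers and writers for genotypes, sample metadata, weight models, scores.

Genotypes move as VCF (FORMAT ``DS`` dosage, INFO ``R2`` quality; falling
back to ``GT`` alt-allele counts) or as a plain TSV matrix. Weight models
use PredictDB-style tables: a weights TSV (gene, tissue, snp_id,
effect_allele, other_allele, weight) and a gene summary TSV (gene, tissue,
training_r2). VCF parsing is delegated to cyvcf2; note that VCF FORMAT
floats are single-precision, so dosages survive a VCF round trip to ~1e-6
while the TSV matrix round-trips exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneModel, GenotypeDataset, SampleTable

logger = logging.getLogger(__name__)

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------- genotypes


def write_vcf(dataset: GenotypeDataset, path: str) -> None:
    """Write the dataset as an uncompressed VCF with DS dosages and INFO R2."""
    snps = dataset.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n'
        )
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        chroms = pd.unique(snps["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for j in range(dataset.n_snps):
            row = snps.iloc[j]
            doses = dataset.dosages[:, j]
            cells = ["." if np.isnan(d) else f"{d:.6f}" for d in doses]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t"
                f".\t.\tR2={row.r2:.6f}\tDS\t" + "\t".join(cells) + "\n"
            )


def _load_vcf(path: str, site_filter=None) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    records, dose_rows = [], []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if site_filter is not None and snp_id not in site_filter:
            continue
        alt = var.ALT[0] if var.ALT else "."
        r2 = var.INFO.get("R2")
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            doses = ds[:, 0].astype(float)
            doses[~np.isfinite(doses)] = np.nan
        else:
            doses = np.full(len(sample_ids), np.nan)
            for i, g in enumerate(var.genotypes):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    continue
                doses[i] = float(sum(1 for a in alleles if a == 1))
        records.append(
            {
                "snp_id": snp_id,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "r2": float(r2) if r2 is not None else 1.0,
            }
        )
        dose_rows.append(doses)
    if not records:
        raise ValueError(f"no variants parsed from {path}")
    return GenotypeDataset(
        sample_ids=sample_ids,
        snps=pd.DataFrame(records),
        dosages=np.vstack(dose_rows).T,
    ).sorted_by_position()


def write_dosage_tsv(dataset: GenotypeDataset, path: str) -> None:
    df = pd.concat(
        [
            dataset.snps,
            pd.DataFrame(dataset.dosages.T, columns=dataset.sample_ids),
        ],
        axis=1,
    )
    # repr round-trips doubles exactly; the TSV matrix is the lossless format
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def _load_dosage_tsv(path: str, site_filter=None) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt", "r2"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns {missing}")
    if site_filter is not None:
        df = df[df["snp_id"].isin(site_filter)].reset_index(drop=True)
    sample_ids = [c for c in df.columns if c not in meta_cols]
    return GenotypeDataset(
        sample_ids=sample_ids,
        snps=df[meta_cols],
        dosages=df[sample_ids].to_numpy(float).T,
    ).sorted_by_position()


def load_genotypes(path: str, site_filter=None) -> GenotypeDataset:
    """Load genotypes from VCF (DS, else GT) or from a dosage TSV matrix.

    Dosages are taken from the DS FORMAT field when present, otherwise from
    GT as the alt-allele count; missing genotypes stay missing (NaN), never
    imputed here. SNPs are canonically sorted by (chrom, pos) so loading is
    order-independent. ``site_filter`` optionally restricts to a set of
    SNP ids.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _load_vcf(path, site_filter)
    return _load_dosage_tsv(path, site_filter)


# ------------------------------------------------------------ sample tables


def write_sample_table(samples: SampleTable, path: str) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def load_sample_table(path: str) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


# ------------------------------------------------------------- gene models


def write_gene_models(models: list[GeneModel], weights_path: str, summary_path: str) -> None:
    wrows, srows = [], []
    for m in models:
        srows.append({"gene": m.gene_id, "tissue": m.tissue, "training_r2": m.training_r2})
        for _, v in m.variants.iterrows():
            wrows.append(
                {
                    "gene": m.gene_id,
                    "tissue": m.tissue,
                    "snp_id": v.snp_id,
                    "effect_allele": v.effect_allele,
                    "other_allele": v.other_allele,
                    "weight": v.weight,
                }
            )
    pd.DataFrame(wrows).to_csv(weights_path, sep="\t", index=False)
    pd.DataFrame(srows).to_csv(summary_path, sep="\t", index=False)


def load_gene_models(
    weights_path: str, summary_path: str, best_tissue_per_gene: bool = True
) -> list[GeneModel]:
    """Load PredictDB-style weight tables, keeping one tissue per gene.

    When a gene has models in several tissues, only the model with the
    highest training R^2 is retained (ties broken by the lexicographically
    smallest tissue name, so the choice is deterministic). Genes present in
    the summary but with no weight rows are dropped with a warning.
    """
    weights = pd.read_csv(weights_path, sep="\t")
    summary = pd.read_csv(summary_path, sep="\t")
    if "tissue" not in weights.columns:
        weights = weights.assign(tissue=summary["tissue"].iloc[0])
    if (summary["training_r2"] < 0).any():
        bad = summary[summary["training_r2"] < 0].iloc[0]
        raise ValueError(f"negative training_r2 for gene {bad.gene}")
    missing = set(weights["gene"]) - set(summary["gene"])
    if missing:
        raise ValueError(f"genes in weights but not summary: {sorted(missing)[:5]}")

    if best_tissue_per_gene:
        summary = (
            summary.sort_values(
                ["gene", "training_r2", "tissue"], ascending=[True, False, True]
            )
            .groupby("gene", as_index=False)
            .first()
        )
    grouped = weights.groupby(["gene", "tissue"])
    models = []
    for _, srow in summary.iterrows():
        key = (srow.gene, srow.tissue)
        if key not in grouped.groups:
            warnings.warn(f"gene {srow.gene} has no variants in tissue {srow.tissue}; dropped")
            continue
        g = grouped.get_group(key)
        models.append(
            GeneModel(
                gene_id=srow.gene,
                tissue=srow.tissue,
                training_r2=float(srow.training_r2),
                variants=g[["snp_id", "effect_allele", "other_allele", "weight"]],
            )
        )
    return models


def load_score_table(path: str) -> pd.DataFrame:
    """Per-SNP normalised selection score TSV (snp_id, [allele], score)."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns or "score" not in df.columns:
        raise ValueError("score table needs columns snp_id, score")
    if not np.all(np.isfinite(df["score"])):
        raise ValueError("non-finite scores")
    return df


# ---------------------------------------------------------- allele alignment


@dataclass
class AlignedModel:
    """A gene model oriented onto a genotype dataset.

    ``snp_index`` indexes into ``dataset.snps`` for each resolvable variant;
    ``flip`` marks variants whose effect allele is the dataset's ref allele
    (dose used as ``2 - dose``); ``ambiguous`` marks strand-ambiguous A/T
    or C/G sites (resolved by allele match only and flagged).
    ``unresolvable`` lists model variants absent from the dataset or whose
    effect allele matches neither dataset allele.
    """

    model: GeneModel
    snp_index: np.ndarray
    weight: np.ndarray
    flip: np.ndarray
    ambiguous: np.ndarray
    unresolvable: pd.DataFrame

    @property
    def n_resolvable(self) -> int:
        return len(self.snp_index)

    def oriented_dosages(self, dataset: GenotypeDataset) -> np.ndarray:
        """(n_samples, n_resolvable) effect-allele dosages."""
        d = dataset.dosages[:, self.snp_index]
        return np.where(self.flip, 2.0 - d, d)

    def resolvable_r2(self, dataset: GenotypeDataset) -> np.ndarray:
        return dataset.snps["r2"].to_numpy(float)[self.snp_index]


def orient_dose(dose: np.ndarray, flip) -> np.ndarray:
    """Effect-allele orientation: identity, or the involution d -> 2 - d."""
    return np.where(flip, 2.0 - np.asarray(dose, float), dose)


def align_alleles(model: GeneModel, dataset: GenotypeDataset) -> AlignedModel:
    """Orient model weights so each weight multiplies its effect-allele dose.

    Variants are matched by SNP id, or by (chrom, pos) when the id has the
    form ``chrom:pos``. If the effect allele equals the dataset alt allele
    the dose is used as-is; if it equals ref, the dose is flipped to
    ``2 - dose``; otherwise the variant is unresolvable. Strand-ambiguous
    A/T and C/G sites are resolved by allele match only (no frequency
    heuristic) and flagged.
    """
    snps = dataset.snps
    by_pos = {(c, p): i for i, (c, p) in enumerate(zip(snps["chrom"], snps["pos"]))}
    idx = dataset.snp_indices(model.variants["snp_id"])

    keep_idx, keep_w, keep_flip, keep_amb, bad_rows = [], [], [], [], []
    for row_i, (_, v) in enumerate(model.variants.iterrows()):
        j = idx[row_i]
        if j < 0 and ":" in str(v.snp_id):
            chrom, _, pos = str(v.snp_id).partition(":")
            try:
                j = by_pos.get((chrom, int(pos)), -1)
            except ValueError:
                j = -1
        if j < 0:
            bad_rows.append({**v.to_dict(), "reason": "absent"})
            continue
        ref, alt = snps["ref"].iat[j], snps["alt"].iat[j]
        if v.effect_allele == alt:
            flip = False
        elif v.effect_allele == ref:
            flip = True
        else:
            bad_rows.append({**v.to_dict(), "reason": "allele mismatch"})
            continue
        amb = (ref, alt) in _AMBIGUOUS_PAIRS
        if amb:
            logger.info(
                "gene %s: strand-ambiguous site %s resolved by allele match",
                model.gene_id,
                v.snp_id,
            )
        keep_idx.append(j)
        keep_w.append(float(v.weight))
        keep_flip.append(flip)
        keep_amb.append(amb)
    if bad_rows:
        logger.info("gene %s: %d unresolvable variants", model.gene_id, len(bad_rows))
    return AlignedModel(
        model=model,
        snp_index=np.asarray(keep_idx, int),
        weight=np.asarray(keep_w, float),
        flip=np.asarray(keep_flip, bool),
        ambiguous=np.asarray(keep_amb, bool),
        unresolvable=pd.DataFrame(bad_rows),
    )
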