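"""Synthetic study generator: Wright-Fisher cohorts, eQTL models, scores.

Generates dated genotype cohorts sampled from Wright-Fisher allele-frequency
trajectories with (optional) genic selection, sparse linear cis-eQTL weight
models with planted selected genes, and standard-normal per-SNP haplotype
selection scores shifted at truly selected sites. Every downstream scan is
testable against the ground truth this module records.

The defaults emulate the study design the scans assume: an effective
population size of 10^4, a ~4,500-year time transect (161 generations at 28
years/generation), 616 ancient plus 91 present-day diploid samples, per-SNP
imputation quality in [0.6, 1.0], and weight models with a median of ~12
SNPs per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneModel, GenotypeDataset, SampleTable, TrueArchitecture

DEFAULT_GENERATION_TIME = 28.0
DEFAULT_NE = 10_000


def default_schedule() -> list[tuple[float, int]]:
    """616 ancient samples over 4,500 years plus 91 present-day samples."""
    return [(4500.0, 154), (3000.0, 154), (1500.0, 154), (500.0, 154), (0.0, 91)]


@dataclass
class SimConfig:
    """Study-design parameters for cohort simulation.

    ``selection_map`` maps SNP id to a per-generation selection coefficient
    (time-constant). ``sample_schedule`` lists (date_years_bp, n_individuals)
    sampling points; dates must fall inside the simulated horizon
    ``n_generations * generation_time``.
    """

    effective_population_size: int = DEFAULT_NE
    generation_time: float = DEFAULT_GENERATION_TIME
    n_generations: int = math.ceil(4500 / DEFAULT_GENERATION_TIME)
    selection_map: dict[str, float] = field(default_factory=dict)
    initial_frequencies: dict[str, float] = field(default_factory=dict)
    sample_schedule: list[tuple[float, int]] = field(default_factory=default_schedule)
    imputation_quality_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0
    snp_spacing_bp: int = 20_000
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        if self.effective_population_size < 2:
            raise ValueError("Ne must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        for snp, p0 in self.initial_frequencies.items():
            if not 0.0 < p0 < 1.0:
                raise ValueError(f"initial frequency for {snp} not in (0,1)")
        lo, hi = self.imputation_quality_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("imputation quality range must lie within [0,1]")
        for date, _n in self.sample_schedule:
            if date < 0:
                raise ValueError("sample dates must be >= 0")

    @property
    def horizon_years(self) -> float:
        return self.n_generations * self.generation_time

    def generation_of_date(self, date_bp: float) -> int:
        """Forward generation index (0 = start of transect) for a date."""
        if date_bp > self.horizon_years + 1e-9:
            raise ValueError(
                f"date {date_bp} BP outside simulated horizon "
                f"({self.horizon_years:.0f} years)"
            )
        g = round((self.horizon_years - date_bp) / self.generation_time)
        return int(min(max(g, 0), self.n_generations))


def simulate_trajectory(
    p0: float, s: float, n_gen: int, ne: int, seed=None
) -> np.ndarray:
    """Wright-Fisher allele-frequency path of length ``n_gen + 1``.

    Each generation draws the next allele count from Binomial(2*Ne, p')
    where ``p' = p(1+s) / (p(1+s) + (1-p))`` is the deterministic genic
    (multiplicative) selection update. Frequencies 0 and 1 are absorbing.
    """
    if not np.isfinite(s):
        raise ValueError("selection coefficient must be finite")
    if n_gen < 0:
        raise ValueError("n_gen must be >= 0")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    path = np.empty(n_gen + 1)
    path[0] = p0
    p = p0
    two_ne = 2 * ne
    for g in range(1, n_gen + 1):
        if p in (0.0, 1.0):
            path[g:] = p
            break
        p_sel = p * (1 + s) / (p * (1 + s) + (1 - p))
        p = rng.binomial(two_ne, p_sel) / two_ne
        path[g] = p
    return path


def simulate_trajectories(
    p0: np.ndarray, s: np.ndarray, n_gen: int, ne: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised Wright-Fisher paths, shape ``(n_snps, n_gen + 1)``."""
    p0 = np.asarray(p0, float)
    s = np.asarray(s, float)
    if not np.all(np.isfinite(s)):
        raise ValueError("selection coefficients must be finite")
    paths = np.empty((p0.size, n_gen + 1))
    paths[:, 0] = p0
    p = p0.copy()
    two_ne = 2 * ne
    for g in range(1, n_gen + 1):
        p_sel = p * (1 + s) / (p * (1 + s) + (1 - p))
        free = (p > 0) & (p < 1)
        p = np.where(free, rng.binomial(two_ne, np.clip(p_sel, 0, 1)) / two_ne, p)
        paths[:, g] = p
    return paths


def _snp_table(snp_ids, config: SimConfig, quality: np.ndarray) -> pd.DataFrame:
    n = len(snp_ids)
    per_chrom = math.ceil(n / config.n_chromosomes)
    chroms = [str(1 + i // per_chrom) for i in range(n)]
    pos = [(i % per_chrom + 1) * config.snp_spacing_bp for i in range(n)]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "r2": quality,
        }
    )


def simulate_cohort(
    config: SimConfig, trajectories: dict[str, np.ndarray]
) -> tuple[GenotypeDataset, SampleTable]:
    """Sample dated diploid individuals from frequency trajectories.

    For an individual dated ``d`` BP, the genotype at each SNP is drawn
    Binomial(2, p) at the matching generation. Imputation noise then shrinks
    the dosage toward the population mean ``2p`` with weight ``1 - q``
    where ``q`` is the SNP's assigned quality, recorded as the SNP's R^2:
    ``dose = q * genotype + (1 - q) * 2p``. At q=1 dosages are exact
    genotypes; at q=0 every dosage collapses to 2p.
    """
    if not config.sample_schedule:
        raise ValueError("empty sample schedule")
    rng = np.random.default_rng(config.seed)
    snp_ids = list(trajectories)
    paths = np.vstack([trajectories[s] for s in snp_ids])  # (n_snps, n_gen+1)
    lo, hi = config.imputation_quality_range
    quality = rng.uniform(lo, hi, size=len(snp_ids))

    rows, dates, dosage_blocks = [], [], []
    idx = 0
    for date, n_ind in config.sample_schedule:
        gen = config.generation_of_date(date)
        p = paths[:, gen]  # (n_snps,)
        geno = rng.binomial(2, np.clip(p, 0, 1), size=(n_ind, p.size)).astype(float)
        dose = quality * geno + (1 - quality) * (2 * p)
        dosage_blocks.append(dose)
        for _ in range(n_ind):
            rows.append(f"ind_{idx}")
            dates.append(date)
            idx += 1
    dosages = np.vstack(dosage_blocks)
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": rows,
                "date_bp": dates,
                "cohort": ["modern" if d == 0 else "ancient" for d in dates],
            }
        )
    )
    dataset = GenotypeDataset(
        sample_ids=rows,
        snps=_snp_table(snp_ids, config, quality),
        dosages=dosages,
    )
    return dataset, samples


def simulate_gene_models(
    n_genes: int,
    snp_ids: list[str],
    snps_per_gene: int = 12,
    weight_scale: float = 0.3,
    selected_genes: dict[str, int] | None = None,
    selected_s: float = 0.02,
    seed=None,
) -> tuple[list[GeneModel], TrueArchitecture]:
    """Sparse weight models over the simulated SNP set, with planted selection.

    Each gene draws its model size k from a Poisson with mean
    ``snps_per_gene`` (clipped to >= 1; median ~12 at the default) and
    takes a contiguous block of k SNPs starting at a random position —
    mimicking the clustering of cis-eQTLs around the gene body — with
    weights from Normal(0, weight_scale). For each gene named in
    ``selected_genes`` (gene_id -> intended expression direction +1/-1),
    every member SNP is assigned a true selection coefficient of magnitude
    ``selected_s`` whose sign is ``sign(weight) * direction``, so that
    frequency shifts push predicted expression the intended way.

    Returns the models plus a :class:`TrueArchitecture` holding the per-SNP
    true s (to feed :class:`SimConfig.selection_map`) and the ground truth.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    selected_genes = dict(selected_genes or {})
    gene_ids = [f"gene_{i}" for i in range(n_genes)]
    unknown = set(selected_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"selected genes not among simulated genes: {unknown}")

    models: list[GeneModel] = []
    true_s: dict[str, float] = {}
    gene_weights: dict[str, pd.DataFrame] = {}
    snp_arr = np.asarray(snp_ids)
    for gid in gene_ids:
        k = max(1, int(rng.poisson(snps_per_gene)))
        k = min(k, len(snp_arr))
        start = int(rng.integers(0, len(snp_arr) - k + 1))
        members = snp_arr[start : start + k]
        weights = rng.normal(0.0, weight_scale, size=k)
        weights[weights == 0.0] = weight_scale  # zero-weight models are degenerate
        variants = pd.DataFrame(
            {
                "snp_id": members,
                "effect_allele": "G",
                "other_allele": "A",
                "weight": weights,
            }
        )
        if gid in selected_genes:
            if np.all(weights == 0):
                raise ValueError(f"selected gene {gid} has a zero-weight model")
            direction = selected_genes[gid]
            for snp, w in zip(members, weights):
                true_s[snp] = float(np.sign(w) * direction * selected_s)
        models.append(
            GeneModel(
                gene_id=gid,
                tissue="SimTissue",
                training_r2=float(rng.uniform(0.05, 0.6)),
                variants=variants,
            )
        )
        gene_weights[gid] = variants
    arch = TrueArchitecture(
        gene_weights=gene_weights, selected_genes=selected_genes, true_s=true_s
    )
    return models, arch


def simulate_classic_scores(
    true_s: dict[str, float],
    snp_ids: list[str],
    shift_per_unit_s: float = 100.0,
    mask_fraction: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Per-SNP normalised selection scores (SDS/iHS stand-in).

    Scores are Normal(shift_per_unit_s * s, 1): standard normal at neutral
    SNPs, mean-shifted at selected SNPs. The score's polarity refers to the
    alt allele (recorded in the ``allele`` column). A ``mask_fraction`` of
    SNPs is dropped uniformly at random to mimic incomplete score coverage.
    """
    if not np.isfinite(shift_per_unit_s):
        raise ValueError("shift_per_unit_s must be finite")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s = np.array([true_s.get(snp, 0.0) for snp in snp_ids])
    scores = rng.normal(shift_per_unit_s * s, 1.0)
    table = pd.DataFrame({"snp_id": snp_ids, "allele": "G", "score": scores})
    if mask_fraction > 0:
        keep = rng.random(len(table)) >= mask_fraction
        table = table[keep].reset_index(drop=True)
    return table


def gene_coordinate_table(
    architecture: TrueArchitecture, dataset
) -> pd.DataFrame:
    """Gene intervals spanned by each gene's model SNPs (gene_id/chrom/start/end)."""
    snps = dataset.snps.set_index("snp_id")
    rows = []
    for gid, variants in architecture.gene_weights.items():
        member = snps.loc[[s for s in variants["snp_id"] if s in snps.index]]
        if len(member) == 0:
            continue
        chrom = member["chrom"].mode().iloc[0]
        on_chrom = member[member["chrom"] == chrom]
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": int(on_chrom["pos"].min()),
                "end": int(on_chrom["pos"].max()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """Bundle of one fully simulated study with its ground truth."""

    config: SimConfig
    dataset: GenotypeDataset
    samples: SampleTable
    models: list[GeneModel]
    architecture: TrueArchitecture
    scores: pd.DataFrame
    trajectories: dict[str, np.ndarray]


def simulate_study(
    n_snps: int = 2000,
    n_genes: int = 150,
    selected_genes: dict[str, int] | None = None,
    config: SimConfig | None = None,
    snps_per_gene: int = 12,
    weight_scale: float = 0.3,
    selected_s: float = 0.02,
    score_shift: float = 100.0,
    score_mask_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a complete study: models, trajectories, cohort, scores.

    Gene models are drawn first so selected genes can plant selection
    coefficients on their member SNPs; the Wright-Fisher trajectories then
    honour those coefficients; finally the dated cohort and the classic
    score table are sampled.
    """
    rng = np.random.default_rng(seed)
    snp_ids = [f"snp_{i}" for i in range(n_snps)]
    models, arch = simulate_gene_models(
        n_genes,
        snp_ids,
        snps_per_gene=snps_per_gene,
        weight_scale=weight_scale,
        selected_genes=selected_genes,
        selected_s=selected_s,
        seed=rng,
    )
    if config is None:
        config = SimConfig(seed=int(rng.integers(2**31)))
    config.selection_map = dict(arch.true_s)
    p0 = rng.uniform(0.1, 0.9, size=n_snps)
    config.initial_frequencies = dict(zip(snp_ids, p0))
    s_vec = np.array([arch.true_s.get(snp, 0.0) for snp in snp_ids])
    paths = simulate_trajectories(
        p0, s_vec, config.n_generations, config.effective_population_size, rng
    )
    trajectories = {snp: paths[i] for i, snp in enumerate(snp_ids)}
    dataset, samples = simulate_cohort(config, trajectories)
    scores = simulate_classic_scores(
        arch.true_s,
        snp_ids,
        shift_per_unit_s=score_shift,
        mask_fraction=score_mask_fraction,
        seed=rng,
    )
    return SimulatedStudy(
        config=config,
        dataset=dataset,
        samples=samples,
        models=models,
        architecture=arch,
        scores=scores,
        trajectories=trajectories,
    )
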