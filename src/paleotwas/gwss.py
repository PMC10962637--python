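"""Genome-wide SNP selection scan from allele-frequency time series.

Sites passing frequency/missingness filters get a per-SNP selection
coefficient estimated from binned allele counts by maximising a binomial
likelihood along a deterministic logistic trajectory,
``logit p(g) = a + s*g`` with g in generations (a pluggable stand-in for
richer time-varying estimators; externally computed s-hat tables can be
supplied instead). Root-mean-square coefficients are averaged in 20-SNP
windows sliding by 10, a gamma distribution fitted to the window statistics
yields upper-tail p-values, and significant windows are merged into peaks
(<5 Mb apart, 0.1 Mb buffers) annotated with gene-overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import GenotypeDataset, SampleTable
from .twss import fdr_call

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING = 10**4.5


# ------------------------------------------------------------- site filters


def filter_sites(
    dataset: GenotypeDataset,
    samples: SampleTable,
    maf_min: float = 0.1,
    max_missingness: float = 0.9,
) -> np.ndarray:
    """Boolean mask of retained SNPs.

    Drops SNPs with overall MAF strictly below ``maf_min`` (0.10 exactly is
    retained), with missingness above ``max_missingness``, and monomorphic
    in the ancient samples (MAF = 0 in the ancient data).
    """
    freq = dataset.alt_frequency()
    maf = np.minimum(freq, 1 - freq)
    miss = dataset.missingness()
    ancient = samples.is_ancient(dataset.sample_ids)
    with np.errstate(invalid="ignore"):
        anc_freq = np.nanmean(dataset.dosages[ancient], axis=0) / 2.0
    anc_maf = np.minimum(anc_freq, 1 - anc_freq)
    keep = (maf >= maf_min) & (miss <= max_missingness) & (anc_maf > 0)
    keep &= np.isfinite(freq) & np.isfinite(anc_freq)
    return keep


# ------------------------------------------------------- selection estimates


@dataclass
class SnpSelectionEstimate:
    """Per-SNP selection-coefficient estimate.

    ``s_hat`` is a scalar (time-constant mode) or a per-block vector;
    ``rms_s`` its root mean square (= |s_hat| in the scalar case).
    ``converged`` is False for monomorphic/undefined sites, which are
    excluded from the window scan.
    """

    snp_key: str
    s_hat: float | np.ndarray
    rms_s: float
    converged: bool
    intercept: float = np.nan


def binned_allele_counts(
    dataset: GenotypeDataset,
    samples: SampleTable,
    bin_years: float = 100.0,
    generation_time: float = 28.0,
    dosage_counts: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(derived, total, generation) count arrays for every SNP.

    Samples are binned by date (one bin per ``bin_years``); derived counts
    are alt-allele counts from rounded hard calls (or dosage expectations
    when ``dosage_counts``); generation times are forward time in
    generations at bin midpoints (0 at present, negative in the past).
    """
    dates = samples.dates_for(dataset.sample_ids)
    bin_idx = np.floor(dates / bin_years).astype(int)
    bins = np.unique(bin_idx)
    D = np.zeros((dataset.n_snps, bins.size))
    N = np.zeros_like(D)
    g = np.empty(bins.size)
    doses = dataset.dosages if dosage_counts else np.round(dataset.dosages)
    for k, b in enumerate(bins):
        rows = bin_idx == b
        block = doses[rows]
        present = ~np.isnan(block)
        D[:, k] = np.nansum(block, axis=0)
        N[:, k] = 2 * present.sum(axis=0)
        g[k] = -(b + 0.5) * bin_years / generation_time
    order = np.argsort(g)
    return D[:, order], N[:, order], g[order]


def _scalar_mle(D: np.ndarray, N: np.ndarray, g: np.ndarray, max_iter: int = 60):
    """Vectorised 2-parameter Newton solver for logit p(g) = a + s*g.

    Returns (a, s, converged) arrays over SNPs. Damped Newton on the exact
    binomial negative log-likelihood; gradient/Hessian are closed-form.
    """
    n_snps = D.shape[0]
    gc = g - g.mean()
    tot_d, tot_n = D.sum(axis=1), N.sum(axis=1)
    defined = (tot_d > 0) & (tot_d < tot_n) & ((N > 0).sum(axis=1) >= 2)
    p_bar = np.clip(np.where(tot_n > 0, tot_d / np.maximum(tot_n, 1), 0.5), 1e-6, 1 - 1e-6)
    a = special.logit(p_bar)
    s = np.zeros(n_snps)

    def nll(a_, s_):
        eta = a_[:, None] + s_[:, None] * gc[None, :]
        # -sum d*eta - n*log(1-p);  log(1-p) = -log(1+exp(eta))
        return -(D * eta).sum(axis=1) + (N * np.logaddexp(0.0, eta)).sum(axis=1)

    cur = nll(a, s)
    converged = np.zeros(n_snps, bool)
    for _ in range(max_iter):
        eta = a[:, None] + s[:, None] * gc[None, :]
        p = special.expit(eta)
        resid = N * p - D
        ga = resid.sum(axis=1)
        gs = (resid * gc).sum(axis=1)
        w = N * p * (1 - p)
        haa = w.sum(axis=1)
        has = (w * gc).sum(axis=1)
        hss = (w * gc * gc).sum(axis=1)
        det = haa * hss - has**2
        ok = defined & (det > 1e-12)
        da = np.where(ok, (hss * ga - has * gs) / np.where(det > 0, det, 1.0), 0.0)
        ds = np.where(ok, (haa * gs - has * ga) / np.where(det > 0, det, 1.0), 0.0)
        step = np.ones(n_snps)
        for _half in range(30):
            new = nll(a - step * da, s - step * ds)
            worse = ok & (new > cur + 1e-12)
            if not worse.any():
                break
            step = np.where(worse, step / 2, step)
        a = a - step * da
        s = s - step * ds
        cur = nll(a, s)
        grad_norm = np.abs(ga) + np.abs(gs)
        converged = defined & (grad_norm < 1e-6 * np.maximum(tot_n, 1.0))
        if converged[defined].all():
            break
    # un-center: logit p(g) = (a - s*mean(g)) + s*g
    return a - s * g.mean(), s, converged & defined


def estimate_selection(
    derived: np.ndarray,
    total: np.ndarray,
    generations: np.ndarray,
    mode: str = "scalar",
    smoothing: float = DEFAULT_SMOOTHING,
    n_blocks: int = 5,
    snp_key: str = "",
) -> SnpSelectionEstimate:
    """Selection coefficient for one SNP from binned counts.

    Scalar mode maximises the binomial likelihood of the counts under
    ``logit p(g) = a + s*g``, starting from s = 0. Blocks mode makes s
    piecewise-constant over ``n_blocks`` equal spans of the time range and
    adds a smoothness penalty ``smoothing * sum (s_{b+1}-s_b)^2`` to the
    negative log-likelihood; as smoothing grows it collapses to the scalar
    fit. Monomorphic series are flagged unconverged (estimate undefined).
    """
    d = np.asarray(derived, float)
    n = np.asarray(total, float)
    g = np.asarray(generations, float)
    if (n > 0).sum() < 2:
        raise ValueError("need >= 2 bins with nonzero totals")
    if mode == "scalar":
        a, s, conv = _scalar_mle(d[None, :], n[None, :], g)
        return SnpSelectionEstimate(
            snp_key=snp_key,
            s_hat=float(s[0]),
            rms_s=abs(float(s[0])),
            converged=bool(conv[0]),
            intercept=float(a[0]),
        )
    if mode != "blocks":
        raise ValueError(f"unknown mode {mode!r}")
    if d.sum() == 0 or d.sum() == n.sum():
        return SnpSelectionEstimate(snp_key, np.zeros(n_blocks), 0.0, False)
    # block b covers an equal span of [g.min(), g.max()]; the cumulative
    # integral of s(g) from g.min() to g_j enters the logit.
    edges = np.linspace(g.min(), g.max(), n_blocks + 1)
    overlap = np.empty((g.size, n_blocks))
    for b in range(n_blocks):
        overlap[:, b] = np.clip(np.minimum(g, edges[b + 1]) - edges[b], 0.0, None)

    def objective(theta):
        a, sb = theta[0], theta[1:]
        eta = a + overlap @ sb
        val = -(d * eta).sum() + (n * np.logaddexp(0.0, eta)).sum()
        val += smoothing * np.sum(np.diff(sb) ** 2)
        p = special.expit(eta)
        grad_eta = n * p - d
        grad = np.empty(n_blocks + 1)
        grad[0] = grad_eta.sum()
        grad[1:] = overlap.T @ grad_eta
        pen = np.zeros(n_blocks)
        dsb = np.diff(sb)
        pen[:-1] -= 2 * smoothing * dsb
        pen[1:] += 2 * smoothing * dsb
        grad[1:] += pen
        return val, grad

    p_bar = np.clip(d.sum() / n.sum(), 1e-6, 1 - 1e-6)
    x0 = np.concatenate([[special.logit(p_bar)], np.zeros(n_blocks)])
    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B")
    sb = res.x[1:]
    return SnpSelectionEstimate(
        snp_key=snp_key,
        s_hat=sb,
        rms_s=float(np.sqrt(np.mean(sb**2))),
        converged=bool(res.success),
        intercept=float(res.x[0]),
    )


def estimate_selection_table(
    dataset: GenotypeDataset,
    samples: SampleTable,
    keep: np.ndarray | None = None,
    bin_years: float = 100.0,
    generation_time: float = 28.0,
    dosage_counts: bool = False,
) -> pd.DataFrame:
    """Scalar selection estimates for all retained SNPs (vectorised)."""
    D, N, g = binned_allele_counts(
        dataset, samples, bin_years, generation_time, dosage_counts
    )
    if keep is None:
        keep = np.ones(dataset.n_snps, bool)
    a, s, conv = _scalar_mle(D[keep], N[keep], g)
    snps = dataset.snps[keep]
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "s_hat": s,
            "rms_s": np.abs(s),
            "converged": conv,
        }
    )


# ------------------------------------------------------------- window scan


def window_scan(
    estimates: pd.DataFrame, window: int = 20, step: int = 10
) -> pd.DataFrame:
    """Sliding-window mean RMS selection coefficient per chromosome.

    ``estimates`` must be sorted by (chrom, pos) and carry chrom, pos,
    rms_s, converged. Windows of ``window`` consecutive converged SNPs
    advance by ``step``; a final partial window (>= step SNPs) is emitted,
    flagged, only when it covers SNPs beyond the last full window.
    Chromosomes with fewer than ``step`` usable SNPs are skipped.
    """
    est = estimates[estimates["converged"]].reset_index(drop=True)
    rows = []
    for chrom, grp in est.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"estimates not sorted by position on chrom {chrom}")
        pos = grp["pos"].to_numpy()
        rms = grp["rms_s"].to_numpy()
        n = len(grp)
        if n < step:
            logger.warning("chrom %s: only %d usable SNPs; skipped", chrom, n)
            continue
        covered_to = -1
        for start in range(0, n, step):
            stop = min(start + window, n)
            size = stop - start
            if size < window:
                if size >= step and stop - 1 > covered_to:
                    rows.append(
                        dict(
                            chrom=chrom,
                            start=int(pos[start]),
                            end=int(pos[stop - 1]),
                            n_snps=size,
                            stat=float(rms[start:stop].mean()),
                            partial=True,
                        )
                    )
                break
            rows.append(
                dict(
                    chrom=chrom,
                    start=int(pos[start]),
                    end=int(pos[stop - 1]),
                    n_snps=size,
                    stat=float(rms[start:stop].mean()),
                    partial=False,
                )
            )
            covered_to = stop - 1
            if stop == n:
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "stat", "partial"])


def gamma_pvalues(windows: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Fit a gamma distribution to all window statistics; upper-tail p's.

    Maximum-likelihood fit with location fixed at zero; zero statistics are
    replaced by half the smallest positive value (logged) before fitting.
    Falls back to method-of-moments if the ML fit fails.
    """
    if len(windows) < 50:
        raise ValueError("gamma fit needs >= 50 windows")
    x = windows["stat"].to_numpy(float).copy()
    if (x <= 0).any():
        pos_min = x[x > 0].min()
        logger.info("replacing %d zero window statistics by %g", (x <= 0).sum(), pos_min / 2)
        x[x <= 0] = pos_min / 2
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise RuntimeError("non-finite gamma fit")
    except Exception:
        logger.warning("gamma MLE failed; falling back to method of moments")
        m, v = x.mean(), x.var()
        shape, scale = m * m / v, v / m
    out = windows.copy()
    out["p"] = stats.gamma.sf(x, shape, scale=scale)
    return out, (float(shape), float(scale))


# ------------------------------------------------------------ peak merging


@dataclass
class SelectionPeak:
    """A merged, buffered run of significant windows with gene overlaps."""

    chrom: str
    start: int
    end: int
    n_windows: int
    min_p: float
    n_all_genes: int = 0
    n_modeled_genes: int = 0
    n_significant_genes: int = 0
    genes: list[str] = field(default_factory=list)


def merge_peaks(
    windows: pd.DataFrame,
    p_threshold: float | None = None,
    gap_bp: float = 5_000_000,
    buffer_bp: float = 100_000,
    gene_table: pd.DataFrame | None = None,
    modeled_genes=None,
    significant_genes=None,
) -> list[SelectionPeak]:
    """Merge significant windows into buffered peaks and count gene overlap.

    Windows with p below the threshold (default: the BH-implied threshold
    at q = 0.05 over all window p's) are merged when the gap between
    consecutive windows on a chromosome is under ``gap_bp``; each merged
    interval then grows by ``buffer_bp`` on both sides (floored at 1).
    ``gene_table`` (gene_id, chrom, start, end) enables the per-peak counts
    of all, modeled, and scan-significant genes.
    """
    if p_threshold is None:
        _, reject, p_threshold = fdr_call(windows["p"].to_numpy(), q=0.05)
        if not reject.any():
            return []
    sig = windows[windows["p"] <= p_threshold].sort_values(["chrom", "start"])
    peaks: list[SelectionPeak] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cur_start = cur_end = None
        members = 0
        min_p = np.inf
        for _, w in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members, min_p = w.start, w.end, 1, w.p
            elif w.start - cur_end < gap_bp:
                cur_end = max(cur_end, w.end)
                members += 1
                min_p = min(min_p, w.p)
            else:
                peaks.append(SelectionPeak(chrom, int(cur_start), int(cur_end), members, float(min_p)))
                cur_start, cur_end, members, min_p = w.start, w.end, 1, w.p
        if cur_start is not None:
            peaks.append(SelectionPeak(chrom, int(cur_start), int(cur_end), members, float(min_p)))
    for pk in peaks:
        pk.start = int(max(1, pk.start - buffer_bp))
        pk.end = int(pk.end + buffer_bp)
    if gene_table is not None:
        modeled = set(modeled_genes or [])
        signif = set(significant_genes or [])
        for pk in peaks:
            sub = gene_table[
                (gene_table["chrom"].astype(str) == str(pk.chrom))
                & (gene_table["start"] <= pk.end)
                & (gene_table["end"] >= pk.start)
            ]
            pk.genes = list(sub["gene_id"])
            pk.n_all_genes = len(sub)
            pk.n_modeled_genes = sum(g in modeled for g in pk.genes)
            pk.n_significant_genes = sum(g in signif for g in pk.genes)
    return peaks


def peaks_to_bed(peaks: list[SelectionPeak], path: str) -> None:
    """Write peaks as BED (0-based half-open, from 1-based inclusive)."""
    with open(path, "w") as fh:
        for pk in peaks:
            fh.write(f"{pk.chrom}\t{pk.start - 1}\t{pk.end}\tpeak\t{pk.min_p:.3g}\n")


def peaks_to_table(peaks: list[SelectionPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": pk.chrom,
                "gwss_start": pk.start,
                "gwss_end": pk.end,
                "n_windows": pk.n_windows,
                "min_p": pk.min_p,
                "n_all_genes": pk.n_all_genes,
                "n_modeled_genes": pk.n_modeled_genes,
                "n_significant_genes": pk.n_significant_genes,
            }
            for pk in peaks
        ]
    )


# ------------------------------------------------------------ model facade


@dataclass
class GwssResults:
    """Fitted genome-wide scan: per-SNP estimates, windows, gamma null."""

    model: "GenomeWideScan"
    estimates: pd.DataFrame
    windows: pd.DataFrame
    gamma_params: tuple[float, float]

    def peaks(
        self,
        p_threshold: float | None = None,
        gene_table: pd.DataFrame | None = None,
        modeled_genes=None,
        significant_genes=None,
        gap_bp: float = 5_000_000,
        buffer_bp: float = 100_000,
    ) -> list[SelectionPeak]:
        return merge_peaks(
            self.windows,
            p_threshold=p_threshold,
            gap_bp=gap_bp,
            buffer_bp=buffer_bp,
            gene_table=gene_table,
            modeled_genes=modeled_genes,
            significant_genes=significant_genes,
        )

    def summary(self) -> str:
        shape, scale = self.gamma_params
        lines = [
            "Genome-wide selection scan",
            "=" * 48,
            f"SNPs retained:     {len(self.estimates)}",
            f"windows:           {len(self.windows)}",
            f"gamma shape/scale: {shape:.3f} / {scale:.3g}",
            f"min window p:      {self.windows['p'].min():.3g}",
        ]
        top = self.windows.nsmallest(min(5, len(self.windows)), "p")
        for _, w in top.iterrows():
            lines.append(f"  {w.chrom}:{w.start}-{w.end}  stat={w.stat:.4g}  p={w.p:.3g}")
        return "\n".join(lines)

    def plot_windows(self, ax=None, p_line: float | None = 1e-4):
        """Manhattan-style plot of window p-values along the genome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            mid = (grp["start"] + grp["end"]) / 2
            ax.plot(offset + mid, -np.log10(grp["p"]), ".", ms=3, label=str(chrom))
            offset += grp["end"].max()
        if p_line is not None:
            ax.axhline(-np.log10(p_line), color="b", lw=0.8)
        ax.set_xlabel("genomic position")
        ax.set_ylabel("-log10 window p")
        return ax

    def to_tsv(self, path: str) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


class GenomeWideScan:
    """SNP-level selection scan over a dated genotype cohort.

    Filters sites (MAF >= 0.1, missingness <= 90%, polymorphic in the
    ancient samples), estimates a per-generation selection coefficient per
    SNP, averages |s-hat| in sliding windows and fits the gamma null.
    Supply ``external_estimates`` (snp_id, s_hat or rms_s) to plug in
    selection coefficients computed elsewhere.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        samples: SampleTable,
        generation_time: float = 28.0,
        bin_years: float = 100.0,
        dosage_counts: bool = False,
    ):
        self.dataset = dataset.sorted_by_position()
        self.samples = samples
        self.generation_time = generation_time
        self.bin_years = bin_years
        self.dosage_counts = dosage_counts

    def fit(
        self,
        window: int = 20,
        step: int = 10,
        maf_min: float = 0.1,
        external_estimates: pd.DataFrame | None = None,
    ) -> GwssResults:
        keep = filter_sites(self.dataset, self.samples, maf_min=maf_min)
        if external_estimates is not None:
            est = self.dataset.snps[keep][["snp_id", "chrom", "pos"]].merge(
                external_estimates, on="snp_id", how="inner"
            )
            if "rms_s" not in est.columns:
                est["rms_s"] = est["s_hat"].abs()
            if "converged" not in est.columns:
                est["converged"] = True
        else:
            est = estimate_selection_table(
                self.dataset,
                self.samples,
                keep=keep,
                bin_years=self.bin_years,
                generation_time=self.generation_time,
                dosage_counts=self.dosage_counts,
            )
        windows = window_scan(est, window=window, step=step)
        windows, params = gamma_pvalues(windows)
        return GwssResults(model=self, estimates=est, windows=windows, gamma_params=params)
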