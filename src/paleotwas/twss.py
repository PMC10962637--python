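"""Transcriptome-wide selection scan: expression-on-time regression.

For each gene, predicted normalized expression is regressed by OLS on
forward time t = -date_bp (so positive slopes mean expression rising toward
the present). The Wald chi-square (beta/se)^2 is corrected by genomic
control -- dividing by the inflation factor lambda, the ratio of the median
observed chi-square to the median of a 1-df chi-square (0.4549...) -- to
absorb the inflation genetic drift induces in every gene's temporal trend.
Significance is called by Benjamini-Hochberg FDR, and a date-randomization
null provides the calibration reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SampleTable

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...
_P_FLOOR = 1e-300  # keeps p in (0, 1] for numerically exact fits


@dataclass
class GenomicControl:
    lambda_gc: float
    n_tests: int


def _times_from(samples: SampleTable, sample_ids, time_convention: str) -> np.ndarray:
    dates = samples.dates_for(sample_ids)
    if time_convention == "forward":
        return -dates
    if time_convention == "before-present":
        return dates
    raise ValueError(f"unknown time convention {time_convention!r}")


def mass_ols_on_time(Y: np.ndarray, t: np.ndarray) -> pd.DataFrame:
    """Vectorised per-row OLS of expression on time with intercept.

    ``Y`` is (n_genes, n_samples); returns beta, se, chi2_raw, p_raw per
    row. chi2_raw is the squared Wald statistic (beta/se)^2 against a 1-df
    chi-square. Rows with constant expression get beta 0, p 1.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    t = np.asarray(t, float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise ValueError("constant dates: slope not identifiable")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    beta = (Yc @ tc) / sxx
    rss = np.maximum((Yc * Yc).sum(axis=1) - beta**2 * sxx, 0.0)
    sigma2 = rss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        chi2 = np.where(se > 0, (beta / se) ** 2, np.where(beta == 0, 0.0, np.inf))
    constant = (Yc == Yc[:, :1]).all(axis=1) & (Yc[:, 0] == 0)
    beta = np.where(constant, 0.0, beta)
    chi2 = np.where(constant, 0.0, chi2)
    chi2 = np.minimum(chi2, stats.chi2.isf(_P_FLOOR, 1))
    p = np.maximum(stats.chi2.sf(chi2, 1), _P_FLOOR)
    return pd.DataFrame({"beta": beta, "se": se, "chi2_raw": chi2, "p_raw": p})


def regress_on_time(
    expr: np.ndarray,
    samples: SampleTable,
    sample_ids=None,
    time_convention: str = "forward",
) -> tuple[float, float, float, float]:
    """OLS of one gene's expression on forward time; (beta, se, chi2, p).

    beta is the change in predicted expression per year of forward time;
    positive means increasing toward the present.
    """
    expr = np.asarray(expr, float)
    if sample_ids is None:
        sample_ids = samples.table["sample_id"]
    t = _times_from(samples, sample_ids, time_convention)
    if np.unique(t).size < 2:
        raise ValueError("constant dates")
    row = mass_ols_on_time(expr[None, :], t).iloc[0]
    return float(row.beta), float(row.se), float(row.chi2_raw), float(row.p_raw)


def genomic_control(chi2_raw: np.ndarray) -> tuple[GenomicControl, np.ndarray]:
    """Inflation factor and corrected p-values.

    lambda = median(chi2) / median(chi2_1df), clamped at 1 (no deflation);
    corrected p from chi2/lambda on the 1-df chi-square upper tail.
    """
    chi2_raw = np.asarray(chi2_raw, float)
    if chi2_raw.size < 2:
        raise ValueError("genomic control needs >= 2 tests")
    lam = float(np.median(chi2_raw) / CHI2_1_MEDIAN)
    lam = max(lam, 1.0)
    p_gc = np.maximum(stats.chi2.sf(chi2_raw / lam, 1), _P_FLOOR)
    return GenomicControl(lambda_gc=lam, n_tests=chi2_raw.size), p_gc


def fdr_call(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini-Hochberg step-up: (q_values, significant mask, implied p threshold).

    The implied threshold is the largest p declared significant (NaN when
    nothing is), the analogue of a scan's FDR p cut line.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    p_values = np.asarray(p_values, float)
    reject, q_values, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    threshold = float(p_values[reject].max()) if reject.any() else float("nan")
    return q_values, reject, threshold


@dataclass
class TwssResults:
    """Fitted transcriptome-wide scan.

    ``table`` holds one row per gene: beta (expression-SD per year of
    forward time), se, chi2_raw, p_raw, chi2_gc, p_gc, q_value,
    significant. ``lambda_gc`` is the genomic-control inflation factor and
    ``implied_threshold`` the largest GC p called significant.
    """

    model: "TranscriptomeWideScan"
    table: pd.DataFrame
    lambda_gc: float
    q: float
    implied_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self) -> str:
        t = self.table
        lines = [
            "Transcriptome-wide selection scan",
            "=" * 48,
            f"genes tested:        {len(t)}",
            f"samples:             {len(self.model.sample_ids)}",
            f"lambda_GC:           {self.lambda_gc:.3f}",
            f"FDR level q:         {self.q:g}",
            f"implied p threshold: {self.implied_threshold:.3g}",
            f"significant genes:   {int(t['significant'].sum())}",
        ]
        top = t.nsmallest(min(10, len(t)), "p_gc")
        lines.append("-" * 48)
        lines.append(f"{'gene':<16}{'beta':>12}{'p_gc':>12}{'q':>9}")
        for gid, row in top.iterrows():
            lines.append(
                f"{gid:<16}{row.beta:>12.3e}{row.p_gc:>12.3e}{row.q_value:>9.3f}"
            )
        return "\n".join(lines)

    def randomized_null(self, n_perm: int, seed=None) -> pd.DataFrame:
        return self.model.randomized_date_null(n_perm, seed=seed)

    def qq_data(self) -> pd.DataFrame:
        """Observed vs expected -log10 p for QQ plotting."""
        p = np.sort(self.table["p_gc"].to_numpy())
        exp = (np.arange(1, p.size + 1) - 0.5) / p.size
        return pd.DataFrame(
            {"expected_nlog10": -np.log10(exp), "observed_nlog10": -np.log10(p)}
        )

    def plot_qq(self, null_p: np.ndarray | None = None, ax=None):
        """QQ plot of corrected p-values, optionally with a permutation null."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qq = self.qq_data()
        ax.plot(qq["expected_nlog10"], qq["observed_nlog10"], ".", label="observed")
        if null_p is not None:
            p = np.sort(np.asarray(null_p, float))
            exp = (np.arange(1, p.size + 1) - 0.5) / p.size
            ax.plot(-np.log10(exp), -np.log10(p), ".", color="gray", label="date-randomized")
        lim = qq["expected_nlog10"].max()
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.legend()
        return ax

    def to_tsv(self, path: str) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)

    def metadata(self) -> dict:
        return {
            "lambda_gc": self.lambda_gc,
            "n_tests": len(self.table),
            "q": self.q,
            "implied_p_threshold": self.implied_threshold,
            "n_significant": int(self.table["significant"].sum()),
            "time_convention": self.model.time_convention,
        }

    def write_metadata(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


class TranscriptomeWideScan:
    """Scan for temporal trends in predicted expression across dated samples.

    Parameters
    ----------
    expression
        Genes x samples DataFrame of predicted normalized expression
        (e.g. ``PredictedExpression.matrix``), already quality-filtered.
    samples
        Dated sample metadata covering every expression column.
    time_convention
        "forward" (default) regresses on t = -date_bp so positive beta
        means expression increasing toward the present; "before-present"
        uses t = date_bp.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        samples: SampleTable,
        time_convention: str = "forward",
    ):
        self.expression = expression
        self.samples = samples
        self.sample_ids = list(expression.columns)
        self.time_convention = time_convention
        self.t = _times_from(samples, self.sample_ids, time_convention)
        if np.unique(self.t).size < 2:
            raise ValueError("constant dates")

    def fit(self, q: float = 0.05, apply_gc: bool = True) -> TwssResults:
        res = mass_ols_on_time(self.expression.to_numpy(float), self.t)
        res.index = self.expression.index
        if apply_gc:
            gc, p_gc = genomic_control(res["chi2_raw"].to_numpy())
            lam = gc.lambda_gc
        else:
            lam, p_gc = 1.0, res["p_raw"].to_numpy()
        res["chi2_gc"] = res["chi2_raw"] / lam
        res["p_gc"] = p_gc
        q_values, reject, threshold = fdr_call(p_gc, q=q)
        res["q_value"] = q_values
        res["significant"] = reject
        return TwssResults(
            model=self, table=res, lambda_gc=lam, q=q, implied_threshold=threshold
        )

    def randomized_date_null(self, n_perm: int, seed=None) -> pd.DataFrame:
        """Pooled null p-values from date permutations.

        Each replicate applies one shared permutation of sample dates to
        all genes (preserving inter-gene correlation), re-runs the
        regression and genomic control, and pools the corrected p-values
        for QQ comparison.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        Y = self.expression.to_numpy(float)
        out = []
        for rep in range(n_perm):
            t_perm = rng.permutation(self.t)
            res = mass_ols_on_time(Y, t_perm)
            _, p_gc = genomic_control(res["chi2_raw"].to_numpy())
            out.append(pd.DataFrame({"replicate": rep, "p_gc": p_gc}))
        return pd.concat(out, ignore_index=True)
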