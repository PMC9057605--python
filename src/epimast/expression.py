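"""RNA-seq filtering, CPM normalization, and NB differential expression.

Genes are kept when they reach a count floor in a minimum number of
samples, normalized to counts per million, and tested gene-by-gene with a
negative-binomial likelihood-ratio test: the NB mean is mu * s_i with
library-size factors s_i as offsets and a fixed gene-wise dispersion
(method-of-moments estimate shrunk halfway toward the common median).
The LRT compares a single shared mean against condition-specific means;
p comes from chi-square with 1 df and is BH-adjusted. A gene is "up"
("down") when q <= q_max and log2FC clears the fold-change floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountsMatrix

__all__ = [
    "DETable",
    "DispersionEstimate",
    "ActivationGrouping",
    "filter_low_expression",
    "normalize_library_size",
    "estimate_dispersion",
    "test_de",
    "top_variance_zscore",
    "group_activation_genes",
]

log = logging.getLogger(__name__)

_POISSON_PHI = 1e-8  # below this the dispersion is treated as Poisson


@dataclass
class DispersionEstimate:
    """Gene-wise NB dispersions: raw MoM, common (median), mean-dispersion
    trend, and the shrunken values used for testing."""

    per_gene: pd.Series
    common: float
    shrunken: pd.Series
    shrink_weight: float
    trend: pd.Series | None = None


@dataclass
class DETable:
    """Per-gene log2FC (case vs control), p, BH q, and up/down/ns status."""

    table: pd.DataFrame  # columns: log2FC, p, q, status
    q_max: float
    min_abs_log2fc: float
    case: str = ""
    control: str = ""

    def n_status(self, status: str) -> int:
        return int((self.table["status"] == status).sum())


@dataclass
class ActivationGrouping:
    """Curated activation genes split into concordant (Group1) vs
    mutant-repressed (Group2) by their two case-vs-WT contrasts."""

    assignments: pd.DataFrame  # gene, log2FC_case, log2FC_other, group
    missing: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return self.assignments["group"].value_counts().to_dict()

    def percentages(self) -> dict[str, float]:
        n = len(self.assignments)
        return {g: 100.0 * c / n for g, c in self.counts().items()} if n else {}


def filter_low_expression(
    counts: CountsMatrix, min_count: int = 10, min_samples: int = 2
) -> CountsMatrix:
    """Keep genes with count >= min_count in at least min_samples samples."""
    keep = (counts.counts >= min_count).sum(axis=1) >= min_samples
    kept = int(keep.sum())
    total = len(keep)
    pct = 100.0 * kept / total if total else 0.0
    log.info("expression filter: kept %d of %d genes (%.1f%%)", kept, total, pct)
    if kept == 0:
        log.warning("no genes pass the expression filter")
    return CountsMatrix(counts.counts.loc[keep], dict(counts.conditions))


def normalize_library_size(counts: CountsMatrix) -> pd.DataFrame:
    """Counts per million: 1e6 * count / sample library size."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return 1e6 * counts.counts / totals


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=0).astype(float)
    return totals / totals.mean()


def estimate_dispersion(
    counts: CountsMatrix, shrink_weight: float | None = None
) -> DispersionEstimate:
    """Gene-wise NB dispersion from within-condition moments.

    Per condition with >= 2 samples, the raw estimate is the bias-corrected
    method of moments phi = max(0, (v - m) / (m^2 - v/n)) on library-size-
    scaled counts (subtracting v/n from the denominator keeps the moment
    equation unbiased at small n); gene-wise estimates are pooled across
    conditions weighted by degrees of freedom.

    The values used for testing are shrunk toward a mean-dispersion trend
    phi(mu) = a + b/mu fitted by iterative weighted least squares across
    genes; the shrink weight per gene comes from the ratio of the
    estimator's sampling variance to the between-gene spread around the
    trend (empirical Bayes), so a dataset with no real dispersion spread
    collapses onto the trend. Pass an explicit ``shrink_weight`` to use a
    fixed weight toward the common (median) value instead.
    """
    s = _size_factors(counts.counts)
    scaled = counts.counts / s
    conditions = sorted(set(counts.conditions.values()))
    num = pd.Series(0.0, index=counts.genes)
    dfs: list[int] = []
    for cond in conditions:
        samples = counts.samples_of(cond)
        if len(samples) < 2:
            continue
        sub = scaled[samples]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        # E[m^2] = mu^2 + sigma^2/n: subtract v/n from the denominator
        denom = (m**2 - v / len(samples)).clip(lower=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = ((v - m) / denom).clip(lower=0.0)
        phi = phi.where((m > 0) & (denom > 0), 0.0)
        w = len(samples) - 1
        num += w * phi
        dfs.append(w)
    if not dfs:
        raise ValueError("need at least one condition with >= 2 samples")
    per_gene = num / sum(dfs)
    finite = per_gene[np.isfinite(per_gene)]
    common = float(finite.median()) if len(finite) else 0.0

    if shrink_weight is not None:
        shrunken = ((1 - shrink_weight) * per_gene
                    + shrink_weight * common).clip(lower=0.0)
        return DispersionEstimate(per_gene, common, shrunken, shrink_weight)

    # mean-dispersion trend phi(mu) = a + b/mu by iterative WLS
    m_all = scaled.mean(axis=1)
    ok = (m_all > 0) & np.isfinite(per_gene)
    x = (1.0 / m_all[ok]).to_numpy()
    y = per_gene[ok].to_numpy()
    a, b = max(common, 1e-4), 0.0
    for _ in range(3):
        pred = np.maximum(a + b * x, 0.0)
        w = 1.0 / np.maximum((x + pred) ** 2, 1e-12)
        design = np.column_stack([np.ones_like(x), x])
        wx = design * w[:, None]
        coef = np.linalg.solve(wx.T @ design, wx.T @ y)
        a, b = float(coef[0]), float(coef[1])
    inv_m = 1.0 / m_all.clip(lower=1e-9)
    trend = pd.Series(np.maximum(a + b * inv_m, 0.0), index=counts.genes)

    # sampling variance of the pooled MoM estimator, then EB weights
    df_arr = np.array(dfs, dtype=float)
    v_g = sum(d**2 * 2.0 * (inv_m + trend) ** 2 / d for d in df_arr) / df_arr.sum() ** 2
    resid = per_gene - trend
    tau2 = max(0.0, float(resid[ok].var(ddof=1) - v_g[ok].mean()))
    if tau2 > 0:
        w_g = v_g / (v_g + tau2)
    else:
        w_g = pd.Series(1.0, index=counts.genes)
    shrunken = ((1 - w_g) * per_gene.fillna(trend) + w_g * trend).clip(lower=0.0)
    return DispersionEstimate(per_gene, common, shrunken,
                              float(np.mean(w_g)), trend)


def _nb_loglik_kernel(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, dropping terms independent of mu.

    y: (G, n) counts; mu: (G, n) fitted means; phi: (G,) dispersions.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    phi_safe = np.maximum(phi, _POISSON_PHI)[:, None]
    nb = term - (y + 1.0 / phi_safe) * np.log1p(phi_safe * mu)
    poisson = term - mu
    out = np.where((phi < _POISSON_PHI)[:, None], poisson, nb)
    return out.sum(axis=1)


def _fit_nb_mean(y: np.ndarray, s: np.ndarray, phi: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """MLE of the NB mean mu with means mu*s_i and fixed dispersion phi.

    Newton iteration on beta = log(mu), vectorized over genes; with equal
    size factors the initial value sum(y)/sum(s) is already the MLE.
    """
    totals = y.sum(axis=1)
    mu = np.maximum(totals / s.sum(), 1e-12)
    beta = np.log(mu)
    phi_col = phi[:, None]
    active = totals > 0
    for _ in range(max_iter):
        m = np.exp(beta)[:, None] * s[None, :]
        g = ((y - m) / (1.0 + phi_col * m)).sum(axis=1)
        h = (m * (1.0 + phi_col * y) / (1.0 + phi_col * m) ** 2).sum(axis=1)
        step = np.where(active & (h > 0), g / np.maximum(h, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(beta)
    return np.where(active, mu, 0.0)


def test_de(
    counts: CountsMatrix,
    case: str,
    control: str,
    dispersion: DispersionEstimate,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> DETable:
    """NB likelihood-ratio test of case vs control, gene by gene."""
    case_samples = counts.samples_of(case)
    ctrl_samples = counts.samples_of(control)
    if not case_samples or not ctrl_samples:
        raise ValueError(f"no samples for contrast {case} vs {control}")
    samples = case_samples + ctrl_samples
    s_all = _size_factors(counts.counts)
    y = counts.counts[samples].to_numpy(dtype=float)
    s = s_all[samples].to_numpy()
    is_case = np.array([samp in case_samples for samp in samples])

    nonzero = y.sum(axis=1) > 0
    genes = counts.genes[nonzero]
    if (~nonzero).any():
        log.info("excluding %d all-zero genes from testing", int((~nonzero).sum()))
    y = y[nonzero]
    phi = dispersion.shrunken.reindex(genes).fillna(dispersion.common).to_numpy()
    phi = np.maximum(phi, 0.0)

    # H0: one mean; H1: condition-specific means
    mu0 = _fit_nb_mean(y, s, phi)
    mu1_case = _fit_nb_mean(y[:, is_case], s[is_case], phi)
    mu1_ctrl = _fit_nb_mean(y[:, ~is_case], s[~is_case], phi)

    m0 = mu0[:, None] * s[None, :]
    m1 = np.empty_like(y)
    m1[:, is_case] = mu1_case[:, None] * s[None, is_case]
    m1[:, ~is_case] = mu1_ctrl[:, None] * s[None, ~is_case]

    ll0 = _nb_loglik_kernel(y, np.maximum(m0, 1e-300), phi)
    ll1 = _nb_loglik_kernel(y, np.maximum(m1, 1e-300), phi)
    lrt = np.maximum(0.0, 2.0 * (ll1 - ll0))
    p = stats.chi2.sf(lrt, df=1)

    adj_case = (y[:, is_case] / s[None, is_case]).mean(axis=1)
    adj_ctrl = (y[:, ~is_case] / s[None, ~is_case]).mean(axis=1)
    log2fc = np.log2((adj_case + 0.5) / (adj_ctrl + 0.5))

    q = multipletests(p, method="fdr_bh")[1]
    status = np.where(
        (q <= q_max) & (log2fc >= min_abs_log2fc), "up",
        np.where((q <= q_max) & (log2fc <= -min_abs_log2fc), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2FC": log2fc, "p": p, "q": q, "status": status}, index=genes
    )
    return DETable(table, q_max, min_abs_log2fc, case, control)


def top_variance_zscore(normalized: pd.DataFrame, n_top: int = 500) -> pd.DataFrame:
    """Z-score table of the n_top genes with the highest variance.

    Variance is computed on log2(CPM + 1) across samples; ties are broken
    by gene id order; each selected gene is standardized to mean 0, sd 1.
    """
    logged = np.log2(normalized + 1.0)
    var = logged.var(axis=1, ddof=1)
    if len(var) < n_top:
        log.warning("only %d genes available for n_top=%d; using all",
                    len(var), n_top)
        n_top = len(var)
    order = pd.DataFrame(
        {"_var": var.to_numpy(), "_gene": var.index.astype(str)}
    ).sort_values(["_var", "_gene"], ascending=[False, True])
    chosen = var.index[order.index[:n_top]]
    sub = logged.loc[chosen]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


def group_activation_genes(
    de_case_vs_wt: DETable,
    de_other_vs_wt: DETable,
    curated: list[str],
    concordance_margin: float = 1.0,
    repression_margin: float = 1.0,
) -> ActivationGrouping:
    """Split curated activation genes into Group1 / Group2.

    Group1 (concordant): log2FC signs agree in the two contrasts and the
    contrasts differ by less than the concordance margin. Group2
    (repressed in the mutant contrast): log2FC_other - log2FC_case >=
    repression margin with the case contrast below zero or below the other.
    Remaining curated genes are unclassified.
    """
    rows = []
    missing = []
    for gene in curated:
        if gene not in de_case_vs_wt.table.index or gene not in de_other_vs_wt.table.index:
            missing.append(gene)
            continue
        lfc_case = float(de_case_vs_wt.table.loc[gene, "log2FC"])
        lfc_other = float(de_other_vs_wt.table.loc[gene, "log2FC"])
        diff = lfc_other - lfc_case
        if diff >= repression_margin and (lfc_case < 0 or lfc_case < lfc_other):
            group = "Group2"
        elif np.sign(lfc_case) == np.sign(lfc_other) and abs(diff) < concordance_margin:
            group = "Group1"
        else:
            group = "unclassified"
        rows.append((gene, lfc_case, lfc_other, group))
    assignments = pd.DataFrame(
        rows, columns=["gene", "log2FC_case", "log2FC_other", "group"]
    )
    if missing:
        log.warning("curated genes absent from DE tables: %s", missing)
    return ActivationGrouping(assignments, missing)
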