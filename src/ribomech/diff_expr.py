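"""Count normalisation, filtering and negative-binomial differential testing.

Counts are modelled NB with variance mu + phi mu^2. The pairwise test is a
conditional exact test on library-equalised counts: samples are scaled to a
common library size (geometric mean, rounded), the two group sums are
conditioned on their total, and the two-sided p-value sums the conditional
probabilities of all outcomes no more likely than the observed one.

Differential translational efficiency is the likelihood-ratio test of the
assay x condition interaction in a per-gene NB log-linear model fitted to the
library-equalised mRNA and RPF counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)
_POISSON_PHI = 1e-8


@dataclass
class FilterReport:
    cpm_threshold: float
    min_samples: int
    n_input: int
    n_retained: int


def cpm_normalise(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million; every column sums to 1e6."""
    libs = library_sizes if library_sizes is not None else counts.sum(axis=0)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"zero/negative library size for samples: {bad}")
    return counts / libs * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_count: int = 5,
    min_samples: int | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop lowly expressed genes via a minimum-CPM rule.

    The CPM threshold corresponds to ``min_count`` raw counts in the smallest
    library; a gene is retained iff its CPM is >= the threshold (inclusive)
    in at least ``min_samples`` samples (default: size of the smallest
    condition group, or all samples if no design is given... the smaller of
    the two group sizes).
    """
    libs = counts.sum(axis=0)
    threshold = min_count / libs.min() * 1e6
    if min_samples is None:
        if design is not None:
            min_samples = int(design.loc[counts.columns, "condition"].value_counts().min())
        else:
            min_samples = counts.shape[1]
    cpm = cpm_normalise(counts, libs)
    keep = (cpm >= threshold).sum(axis=1) >= min_samples
    report = FilterReport(float(threshold), min_samples, counts.shape[0], int(keep.sum()))
    return counts.loc[keep], report


def _equalise_libraries(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the geometric-mean library size and round.

    Stand-in for edgeR's quantile adjustment: after scaling, samples are
    treated as sharing one effective library size.
    """
    libs = counts.sum(axis=0).astype(float)
    common = np.exp(np.log(libs).mean())
    return (counts * (common / libs)).round().astype(np.int64)


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    prior_df: float = 20.0,
) -> pd.Series:
    """Per-gene moment dispersion, shrunk toward the global mean estimate.

    On library-equalised counts, phi_raw = sum_c (var_c - mean_c) / sum_c
    mean_c^2 pooled over groups (floored at 0); the returned value is the
    prior-weighted average of phi_raw and the global mean of phi_raw, with
    the gene's residual degrees of freedom as its weight.
    """
    grp = groups.loc[counts.columns]
    sizes = grp.value_counts()
    if (sizes < 2).any():
        raise ValueError(
            "dispersion estimation needs >= 2 replicates per group; "
            "use a common-dispersion value instead"
        )
    eq = _equalise_libraries(counts)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    df = 0.0
    for g in sizes.index:
        sub = eq.loc[:, grp[grp == g].index].to_numpy(float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2
        df += sub.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.maximum(raw, 0.0)
    global_mean = float(raw.mean()) if len(raw) else 0.0
    shrunk = (prior_df * global_mean + df * raw) / (prior_df + df)
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def _conditional_pvalue(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """P(outcomes no more likely than observed | group sums total)."""
    s = np.arange(total + 1)
    if phi <= _POISSON_PHI:
        logp = stats.binom.logpmf(s, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)  # per-sample mean under the null
        p_null = 1.0 / (1.0 + phi * mu)
        logp = stats.nbinom.logpmf(s, n_a / phi, p_null) + stats.nbinom.logpmf(
            total - s, n_b / phi, p_null
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[s_a]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-10)].sum()))


def exact_test_nb(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    phi: pd.Series | float,
) -> pd.DataFrame:
    """Pairwise NB exact test, group B versus group A (log2fc = B over A).

    Both matrices are library-equalised jointly; the log2 fold change uses a
    0.5 pseudo-count on each group mean (testing never uses the pseudo-count).
    """
    if np.any(np.asarray(phi) < 0):
        raise ValueError("dispersion must be >= 0")
    joint = _equalise_libraries(pd.concat([counts_a, counts_b], axis=1))
    eq_a = joint.iloc[:, : counts_a.shape[1]].to_numpy()
    eq_b = joint.iloc[:, counts_a.shape[1] :].to_numpy()
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    phi_arr = (
        phi.loc[counts_a.index].to_numpy()
        if isinstance(phi, pd.Series)
        else np.full(len(counts_a), float(phi))
    )
    sums_a = eq_a.sum(axis=1)
    sums_b = eq_b.sum(axis=1)
    log2fc = np.log2((sums_b / n_b + 0.5) / (sums_a / n_a + 0.5))
    pvals = np.empty(len(sums_a))
    for i, (sa, sb, ph) in enumerate(zip(sums_a, sums_b, phi_arr)):
        pvals[i] = _conditional_pvalue(int(sa), int(sa + sb), n_a, n_b, ph)
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals}, index=counts_a.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant(log2fc, fdr, fdr_cut: float = 0.05, lfc_cut: float = 0.5) -> np.ndarray:
    return (np.asarray(fdr) < fdr_cut) & (np.abs(np.asarray(log2fc)) > lfc_cut)


def de_analysis(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    assay: str,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> pd.DataFrame:
    """mRNA- or RPF-level differential expression (treatment vs control)."""
    level = {"mrna": "mRNA", "rpf": "RPF"}[assay]
    sub = design[design["assay"] == assay]
    ctrl = sub.index[sub["condition"] == "control"]
    trt = sub.index[sub["condition"] == "treatment"]
    c = counts.loc[:, list(ctrl) + list(trt)]
    phi = estimate_dispersion(c, sub["condition"])
    res = exact_test_nb(counts[ctrl], counts[trt], phi)
    res["fdr"] = bh_adjust(res["pvalue"])
    res["significant"] = significant(res["log2fc"], res["fdr"], fdr_cut, lfc_cut)
    res.insert(0, "level", level)
    res.index.name = "gene_id"
    return res


# --- differential translational efficiency ---------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    if phi <= _POISSON_PHI:
        return float(stats.poisson.logpmf(y, mu).sum())
    size = 1.0 / phi
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def _irls_nb(y: np.ndarray, X: np.ndarray, phi: float, max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Fisher-scoring fit of an NB log-linear model (fixed phi)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.5))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            return beta, False
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new, -30, 30)), phi)
        if not np.isfinite(ll):
            return beta, False
        beta = beta_new
        if abs(ll - ll_old) < 1e-8 * (abs(ll_old) + 1):
            return beta, True
        ll_old = ll
    return beta, False


def test_differential_te(
    mrna_counts: pd.DataFrame,
    rpf_counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> pd.DataFrame:
    """TE interaction test on the shared gene universe.

    Per gene, an NB log-linear model with assay + condition +
    assay x condition terms is fitted to library-equalised counts; the TE
    log2 fold change is the interaction coefficient / ln 2 and the p-value
    comes from the likelihood-ratio test of that term. The full model is
    saturated on the four groups, so its MLE means are the group means.
    Non-converging genes are reported with p = 1 and converged = False. A
    ratio-based estimate (te_ratio) is emitted alongside the GLM estimate.
    """
    genes = mrna_counts.index.intersection(rpf_counts.index)
    mrna = mrna_counts.loc[genes]
    rpf = rpf_counts.loc[genes]
    md = design[design["assay"] == "mrna"].loc[mrna.columns]
    rd = design[design["assay"] == "rpf"].loc[rpf.columns]

    joint = _equalise_libraries(pd.concat([mrna, rpf], axis=1))
    eq_m = joint.iloc[:, : mrna.shape[1]]
    eq_r = joint.iloc[:, mrna.shape[1] :]

    group_cols = {
        ("mrna", "control"): md.index[md["condition"] == "control"],
        ("mrna", "treatment"): md.index[md["condition"] == "treatment"],
        ("rpf", "control"): rd.index[rd["condition"] == "control"],
        ("rpf", "treatment"): rd.index[rd["condition"] == "treatment"],
    }
    groups = pd.Series(
        {s: f"{a}_{c}" for (a, c), cols in group_cols.items() for s in cols}
    )
    phi = estimate_dispersion(joint, groups)

    is_rpf = np.concatenate([np.zeros(mrna.shape[1]), np.ones(rpf.shape[1])])
    is_trt = np.array(
        [1.0 if groups[s].endswith("treatment") else 0.0 for s in joint.columns]
    )
    X_red = np.column_stack([np.ones_like(is_rpf), is_rpf, is_trt])

    y_all = joint.to_numpy(float)
    masks = {k: joint.columns.isin(cols) for k, cols in group_cols.items()}

    lfc_glm = np.empty(len(genes))
    pvals = np.empty(len(genes))
    converged = np.ones(len(genes), dtype=bool)
    for i in range(len(genes)):
        y = y_all[i]
        ph = float(phi.iloc[i])
        means = {k: max(y[m].mean(), 1e-8) for k, m in masks.items()}
        interaction = (
            np.log(means[("rpf", "treatment")])
            - np.log(means[("rpf", "control")])
            - np.log(means[("mrna", "treatment")])
            + np.log(means[("mrna", "control")])
        )
        lfc_glm[i] = interaction / LOG2
        mu_full = np.empty_like(y)
        for k, m in masks.items():
            mu_full[m] = means[k]
        ll_full = _nb_loglik(y, mu_full, ph)
        beta, ok = _irls_nb(y, X_red, ph)
        if not ok:
            pvals[i] = 1.0
            converged[i] = False
            continue
        ll_red = _nb_loglik(y, np.exp(np.clip(X_red @ beta, -30, 30)), ph)
        lr = max(0.0, 2.0 * (ll_full - ll_red))
        pvals[i] = float(stats.chi2.sf(lr, 1))

    mean = lambda k: y_all[:, masks[k]].mean(axis=1)  # noqa: E731
    te_ratio = np.log2(
        (mean(("rpf", "treatment")) + 0.5) / (mean(("rpf", "control")) + 0.5)
    ) - np.log2((mean(("mrna", "treatment")) + 0.5) / (mean(("mrna", "control")) + 0.5))

    out = pd.DataFrame(
        {
            "level": "TE",
            "log2fc": lfc_glm,
            "te_ratio": te_ratio,
            "pvalue": pvals,
            "converged": converged,
        },
        index=genes,
    )
    out["fdr"] = bh_adjust(out["pvalue"])
    out["significant"] = significant(out["log2fc"], out["fdr"], fdr_cut, lfc_cut)
    out.index.name = "gene_id"
    return out
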