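"""Target-stratified distribution-shift analysis and mechanism calling.

For each gene stratum the fold-change distribution at each level (mRNA, RPF,
TE) is compared to the no-site background by the two-sided Kolmogorov-Smirnov
test; median shifts carry seeded percentile-bootstrap 95% CIs, and the
within-stratum Pearson correlation between mRNA and RPF fold changes is
reported. A simple decision rule converts the three median shifts into a
mechanism call (destabilisation- vs translation-dominant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diff_expr import bh_adjust

LEVELS = ("mRNA", "RPF", "TE")


@dataclass
class MechanismCall:
    stratum: str
    call: str  # destabilisation_dominant | translation_dominant | mixed | none
    median_mrna: float
    median_rpf: float
    median_te: float


def ks_shift_test(stratum_lfc, background_lfc) -> tuple[float, float]:
    """Two-sided two-sample KS test (exact for small groups).

    Exact enumeration-based p for min(n, m) <= 10, asymptotic otherwise.
    """
    x = np.asarray(stratum_lfc, dtype=float)
    y = np.asarray(background_lfc, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold-change vectors must be finite")
    method = "exact" if min(len(x), len(y)) <= 10 else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def median_with_ci(
    lfc, n_boot: int = 2000, seed: int = 0, confidence: float = 0.95
) -> tuple[float, float, float, bool]:
    """Median with a seeded percentile-bootstrap CI.

    Returns (median, lo, hi, degenerate); for n < 3 the CI collapses to the
    median and the degenerate flag is set.
    """
    v = np.asarray(lfc, dtype=float)
    med = float(np.median(v))
    if len(v) < 3:
        return med, med, med, True
    rng = np.random.default_rng(seed)
    boot = np.median(rng.choice(v, size=(n_boot, len(v)), replace=True), axis=1)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return med, float(lo), float(hi), False


def stratified_analysis(
    results: dict[str, pd.DataFrame],
    labels: pd.Series,
    background_label: str = "no_site",
    min_genes: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
    exclude_labels: tuple[str, ...] = ("excluded",),
) -> pd.DataFrame:
    """Compare every stratum to the no-site background at every level.

    ``results`` maps level name (mRNA/RPF/TE) to a per-gene table carrying a
    ``log2fc`` column; ``labels`` assigns each gene its stratum. Strata with
    fewer than ``min_genes`` genes are reported descriptively (n only,
    statistics suppressed as NaN, suppressed=True). BH-adjusted KS p-values
    are added within each level; raw p-values are kept.
    """
    rows = []
    strata = [
        l for l in labels.unique() if l != background_label and l not in exclude_labels
    ]
    for level, table in results.items():
        lab = labels.reindex(table.index)
        bg = table.loc[lab == background_label, "log2fc"].dropna()
        mrna_tab = results.get("mRNA")
        rpf_tab = results.get("RPF")
        for stratum in sorted(strata):
            genes = lab.index[lab == stratum]
            lfc = table.loc[table.index.intersection(genes), "log2fc"].dropna()
            row = {
                "label": stratum,
                "level": level,
                "n": int(len(lfc)),
                "n_background": int(len(bg)),
            }
            if len(lfc) < min_genes or len(bg) < min_genes:
                row.update(
                    ks_D=np.nan, ks_p=np.nan, median=np.nan, ci_lo=np.nan,
                    ci_hi=np.nan, pearson_r=np.nan, pearson_p=np.nan, suppressed=True,
                )
                rows.append(row)
                continue
            D, p = ks_shift_test(lfc, bg)
            med, lo, hi, _ = median_with_ci(lfc, n_boot=n_boot, seed=seed)
            r = rp = np.nan
            if mrna_tab is not None and rpf_tab is not None:
                shared = (
                    mrna_tab.index.intersection(rpf_tab.index).intersection(genes)
                )
                if len(shared) >= 3:
                    r, rp = stats.pearsonr(
                        mrna_tab.loc[shared, "log2fc"], rpf_tab.loc[shared, "log2fc"]
                    )
            row.update(
                ks_D=D, ks_p=p, median=med, ci_lo=lo, ci_hi=hi,
                pearson_r=float(r), pearson_p=float(rp), suppressed=False,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["ks_fdr"] = np.nan
        for level in out["level"].unique():
            m = (out["level"] == level) & out["ks_p"].notna()
            if m.any():
                out.loc[m, "ks_fdr"] = bh_adjust(out.loc[m, "ks_p"])
    return out


def ecdf_coordinates(values) -> pd.DataFrame:
    """Sorted (x, ecdf) pairs for cumulative-distribution plotting."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"x": v, "ecdf": np.arange(1, len(v) + 1) / len(v)})


def mechanism_call(
    median_mrna: float,
    median_rpf: float,
    median_te: float,
    stratum: str = "",
    delta: float = 0.1,
) -> MechanismCall:
    """Classify a stratum's repression mode from its three median shifts.

    destabilisation_dominant: mRNA shifted down and the TE shift is at most
    half the mRNA shift in magnitude; translation_dominant: the mirror case;
    mixed: both shifted down but neither dominates; none: otherwise.
    """
    m, t = median_mrna, median_te
    if m < -delta and abs(t) <= abs(m) / 2:
        call = "destabilisation_dominant"
    elif t < -delta and abs(m) <= abs(t) / 2:
        call = "translation_dominant"
    elif m < -delta and t < -delta:
        call = "mixed"
    else:
        call = "none"
    return MechanismCall(stratum, call, median_mrna, median_rpf, median_te)


def cross_condition_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    selection: pd.Index | None = None,
    significant_both: bool = False,
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes between two conditions.

    ``selection`` restricts to a gene set (e.g. 3'UTR or CDS targets);
    ``significant_both`` further restricts to genes significant in both
    result tables.
    """
    genes = results_a.index.intersection(results_b.index)
    if selection is not None:
        genes = genes.intersection(pd.Index(selection))
    if significant_both:
        sig = results_a.loc[genes, "significant"] & results_b.loc[genes, "significant"]
        genes = genes[sig.to_numpy(bool)]
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    r, p = stats.pearsonr(results_a.loc[genes, "log2fc"], results_b.loc[genes, "log2fc"])
    return float(r), float(p), int(len(genes))


def hypergeom_enrichment(query_genes, term_genes, universe) -> dict:
    """One-sided over-representation p for a gene set (generic helper)."""
    universe = set(universe)
    q = set(query_genes) & universe
    t = set(term_genes) & universe
    k = len(q & t)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(t), len(q)))
    return {"overlap": k, "query": len(q), "term": len(t), "universe": len(universe), "p": p}
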