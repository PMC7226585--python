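"""qPCR panel analysis: delta-Ct arithmetic, -ddCt fold changes, t-tests,
two-stage (Benjamini-Krieger-Yekutieli) FDR and seed-family grouping.

Reference aggregation is the arithmetic mean of the reference Cts, which
equals the geometric mean of the reference expression levels on the linear
scale. One cycle of Ct difference corresponds to one log2 unit of
expression; the sign convention is that positive -ddCt means upregulation in
the treatment condition.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_fasta

DEFAULT_REFS = ("U6", "U44")


def delta_ct(ct_table: pd.DataFrame, refs: Sequence[str] = DEFAULT_REFS) -> pd.DataFrame:
    """Per-(miRNA, sample) delta-Ct against the reference mean.

    Technical replicates (multiple rows per miRNA and sample) are averaged
    first; delta-Ct = mean target Ct - arithmetic mean of the averaged
    reference Cts of the same sample.
    """
    averaged = (
        ct_table.groupby(["mirna", "sample", "condition"], as_index=False)["ct"].mean()
    )
    ref_rows = averaged[averaged["mirna"].isin(refs)]
    per_sample = ref_rows.groupby("sample")["mirna"].nunique()
    for sample in averaged["sample"].unique():
        if per_sample.get(sample, 0) != len(refs):
            raise ValueError(f"missing reference measurements for sample {sample!r}")
    ref_mean = ref_rows.groupby("sample")["ct"].mean()
    targets = averaged[~averaged["mirna"].isin(refs)].copy()
    targets["delta_ct"] = targets["ct"] - targets["sample"].map(ref_mean)
    return targets[["mirna", "sample", "condition", "delta_ct"]]


def ddct_test(
    dct_treatment, dct_control, equal_var: bool = True
) -> tuple[float, float, bool]:
    """-ddCt estimate and two-sided t-test p over biological replicates.

    Returns (neg_ddct, p, degenerate); zero-variance identical groups are
    reported with p = 1 and the degenerate flag instead of failing.
    """
    a = np.asarray(dct_treatment, dtype=float)
    b = np.asarray(dct_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 biological replicates per condition")
    neg_ddct = -(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        return float(neg_ddct), 1.0 if a.mean() == b.mean() else 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(neg_ddct), float(p), False


def bky_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up FDR control.

    Stage 1 runs BH at q' = q/(1+q) to estimate the number of true nulls
    m0 = m - r1; with 0 < m0 < m, stage 2 reruns BH at level q' * m / m0.
    All hypotheses are rejected if stage 1 rejects everything; none if it
    rejects nothing. Also returns stage-2 BH adjusted p-values scaled by
    m0/m (an extension: the procedure natively yields only decisions).
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, bool), np.zeros(0)
    q1 = q / (1.0 + q)
    rej1, adj1 = _bh(p, q1)
    r1 = int(rej1.sum())
    if r1 == 0:
        return np.zeros(m, bool), np.minimum(adj1 * 1.0, 1.0)
    if r1 == m:
        return np.ones(m, bool), adj1 * 0.0
    m0 = m - r1
    rej2, adj2 = _bh(p, q1 * m / m0)
    return rej2, np.minimum(adj2 * m0 / m, 1.0)


def _bh(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up decisions at level alpha plus adjusted p-values."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresholds = alpha * np.arange(1, m + 1) / m
    below = ranked <= thresholds
    k = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    rej = np.zeros(m, dtype=bool)
    rej[order[:k]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return rej, out


def analyse_panel(
    ct_table: pd.DataFrame,
    refs: Sequence[str] = DEFAULT_REFS,
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full panel analysis: delta-Ct, -ddCt, t-tests and BKY flags."""
    dct = delta_ct(ct_table, refs)
    rows = []
    for mirna, grp in dct.groupby("mirna", sort=True):
        trt = grp.loc[grp["condition"] == "treatment", "delta_ct"]
        ctrl = grp.loc[grp["condition"] == "control", "delta_ct"]
        neg_ddct, p, degenerate = ddct_test(trt, ctrl, equal_var=equal_var)
        rows.append(
            {"mirna": mirna, "neg_ddct": neg_ddct, "t_p": p, "degenerate": degenerate}
        )
    out = pd.DataFrame(rows)
    flags, adj = bky_adjust(out["t_p"].to_numpy(), q=q)
    out["bky_significant"] = flags
    out["bky_adjusted_p"] = adj
    out["q"] = q
    return out


def seed_family(
    sequences: Mapping[str, str] | str | Path, min_length: int = 8
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Group mature miRNAs by their seed (nt 2-8) heptamer.

    Accepts a name->sequence mapping or a FASTA path. Returns the families
    (seed -> member names) and a table of seed pairs at Hamming distance 1
    ("similar" seeds). Sequences shorter than ``min_length`` are skipped.
    """
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    families: dict[str, list[str]] = {}
    skipped = []
    for name, seq in sequences.items():
        s = seq.upper().replace("T", "U")
        if len(s) < min_length:
            skipped.append(name)
            continue
        families.setdefault(s[1:8], []).append(name)
    if skipped:
        import warnings

        warnings.warn(f"skipped short sequences: {skipped}", stacklevel=2)
    seeds = sorted(families)
    rows = [
        {"seed_a": a, "seed_b": b, "hamming": 1}
        for i, a in enumerate(seeds)
        for b in seeds[i + 1 :]
        if sum(x != y for x, y in zip(a, b)) == 1
    ]
    return families, pd.DataFrame(rows, columns=["seed_a", "seed_b", "hamming"])
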