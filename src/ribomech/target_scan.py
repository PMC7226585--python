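"""Canonical miRNA seed-site prediction, context scoring and stratification.

Site definitions follow the canonical seed-match taxonomy: with the mature
miRNA written 5'->3', the target-site match strings (also 5'->3') are

* ``8mer``      reverse complement of miRNA nt 2-8, followed by an A
* ``7mer-m8``   reverse complement of miRNA nt 2-8
* ``7mer-1a``   reverse complement of miRNA nt 2-7, followed by an A
* ``6mer``      reverse complement of miRNA nt 2-7

Overlapping classifications at one seed locus resolve to the strongest type
(8mer > 7mer-m8 > 7mer-1a > 6mer).

The context score is a deliberately small surrogate for the trained
context++ model: a site-type base term, a local AU-content term and a
positional term, all configurable via :class:`ScoringCoefficients`. External
site tables in the TargetScan "Predicted Targets" layout can be used instead
(:func:`read_targetscan_sites`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptModel

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1a", "6mer")
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-1a": 7, "6mer": 6}
#: precedence rank: lower = stronger
SITE_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-1a": 2, "6mer": 3}

SITE_COLUMNS = ["gene_id", "region", "start", "site_type", "context_score"]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class SeedSite:
    """A predicted site; ``start`` is 0-based within its region."""

    transcript_id: str
    region: str  # "utr3" or "cds"
    start: int
    site_type: str
    context_score: float = float("nan")

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTHS[self.site_type]


@dataclass
class ScoringCoefficients:
    """Coefficients of the 3-feature context-score surrogate."""

    base: Mapping[str, float] = field(
        default_factory=lambda: {
            "8mer": -0.31,
            "7mer-m8": -0.16,
            "7mer-1a": -0.10,
            "6mer": -0.02,
        }
    )
    w_au: float = -0.1
    w_pos: float = 0.05
    flank: int = 30
    max_dist: int = 1500


def _clean(seq: str, label: str) -> str:
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in "ACGU":
            raise ValueError(f"{label}: invalid character {ch!r} at position {i}")
    return s


def reverse_complement(rna: str) -> str:
    return rna.translate(_COMPLEMENT)[::-1]


def seed_patterns(mirna_sequence: str) -> dict[str, str]:
    """Target-strand match strings for each canonical site type."""
    m = _clean(mirna_sequence, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA length must be >= 8 nt")
    core = reverse_complement(m[1:7])  # seed nt 2-7
    m8 = reverse_complement(m[7])  # complement of nt 8, 5' of the core
    return {
        "8mer": m8 + core + "A",
        "7mer-m8": m8 + core,
        "7mer-1a": core + "A",
        "6mer": core,
    }


def find_seed_sites(
    region_sequence: str,
    mirna_sequence: str,
    transcript_id: str = "",
    region: str = "utr3",
) -> list[SeedSite]:
    """Scan one region for canonical seed matches, strongest type per locus.

    Every occurrence of the 6-nt seed core defines one locus; the presence of
    a position-8 match (immediately 5') and/or a target A (immediately 3')
    upgrades the locus to 7mer-m8 / 7mer-1a / 8mer. Sites are returned 5'->3'.
    """
    target = _clean(region_sequence, "target")
    patterns = seed_patterns(mirna_sequence)
    core = patterns["6mer"]
    m8 = patterns["7mer-m8"][0]
    sites: list[SeedSite] = []
    p = target.find(core)
    while p != -1:
        has_m8 = p > 0 and target[p - 1] == m8
        has_1a = p + 6 < len(target) and target[p + 6] == "A"
        if has_m8 and has_1a:
            site_type, start = "8mer", p - 1
        elif has_m8:
            site_type, start = "7mer-m8", p - 1
        elif has_1a:
            site_type, start = "7mer-1a", p
        else:
            site_type, start = "6mer", p
        sites.append(SeedSite(transcript_id, region, start, site_type))
        p = target.find(core, p + 1)
    return sites


def score_site(
    site: SeedSite,
    region_sequence: str,
    region_length: int | None = None,
    coeffs: ScoringCoefficients | None = None,
) -> float:
    """Surrogate context score; more negative = more repressive.

    score = base(type) + w_au * (AU fraction of +/-30 nt flanks - 0.5)
                       + w_pos * min(distance to region boundary, 1500)/1500
    """
    coeffs = coeffs or ScoringCoefficients()
    seq = region_sequence.upper().replace("T", "U")
    n = region_length if region_length is not None else len(seq)
    end = site.start + SITE_LENGTHS[site.site_type]
    flank = seq[max(0, site.start - coeffs.flank) : site.start] + seq[end : end + coeffs.flank]
    au = (
        sum(ch in "AU" for ch in flank) / len(flank) if flank else 0.5
    )  # empty flanks contribute no AU term
    dist = min(site.start, n - end)
    pos = min(dist, coeffs.max_dist) / coeffs.max_dist
    return coeffs.base[site.site_type] + coeffs.w_au * (au - 0.5) + coeffs.w_pos * pos


def scan_transcripts(
    transcripts: Iterable[TranscriptModel],
    mirna_sequence: str,
    coeffs: ScoringCoefficients | None = None,
    regions: Sequence[str] = ("utr3", "cds"),
) -> pd.DataFrame:
    """Scan and score 3'UTRs and CDSs of many transcripts.

    Returns a site table (gene_id, region, start, site_type, context_score);
    coordinates are region-relative, 0-based.
    """
    rows = []
    for t in transcripts:
        for region in regions:
            seq = t.utr3 if region == "utr3" else t.cds
            for site in find_seed_sites(seq, mirna_sequence, t.transcript_id, region):
                score = score_site(site, seq, coeffs=coeffs)
                rows.append((t.transcript_id, region, site.start, site.site_type, score))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def aggregate_and_filter(
    sites: pd.DataFrame,
    pct: Mapping[str, float] | pd.Series | None = None,
    threshold: float = -0.2,
) -> pd.DataFrame:
    """Per-gene aggregates (CWCS over 3'UTR sites, TCS over CDS sites).

    Returns one row per gene carrying a site: n_utr3/n_cds site counts, cwcs,
    tcs, pct, and the two "filtered target" flags. A gene is a filtered 3'UTR
    target when cwcs < threshold and it has no CDS site; a filtered CDS target
    when tcs < threshold and it has no 3'UTR site (region-exclusive, so the
    two analyses never share genes).
    """
    if sites.empty:
        return pd.DataFrame(
            columns=["n_utr3", "n_cds", "cwcs", "tcs", "pct", "utr3_target", "cds_target"]
        )
    grouped = sites.groupby(["gene_id", "region"])["context_score"].agg(["size", "sum"])
    ann = pd.DataFrame(index=sites["gene_id"].unique())
    ann.index.name = "gene_id"
    for region, count_col, sum_col in (("utr3", "n_utr3", "cwcs"), ("cds", "n_cds", "tcs")):
        sub = grouped.xs(region, level="region") if region in sites["region"].values else None
        ann[count_col] = sub["size"].reindex(ann.index).fillna(0).astype(int) if sub is not None else 0
        ann[sum_col] = sub["sum"].reindex(ann.index).fillna(0.0) if sub is not None else 0.0
    if pct is None:
        ann["pct"] = 0.0
    else:
        ann["pct"] = pd.Series(pct).reindex(ann.index).fillna(0.0)
    ann["utr3_target"] = (ann["cwcs"] < threshold) & (ann["n_cds"] == 0)
    ann["cds_target"] = (ann["tcs"] < threshold) & (ann["n_utr3"] == 0)
    return ann


STRATA_SCHEMES = ("pct_group", "cwcs_quartile", "seed_type", "region_class")


def assign_strata(
    annotations: pd.DataFrame,
    scheme: str,
    expressed_genes: Iterable[str],
    sites: pd.DataFrame | None = None,
) -> pd.Series:
    """Label every expressed gene under one stratification scheme.

    Labels form a partition: genes without any predicted site get "no_site";
    genes carrying sites that the scheme does not compare (e.g. CDS-site genes
    under a 3'UTR scheme, or 6mer-only genes under seed_type) get "excluded".
    """
    genes = pd.Index(expressed_genes)
    ann = annotations.reindex(genes.intersection(annotations.index))
    labels = pd.Series("no_site", index=genes, name=scheme)

    if scheme == "region_class":
        both = ann.index[(ann["n_utr3"] > 0) & (ann["n_cds"] > 0)]
        u3 = ann.index[(ann["n_utr3"] > 0) & (ann["n_cds"] == 0)]
        cds = ann.index[(ann["n_utr3"] == 0) & (ann["n_cds"] > 0)]
        labels.loc[both] = "both"
        labels.loc[u3] = "utr3_only"
        labels.loc[cds] = "cds_only"
        return labels

    if scheme == "pct_group":
        # 3'UTR analysis: genes with CDS sites are excluded outright
        with_utr3 = ann[ann["n_utr3"] > 0]
        labels.loc[ann.index[(ann["n_utr3"] == 0) & (ann["n_cds"] > 0)]] = "excluded"
        labels.loc[ann.index[(ann["n_utr3"] > 0) & (ann["n_cds"] > 0)]] = "excluded"
        eligible = with_utr3[with_utr3["n_cds"] == 0]
        labels.loc[eligible.index[eligible["pct"] > 0.5]] = "high"
        labels.loc[eligible.index[(eligible["pct"] > 0) & (eligible["pct"] <= 0.5)]] = "low"
        labels.loc[eligible.index[eligible["pct"] == 0]] = "nonconserved"
        return labels

    if scheme == "cwcs_quartile":
        has_site = ann.index[(ann["n_utr3"] > 0) | (ann["n_cds"] > 0)]
        labels.loc[has_site] = "excluded"
        targets = ann[ann["utr3_target"]]
        if len(targets) == 0:
            return labels
        q = np.quantile(targets["cwcs"], [0.25, 0.5, 0.75])
        # boundary values go to the lower (more repressive) quartile
        for gene, cwcs in targets["cwcs"].items():
            if cwcs <= q[0]:
                labels.loc[gene] = "Q1"
            elif cwcs <= q[1]:
                labels.loc[gene] = "Q2"
            elif cwcs <= q[2]:
                labels.loc[gene] = "Q3"
            else:
                labels.loc[gene] = "Q4"
        return labels

    if scheme == "seed_type":
        if sites is None:
            raise ValueError("seed_type scheme requires the site table")
        has_site = ann.index[(ann["n_utr3"] > 0) | (ann["n_cds"] > 0)]
        labels.loc[has_site] = "excluded"
        targets = ann[ann["utr3_target"]]
        utr3_sites = sites[sites["region"] == "utr3"]
        for gene in targets.index:
            gsites = utr3_sites[utr3_sites["gene_id"] == gene]
            if len(gsites) > 1:
                labels.loc[gene] = "multi_site"
            elif len(gsites) == 1:
                stype = gsites["site_type"].iloc[0]
                if stype != "6mer":  # 6mer-only genes stay excluded
                    labels.loc[gene] = stype
        return labels

    raise ValueError(f"unknown stratification scheme {scheme!r}; choose from {STRATA_SCHEMES}")


# --- TargetScan interchange -------------------------------------------------

_TS_SITE_TYPE_MAP = {
    "8mer-1a": "8mer",
    "8mer": "8mer",
    "7mer-m8": "7mer-m8",
    "7mer-1a": "7mer-1a",
    "7mer-a1": "7mer-1a",
    "6mer": "6mer",
}


def read_targetscan_sites(path: str | Path) -> pd.DataFrame:
    """Read a TargetScan "Predicted Targets"-style TSV into the site layout.

    Column matching is tolerant: the gene column is the first of
    {Gene Symbol, Gene ID, gene_id}; the score column the first containing
    "context" and "score"; Pct the first containing "PCT"/"Pct".
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def pick(*cands, contains=None):
        for c in cands:
            if c.lower() in cols:
                return cols[c.lower()]
        if contains:
            for lc, orig in cols.items():
                if all(tok in lc for tok in contains):
                    return orig
        return None

    gene_col = pick("Gene Symbol", "Gene ID", "gene_id", "gene")
    type_col = pick("Site Type", "site_type", contains=("site", "type"))
    score_col = pick(
        "weighted context++ score", "context++ score", contains=("context", "score")
    )
    pct_col = pick("PCT", "Pct", "pct")
    if gene_col is None or type_col is None:
        raise ValueError("could not locate gene / site-type columns in TargetScan table")
    out = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str),
            "region": "utr3",
            "start": df[pick("UTR start", "start")] if pick("UTR start", "start") else -1,
            "site_type": df[type_col].astype(str).str.strip().map(_TS_SITE_TYPE_MAP),
            "context_score": pd.to_numeric(df[score_col], errors="coerce")
            if score_col
            else np.nan,
        }
    )
    if pct_col is not None:
        out["pct"] = pd.to_numeric(df[pct_col], errors="coerce").fillna(0.0)
    if out["site_type"].isna().any():
        bad = df[type_col][out["site_type"].isna()].unique()
        raise ValueError(f"unrecognised TargetScan site types: {bad}")
    return out
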