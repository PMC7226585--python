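"""Synthetic transcriptomes, count matrices, footprints and qPCR Ct tables.

Every downstream stage of the pipeline is testable against the ground truth
produced here: planted seed sites are recorded exactly (region, position,
type, context score), per-gene log2 effects are split into a stability
component ``s_g <= 0`` (acting on mRNA abundance) and a translational
component ``t_g <= 0`` (acting on ribosome occupancy over and above mRNA), so
that by construction the expected mRNA log2fc is ``s_g``, the expected RPF
log2fc is ``s_g + t_g`` and the expected TE log2fc is ``t_g``.

Background sequence is rejection-sampled so that the focal miRNA has no
accidental seed matches; other miRNAs may match by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptModel
from .target_scan import (
    SITE_COLUMNS,
    SITE_LENGTHS,
    ScoringCoefficients,
    SeedSite,
    find_seed_sites,
    score_site,
    seed_patterns,
)

#: arbitrary focal miRNA used by default in simulations (not a miRBase entry)
DEFAULT_MIRNA = "UCGGAUCCGUAAGUGCAAUCGU"

_STOPS = ("UAA", "UAG", "UGA")


@dataclass
class EffectModel:
    """Per-gene log2 effects for planted target genes.

    ``stability`` and ``te`` are the mean log2 effects (both <= 0). With
    ``proportional_to_context`` the per-gene effect is scaled by the gene's
    aggregate context score relative to the target-set mean, so stronger
    (more negative) scores receive proportionally stronger repression.
    """

    stability: float = -1.0
    te: float = 0.0
    proportional_to_context: bool = False

    def __post_init__(self):
        if self.stability > 0 or self.te > 0:
            raise ValueError("effect components must be <= 0 (repressive)")


@dataclass
class SimConfig:
    n_genes: int = 200
    region_lengths: tuple[int, int, int] = (90, 300, 210)  # mean 5'UTR, CDS, 3'UTR
    gc_content: float = 0.5
    n_replicates: int = 4
    lib_size_mean: float = 1e6
    dispersion: float = 0.1  # NB: var = mu + phi * mu^2
    target_fraction: float = 0.25
    effect_model: EffectModel = field(default_factory=EffectModel)
    mirna_sequence: str = DEFAULT_MIRNA
    site_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"8mer": 0.4, "7mer-m8": 0.3, "7mer-1a": 0.3}
    )
    region_weights: Mapping[str, float] = field(default_factory=lambda: {"utr3": 1.0})
    multi_site_fraction: float = 0.0  # fraction of target genes with two sites
    psite_offset: int | Mapping[int, int] = 12
    periodicity: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for name, frac in (
            ("target_fraction", self.target_fraction),
            ("periodicity", self.periodicity),
            ("multi_site_fraction", self.multi_site_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    def cds_length(self, drawn: int) -> int:
        return max(9, drawn - drawn % 3)


@dataclass
class SimTruth:
    """Ground truth of one simulated transcriptome."""

    sites: pd.DataFrame  # planted sites: gene_id, region, start, site_type, context_score
    effects: pd.DataFrame  # per gene: s, t, cwcs, tcs, pct
    config: SimConfig

    @property
    def target_genes(self) -> pd.Index:
        return self.effects.index[(self.effects["s"] != 0) | (self.effects["t"] != 0)]


def _offset_for(psite_offset: int | Mapping[int, int], length: int) -> int:
    if isinstance(psite_offset, Mapping):
        return psite_offset[length]
    return int(psite_offset)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=probs))


def _clean_background(rng: np.random.Generator, n: int, gc: float, core: str) -> str:
    """Random sequence guaranteed not to contain the focal seed core."""
    for _ in range(200):
        seq = _random_seq(rng, n, gc)
        if core not in seq:
            return seq
    raise RuntimeError("could not rejection-sample a clean background sequence")


def _clean_cds(rng: np.random.Generator, n: int, gc: float, core: str) -> str:
    """AUG-initiated, stop-terminated CDS free of the focal seed core."""
    for _ in range(200):
        body = _random_seq(rng, n - 6, gc)
        stop = _STOPS[rng.integers(len(_STOPS))]
        seq = "AUG" + body + stop
        if core not in seq:
            return seq
    raise RuntimeError("could not rejection-sample a clean CDS")


def generate_transcriptome(config: SimConfig) -> tuple[list[TranscriptModel], SimTruth]:
    """Generate transcripts with planted seed sites and record the truth.

    Site insertion overwrites background sequence with the exact match
    string; each modified region is re-scanned and regenerated until the
    scanner's output equals the plan, so the planted site list is exact.
    """
    rng = np.random.default_rng(config.seed)
    patterns = seed_patterns(config.mirna_sequence)
    core = patterns["6mer"]
    coeffs = ScoringCoefficients()

    u5_mean, cds_mean, u3_mean = config.region_lengths
    n_targets = int(round(config.target_fraction * config.n_genes))
    target_idx = set(rng.choice(config.n_genes, size=n_targets, replace=False).tolist())

    type_names = list(config.site_type_weights)
    type_p = np.array([config.site_type_weights[t] for t in type_names], dtype=float)
    type_p /= type_p.sum()
    region_names = list(config.region_weights)
    region_p = np.array([config.region_weights[r] for r in region_names], dtype=float)
    region_p /= region_p.sum()

    transcripts: list[TranscriptModel] = []
    site_rows: list[tuple] = []
    pct: dict[str, float] = {}

    for g in range(config.n_genes):
        gene = f"gene{g:05d}"
        u5_len = max(20, int(rng.normal(u5_mean, u5_mean * 0.15)))
        cds_len = config.cds_length(max(30, int(rng.normal(cds_mean, cds_mean * 0.15))))
        u3_len = max(30, int(rng.normal(u3_mean, u3_mean * 0.15)))

        plan: dict[str, list[tuple[int, str]]] = {"utr3": [], "cds": []}
        if g in target_idx:
            n_sites = 2 if rng.random() < config.multi_site_fraction else 1
            for _ in range(n_sites):
                stype = type_names[rng.choice(len(type_names), p=type_p)]
                region = region_names[rng.choice(len(region_names), p=region_p)]
                plan[region].append((0, stype))  # position assigned below

        utr5 = _clean_background(rng, u5_len, config.gc_content, core)
        cds = _plant_region(
            rng, config, core, patterns, plan["cds"], length=cds_len, region="cds", gene=gene
        )
        utr3 = _plant_region(
            rng, config, core, patterns, plan["utr3"], length=u3_len, region="utr3", gene=gene
        )
        t = TranscriptModel(gene, utr5, cds, utr3)
        transcripts.append(t)

        planted = False
        for region, seq in (("utr3", utr3), ("cds", cds)):
            for site in find_seed_sites(seq, config.mirna_sequence, gene, region):
                score = score_site(site, seq, coeffs=coeffs)
                site_rows.append((gene, region, site.start, site.site_type, score))
                planted = True
        if planted:
            u = rng.random()
            pct[gene] = 0.0 if u < 1 / 3 else float(rng.uniform(0.01, 0.5)) if u < 2 / 3 else float(
                rng.uniform(0.5, 1.0)
            )

    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    effects = _effects_from_sites(sites, pct, [t.transcript_id for t in transcripts], config)
    return transcripts, SimTruth(sites=sites, effects=effects, config=config)


def _plant_region(
    rng: np.random.Generator,
    config: SimConfig,
    core: str,
    patterns: Mapping[str, str],
    planned: Sequence[tuple[int, str]],
    length: int,
    region: str,
    gene: str,
) -> str:
    """Background region with the planned sites overwritten into it.

    Rejection loop: regenerate until the scanner recovers exactly the plan.
    """
    margin = 3 if region == "cds" else 0  # keep start/stop codons intact
    if not planned:
        if region == "cds":
            return _clean_cds(rng, length, config.gc_content, core)
        return _clean_background(rng, length, config.gc_content, core)

    max_len = max(SITE_LENGTHS[stype] for _, stype in planned)
    if length - 2 * margin < max_len + 2 * len(planned):
        raise ValueError(f"region {region} of {gene} too short to host planted sites")

    for _ in range(500):
        if region == "cds":
            seq = list(_clean_cds(rng, length, config.gc_content, core))
        else:
            seq = list(_clean_background(rng, length, config.gc_content, core))
        placed: list[tuple[int, str]] = []
        ok = True
        for _, stype in planned:
            match = patterns[stype]
            for _ in range(100):
                start = int(rng.integers(margin, length - margin - len(match) + 1))
                if all(
                    start + len(match) + 1 <= s or start >= s + len(patterns[t]) + 1
                    for s, t in placed
                ):
                    break
            else:
                ok = False
                break
            seq[start : start + len(match)] = match
            placed.append((start, stype))
        if not ok:
            continue
        out = "".join(seq)
        found = find_seed_sites(out, config.mirna_sequence, gene, region)
        want = sorted(placed)
        got = sorted((s.start, s.site_type) for s in found)
        if got == want:
            return out
    raise RuntimeError(f"failed to plant sites in {region} of {gene}")


def _effects_from_sites(
    sites: pd.DataFrame,
    pct: Mapping[str, float],
    genes: Sequence[str],
    config: SimConfig,
) -> pd.DataFrame:
    eff = pd.DataFrame(
        {"s": 0.0, "t": 0.0, "cwcs": 0.0, "tcs": 0.0, "pct": 0.0}, index=pd.Index(genes, name="gene_id")
    )
    if len(sites):
        agg = sites.groupby(["gene_id", "region"])["context_score"].sum()
        for region, col in (("utr3", "cwcs"), ("cds", "tcs")):
            if region in sites["region"].values:
                sub = agg.xs(region, level="region")
                eff.loc[sub.index, col] = sub.values
    for g, v in pct.items():
        eff.loc[g, "pct"] = v

    targets = sites["gene_id"].unique() if len(sites) else []
    em = config.effect_model
    if len(targets):
        if em.proportional_to_context:
            total = eff.loc[targets, "cwcs"] + eff.loc[targets, "tcs"]
            mean = total.mean()
            scale = total / mean if mean != 0 else 1.0
            eff.loc[targets, "s"] = em.stability * scale
            eff.loc[targets, "t"] = em.te * scale
        else:
            eff.loc[targets, "s"] = em.stability
            eff.loc[targets, "t"] = em.te
    return eff


def simulate_counts(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired mRNA/RPF count matrices plus the design table.

    Counts ~ NB(mu, phi) with var = mu + phi mu^2; treatment means are the
    control means times 2^s (mRNA) or 2^(s+t) (RPF). Library sizes are drawn
    lognormally around ``lib_size_mean``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    genes = truth.effects.index
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base /= base.sum()
    s = truth.effects["s"].values
    t = truth.effects["t"].values

    columns, conds, assays = [], [], []
    mus = []
    for assay in ("mrna", "rpf"):
        for cond in ("control", "treatment"):
            for rep in range(1, config.n_replicates + 1):
                lib = config.lib_size_mean * rng.lognormal(0.0, 0.1)
                fold = np.ones(n_genes)
                if cond == "treatment":
                    fold = 2.0 ** (s if assay == "mrna" else s + t)
                mus.append(base * lib * fold)
                columns.append(f"{assay}_{cond}_{rep}")
                conds.append(cond)
                assays.append(assay)
    mu = np.column_stack(mus)
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=columns)
    design = pd.DataFrame(
        {"condition": conds, "assay": assays}, index=pd.Index(columns, name="sample")
    )
    return counts_df, design


def simulate_footprints(
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
    n_reads: int = 100_000,
    init_fraction: float = 0.1,
    lengths: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phased ribosome footprints in transcript coordinates (BED-like).

    With probability ``periodicity`` a read's P-site (5' end + offset) lands
    on a CDS codon start; otherwise it is shifted +1 or +2 nt (off-frame).
    ``init_fraction`` of reads pile onto the start codon — the initiation
    peak that P-site calibration keys on (the modal 5'end-to-start distance
    equals the offset only when initiation dominates the start vicinity).
    Read lengths are drawn from 25-40 nt.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    lengths = list(lengths) if lengths is not None else list(range(25, 41))
    eligible = [t for t in transcripts if len(t.cds) >= 9]
    if not eligible:
        raise ValueError("no transcripts with an annotated CDS of >= 3 codons")
    weights = np.array([len(t.cds) for t in eligible], dtype=float)
    weights /= weights.sum()

    rows = []
    t_choice = rng.choice(len(eligible), size=n_reads, p=weights)
    for i in range(n_reads):
        t = eligible[t_choice[i]]
        n_codons = len(t.cds) // 3
        length = int(lengths[rng.integers(len(lengths))])
        offset = _offset_for(config.psite_offset, length)
        for _ in range(50):
            if init_fraction > 0 and rng.random() < init_fraction:
                codon = 0
            else:
                codon = int(rng.integers(1, max(2, n_codons - 1)))  # interior codons
            psite = t.cds_start + 3 * codon
            if rng.random() >= config.periodicity:
                psite += int(rng.integers(1, 3))
            start = psite - offset
            if start >= 0 and start + length <= t.length:
                rows.append((t.transcript_id, start, start + length, length))
                break
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "length"])


def simulate_ct_table(
    panel: Mapping[str, float],
    refs: Sequence[str] = ("U6", "U44"),
    n_replicates: int = 4,
    noise_sd: float = 0.1,
    baseline: float = 25.0,
    ref_baseline: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table for a miRNA panel with two reference small RNAs.

    ``panel`` maps miRNA name -> true log2 fold change (treatment vs
    control). One log2 unit of upregulation lowers the treatment Ct by one
    cycle. Reference Cts are constant across conditions up to noise.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ("control", "treatment"):
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_{rep}"
            for mirna, lfc in panel.items():
                ct = baseline - (lfc if cond == "treatment" else 0.0)
                rows.append((mirna, sample, cond, rep, ct + rng.normal(0, noise_sd)))
            for ref in refs:
                rows.append((ref, sample, cond, rep, ref_baseline + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["mirna", "sample", "condition", "replicate", "ct"])


def null_truth(config: SimConfig) -> SimTruth:
    """Effect-free truth (no planted sites) for count-level null simulations.

    Skips sequence generation entirely; useful for calibration studies where
    only the count model matters.
    """
    genes = pd.Index([f"gene{g:05d}" for g in range(config.n_genes)], name="gene_id")
    effects = pd.DataFrame(
        {"s": 0.0, "t": 0.0, "cwcs": 0.0, "tcs": 0.0, "pct": 0.0}, index=genes
    )
    sites = pd.DataFrame(columns=SITE_COLUMNS)
    return SimTruth(sites=sites, effects=effects, config=config)


def plant_site(region_sequence: str, mirna_sequence: str, site_type: str, start: int) -> str:
    """Overwrite ``region_sequence`` with the exact match string at ``start``."""
    match = seed_patterns(mirna_sequence)[site_type]
    if start < 0 or start + len(match) > len(region_sequence):
        raise ValueError("site does not fit in the region")
    seq = list(region_sequence)
    seq[start : start + len(match)] = match
    return "".join(seq)


def random_clean_sequence(
    n: int, gc_content: float, mirna_sequence: str, rng: np.random.Generator
) -> str:
    """Random background with no seed match for the focal miRNA."""
    return _clean_background(rng, n, gc_content, seed_patterns(mirna_sequence)["6mer"])


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
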