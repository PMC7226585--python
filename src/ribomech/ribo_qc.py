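"""Ribosome-profiling diagnostics: feature alignment, P-site calibration,
sub-codon phasing and metagene density.

All operations take footprint alignments in transcript coordinates (columns
transcript_id, start, end, length; 0-based half-open) and a region-length
table (transcript_id, utr5_len, cds_len, utr3_len).

Frames are 0-indexed: frame 0 is the canonical CDS reading frame. Reads are
assigned by P-site (footprints; 5' end + length-specific offset) or by
midpoint (randomly fragmented mRNA-Seq-like reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class PhasingResult:
    frame_fractions: tuple[float, float, float]
    dominant_frame: int
    n_reads: int

    def __post_init__(self):
        if abs(sum(self.frame_fractions) - 1.0) > 1e-9:
            raise ValueError("frame fractions must sum to 1")


@dataclass
class MetageneProfile:
    offsets: np.ndarray  # positions relative to the anchor codon's first nt
    density: np.ndarray  # per-offset density, unit-mean per transcript then summed
    n_transcripts: int
    n_excluded: int  # transcripts shorter than the window


def _region_arrays(regions: pd.DataFrame):
    idx = regions.set_index("transcript_id")
    cds_start = idx["utr5_len"].astype(int)
    cds_end = cds_start + idx["cds_len"].astype(int)
    total = cds_end + idx["utr3_len"].astype(int)
    return cds_start, cds_end, total


def _positions(
    alignments: pd.DataFrame,
    mode: str,
    psite_offsets: int | Mapping[int, int] | None,
) -> np.ndarray:
    starts = alignments["start"].to_numpy()
    lengths = alignments["length"].to_numpy()
    if mode == "psite":
        if psite_offsets is None:
            raise ValueError("P-site assignment requires psite_offsets")
        if isinstance(psite_offsets, Mapping):
            offs = np.array([psite_offsets[int(l)] for l in lengths])
        else:
            offs = np.full(len(starts), int(psite_offsets))
        return starts + offs
    if mode == "midpoint":
        return starts + lengths // 2
    raise ValueError(f"unknown assignment mode {mode!r}")


def region_alignment_stats(
    alignments: pd.DataFrame,
    regions: pd.DataFrame,
    assay: str = "rpf",
    psite_offsets: int | Mapping[int, int] | None = None,
) -> dict:
    """Proportion of reads in 5'UTR / CDS / 3'UTR.

    Ribo-Seq reads are assigned to the region containing their P-site;
    mRNA-Seq reads to the region containing their midpoint. Reads whose
    assigned position falls outside the transcript are counted as discarded.
    """
    mode = "psite" if assay == "rpf" else "midpoint"
    pos = _positions(alignments, mode, psite_offsets)
    cds_start, cds_end, total = _region_arrays(regions)
    tids = alignments["transcript_id"]
    cs = cds_start.reindex(tids).to_numpy()
    ce = cds_end.reindex(tids).to_numpy()
    tot = total.reindex(tids).to_numpy()

    valid = (pos >= 0) & (pos < tot)
    discarded = int((~valid).sum())
    pos_v, cs_v, ce_v = pos[valid], cs[valid], ce[valid]
    n = len(pos_v)
    if n == 0:
        raise ValueError("no reads within transcript bounds")
    in_utr5 = (pos_v < cs_v).sum()
    in_cds = ((pos_v >= cs_v) & (pos_v < ce_v)).sum()
    in_utr3 = (pos_v >= ce_v).sum()
    return {
        "utr5": in_utr5 / n,
        "cds": in_cds / n,
        "utr3": in_utr3 / n,
        "n_assigned": n,
        "n_discarded": discarded,
    }


def estimate_psite_offsets(
    alignments: pd.DataFrame,
    regions: pd.DataFrame,
    min_reads: int = 500,
) -> tuple[dict[int, int], dict[int, bool]]:
    """Per-read-length P-site offset from start-codon cross-correlation.

    For each read length the offset is the modal distance from the 5' end to
    the annotated start codon among reads overlapping a start codon. Length
    classes with fewer than ``min_reads`` such reads fall back to the global
    modal offset; the second return value flags those classes.
    """
    cds_start, _, _ = _region_arrays(regions)
    cs = cds_start.reindex(alignments["transcript_id"]).to_numpy()
    starts = alignments["start"].to_numpy()
    ends = alignments["end"].to_numpy()
    lengths = alignments["length"].to_numpy()
    overlap = (starts <= cs) & (cs < ends)
    if not overlap.any():
        raise ValueError("no reads overlap annotated start codons")
    dist = (cs - starts)[overlap].astype(int)
    lens = lengths[overlap]

    global_mode = int(np.bincount(dist).argmax())
    offsets: dict[int, int] = {}
    fallback: dict[int, bool] = {}
    for length in sorted(np.unique(lengths).astype(int)):
        d = dist[lens == length]
        if len(d) >= min_reads:
            offsets[length] = int(np.bincount(d).argmax())
            fallback[length] = False
        else:
            offsets[length] = global_mode
            fallback[length] = True
    return offsets, fallback


def phasing_fractions(
    alignments: pd.DataFrame,
    psite_offsets: int | Mapping[int, int],
    regions: pd.DataFrame,
) -> PhasingResult:
    """Sub-codon phasing of P-sites over the three CDS frames.

    Only P-sites in the CDS interior (first and last codons excluded, to
    keep initiation/termination pile-ups from inflating one frame) are used.
    """
    pos = _positions(alignments, "psite", psite_offsets)
    cds_start, cds_end, _ = _region_arrays(regions)
    tids = alignments["transcript_id"]
    cs = cds_start.reindex(tids).to_numpy()
    ce = cds_end.reindex(tids).to_numpy()
    interior = (pos >= cs + 3) & (pos < ce - 3)
    if not interior.any():
        raise ValueError("no P-sites in the CDS interior")
    frames = ((pos - cs)[interior] % 3).astype(int)
    counts = np.bincount(frames, minlength=3).astype(float)
    fracs = counts / counts.sum()
    return PhasingResult(tuple(fracs), int(counts.argmax()), int(counts.sum()))


def metagene_profile(
    alignments: pd.DataFrame,
    regions: pd.DataFrame,
    window: tuple[int, int] = (-50, 100),
    anchor: str = "start",
    psite_offsets: int | Mapping[int, int] | None = None,
    assay: str = "rpf",
) -> MetageneProfile:
    """Read density around the start (or stop) codon.

    Each eligible transcript's windowed count vector is scaled to unit mean
    before summation so deep transcripts do not dominate; transcripts whose
    window does not fit inside the transcript (or with no reads in the
    window) are excluded and counted.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    mode = "psite" if assay == "rpf" else "midpoint"
    pos = _positions(alignments, mode, psite_offsets)
    cds_start, cds_end, total = _region_arrays(regions)
    anchor_pos = cds_start if anchor == "start" else cds_end - 3
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")

    offsets = np.arange(lo, hi + 1)
    density = np.zeros(len(offsets))
    n_used = n_excluded = 0
    by_tid = pd.DataFrame({"transcript_id": alignments["transcript_id"], "pos": pos}).groupby(
        "transcript_id"
    )
    for tid, grp in by_tid:
        a = int(anchor_pos.get(tid, -1))
        if a < 0:
            n_excluded += 1
            continue
        if a + lo < 0 or a + hi >= int(total[tid]):
            n_excluded += 1
            continue
        rel = grp["pos"].to_numpy() - a
        in_win = (rel >= lo) & (rel <= hi)
        if not in_win.any():
            n_excluded += 1
            continue
        counts = np.bincount(rel[in_win] - lo, minlength=len(offsets)).astype(float)
        density += counts / counts.mean()
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible transcripts for the metagene window")
    return MetageneProfile(offsets, density, n_used, n_excluded)


def qc_report(
    alignments: pd.DataFrame,
    regions: pd.DataFrame,
    min_reads: int = 500,
) -> dict:
    """Consolidated QC: offsets, phasing and feature alignment proportions."""
    offsets, fallback = estimate_psite_offsets(alignments, regions, min_reads=min_reads)
    phasing = phasing_fractions(alignments, offsets, regions)
    stats = region_alignment_stats(alignments, regions, assay="rpf", psite_offsets=offsets)
    return {
        "psite_offsets": {int(k): int(v) for k, v in offsets.items()},
        "psite_offset_fallback": {int(k): bool(v) for k, v in fallback.items()},
        "frame_fractions": list(phasing.frame_fractions),
        "dominant_frame": phasing.dominant_frame,
        "region_proportions": {k: stats[k] for k in ("utr5", "cds", "utr3")},
        "n_discarded": stats["n_discarded"],
    }
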