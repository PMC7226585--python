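"""Shared domain types and plain-text readers/writers.

All tabular interchange is TSV; sequences are FASTA (via Biopython). Footprint
alignments are BED-like records in transcript coordinates (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_COLUMNS = ["transcript_id", "utr5_len", "cds_len", "utr3_len"]
FOOTPRINT_COLUMNS = ["transcript_id", "start", "end", "length"]
DESIGN_COLUMNS = ["sample", "condition", "assay"]
CT_COLUMNS = ["mirna", "sample", "condition", "replicate", "ct"]


@dataclass
class TranscriptModel:
    """One transcript: contiguous 5'UTR, CDS and 3'UTR sequences (RNA)."""

    transcript_id: str
    utr5: str
    cds: str
    utr3: str

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_start(self) -> int:
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)

    def region_lengths(self) -> tuple[int, int, int]:
        return len(self.utr5), len(self.cds), len(self.utr3)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def region_table(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Region-length table (transcript_id, utr5_len, cds_len, utr3_len)."""
    rows = [(t.transcript_id, *t.region_lengths()) for t in transcripts]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_transcripts(
    transcripts: Iterable[TranscriptModel], fasta_path: str | Path, regions_path: str | Path
) -> None:
    transcripts = list(transcripts)
    write_fasta({t.transcript_id: t.sequence for t in transcripts}, fasta_path)
    region_table(transcripts).to_csv(regions_path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path, regions_path: str | Path) -> list[TranscriptModel]:
    seqs = read_fasta(fasta_path)
    regions = read_regions(regions_path)
    out = []
    for row in regions.itertuples():
        seq = seqs[row.transcript_id]
        u5, cds = int(row.utr5_len), int(row.cds_len)
        out.append(
            TranscriptModel(
                row.transcript_id,
                seq[:u5],
                seq[u5 : u5 + cds],
                seq[u5 + cds : u5 + cds + int(row.utr3_len)],
            )
        )
    return out


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df.set_index("sample")


def read_footprints(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df
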