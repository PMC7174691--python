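"""Readers and writers for the standard formats the pipeline touches.

GTF is read through gffutils and written in the 2.2 dialect (1-based
inclusive coordinates, ``gene_id``/``transcript_id`` attributes, plus a
``read_support`` attribute on transcript features). FASTA goes through
Biopython. Tab-separated tables go through pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import SampleDesign
from .models import GenomicInterval, TranscriptModel


def write_gtf(
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    source: str = "cerna",
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "g_{t.id}"; transcript_id "{t.id}"; '
                f'read_support "{t.read_support}";'
            )
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> List[TranscriptModel]:
    """Parse transcripts (exon structure + read support) from a GTF file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, List[GenomicInterval]] = {}
    support: Dict[str, int] = {}
    order: List[str] = []
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        order.append(tid)
        if "read_support" in f.attributes:
            support[tid] = int(f.attributes["read_support"][0])
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        exons.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
        if tid not in support and "read_support" in f.attributes:
            support[tid] = int(f.attributes["read_support"][0])
    for tid in exons:
        if tid not in order:
            order.append(tid)
    return [
        TranscriptModel(
            id=tid,
            exons=tuple(sorted(exons[tid], key=lambda e: e.start)),
            read_support=support.get(tid, 0),
        )
        for tid in order
        if tid in exons
    ]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def attach_sequences(
    transcripts: Iterable[TranscriptModel], sequences: Mapping[str, str]
) -> List[TranscriptModel]:
    """Attach FASTA sequences to transcript models (errors on missing ids)."""
    out = []
    for t in transcripts:
        if t.id not in sequences:
            raise KeyError(f"no sequence for transcript {t.id!r}")
        t.sequence = sequences[t.id]
        t.__post_init__()  # re-validate length consistency
        out.append(t)
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index_label="sample")


def read_design_tsv(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", index_col="sample"))
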