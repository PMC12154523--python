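"""File-format plumbing: FASTA/FASTQ (Biopython), TSV tables, sample sheets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GraftSample, ReadSet

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "read_sample_sheet", "write_sample_sheet",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genes: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="")
               for gid, seq in genes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> ReadSet:
    names, seqs, quals = [], [], []
    with open(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            names.append(title)
            seqs.append(seq.upper())
            quals.append(qual)
    return ReadSet(names, seqs, quals)


def write_fastq(reads: ReadSet, path) -> None:
    reads.to_fastq(path)


def write_sample_sheet(samples: list[GraftSample], path) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "graft_type": s.graft_type,
        "tissue": s.tissue, "replicate": s.replicate,
        "fastq": ";".join(s.fastq_paths),
    } for s in samples]).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[GraftSample]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = []
    for _, row in df.iterrows():
        fastq = row.get("fastq", "")
        paths = tuple(p for p in str(fastq).split(";") if p and p != "nan")
        samples.append(GraftSample(
            sample_id=row["sample_id"], graft_type=row["graft_type"],
            tissue=row["tissue"], replicate=int(row["replicate"]),
            fastq_paths=paths))
    return samples
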