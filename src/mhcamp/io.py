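"""FASTA/FASTQ reading and report writing (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demultiplex import DemuxResult, Read

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_demux_fastas",
    "write_demux_report",
    "write_variant_report",
    "write_key_values",
]


def read_sequences(path, fmt: str | None = None) -> list[Read]:
    """Load reads from FASTA or FASTQ (format inferred from the suffix when
    not given; qualities are ignored)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [Read(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, fmt)]


def write_fasta(sequences: Iterable[tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, path, "fasta")


def write_demux_fastas(demux: DemuxResult, outdir) -> None:
    """One FASTA of retained window sequences per amplicon."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (individual, replicate), reads in demux.assigned.items():
        if not reads:
            continue
        write_fasta(reads, outdir / f"{individual}.{replicate}.fasta")


def write_demux_report(demux: DemuxResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\treplicate\treads\n")
        for (individual, replicate), reads in sorted(demux.assigned.items()):
            fh.write(f"{individual}\t{replicate}\t{len(reads)}\n")
        for rid, reason in demux.unassigned:
            fh.write(f"#unassigned\t{rid}\t{reason}\n")


def write_key_values(values: Mapping[str, object], path) -> None:
    """Machine-readable summary: one ``key<TAB>value`` line per entry."""
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key}\t{value}\n")


def write_variant_report(records: Mapping[str, object], path) -> None:
    """Tab-separated variant report: id, MPAF, status, cluster, witness."""
    with open(path, "w") as fh:
        fh.write("variant\tmpaf\tstatus\tcluster\twitness\n")
        for i, (seq, rec) in enumerate(sorted(records.items(),
                                              key=lambda kv: -kv[1].mpaf)):
            witness = ""
            if rec.witnesses:
                w = rec.witnesses[0]
                witness = f"breakpoint={w.breakpoint}@{w.amplicon}"
            fh.write(
                f"var{i:04d}:{seq}\t{rec.mpaf:.6f}\t{rec.status}\t"
                f"{rec.cluster or ''}\t{witness}\n"
            )
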