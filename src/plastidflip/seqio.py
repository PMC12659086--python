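"""Sequence and interval file I/O (FASTA/FASTQ with transparent gzip,
BED, GFF3, bedGraph, TSV)."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Any, Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plastidflip.genome import Gene, QuadripartiteGenome
from plastidflip.reads import LongRead


def _open(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, description, sequence) triples; empty file -> empty list."""
    out = []
    with _open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                out.append((rec.id, rec.description, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, description, sequence) records."""
    recs = [
        SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: str | Path) -> list[LongRead]:
    reads: list[LongRead] = []
    with _open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                reads.append(LongRead(id=rec.id, seq=str(rec.seq), qual=qual))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[LongRead]) -> None:
    with _open(path, "wt") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def write_genome_fasta(path: str | Path, genomes: dict[str, QuadripartiteGenome]) -> None:
    """One record per genome; description encodes the region boundaries."""
    write_fasta(
        path,
        [(gid, g.boundary_description(), g.seq) for gid, g in genomes.items()],
    )


def read_genome_fasta(path: str | Path) -> dict[str, QuadripartiteGenome]:
    out: dict[str, QuadripartiteGenome] = {}
    for rid, desc, seq in read_fasta(path):
        body = desc[len(rid) :].strip() if desc.startswith(rid) else desc
        out[rid] = QuadripartiteGenome.parse_boundary_description(seq, body)
    return out


def write_bed(
    path: str | Path, intervals: Iterable[tuple[str, int, int, str]]
) -> None:
    """BED4 (chrom, 0-based half-open start/end, name)."""
    with _open(path, "wt") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bedgraph(
    path: str | Path, chrom: str, values: Iterable[float]
) -> None:
    """Per-base track compressed into equal-value runs."""
    with _open(path, "wt") as fh:
        run_start = 0
        run_val: float | None = None
        pos = 0
        for pos, v in enumerate(values):
            if run_val is None:
                run_start, run_val = pos, v
            elif v != run_val:
                fh.write(f"{chrom}\t{run_start}\t{pos}\t{run_val:g}\n")
                run_start, run_val = pos, v
        if run_val is not None:
            fh.write(f"{chrom}\t{run_start}\t{pos + 1}\t{run_val:g}\n")


def write_gff3(path: str | Path, chrom: str, genes: Iterable[Gene]) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{chrom}\tplastidflip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.name}\n"
            )


def read_gff3(path: str | Path) -> list[Gene]:
    genes: list[Gene] = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 fields")
            if parts[2] not in ("gene", "exon", "CDS"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or f"feature_{ln}"
            genes.append(Gene(name, int(parts[3]) - 1, int(parts[4]), parts[6]))
    return genes


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable[Any]]) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
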