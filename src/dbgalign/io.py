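"""Reading reads, quality trimming, and writing the pipeline's outputs."""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_reads",
    "quality_trim",
    "trim_records",
    "write_fasta",
    "write_fastq",
    "write_contigs_fasta",
    "write_transcripts_fasta",
    "write_retained_tsv",
    "write_evidence_tsv",
]

DEFAULT_QUALITY_THRESHOLD = 15


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_reads(path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA/FASTQ (optionally gzipped) into SeqRecords."""
    fmt = fmt or _sniff_format(path)
    with _open_maybe_gzip(path) as fh:
        return list(SeqIO.parse(fh, fmt))


def quality_trim(bases: str, quals: Sequence[int],
                 threshold: int = DEFAULT_QUALITY_THRESHOLD) -> tuple[str, Sequence[int]]:
    """Truncate at the first position with quality below *threshold*.

    Everything from the first sub-threshold position rightwards is removed;
    the result may be empty.
    """
    if len(bases) != len(quals):
        raise ValueError(
            f"base/quality length mismatch: {len(bases)} vs {len(quals)}")
    for i, q in enumerate(quals):
        if q < threshold:
            return bases[:i], list(quals[:i])
    return bases, list(quals)


def trim_records(records: Iterable[SeqRecord],
                 threshold: int = DEFAULT_QUALITY_THRESHOLD) -> list[SeqRecord]:
    """Quality-trim records that carry phred qualities; pass others through."""
    out = []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            out.append(rec)
            continue
        bases, quals = quality_trim(str(rec.seq), quals, threshold)
        new = SeqRecord(Seq(bases), id=rec.id, description=rec.description)
        new.letter_annotations["phred_quality"] = quals
        out.append(new)
    return out


def write_fasta(records: Iterable[tuple[str, str]], destination) -> None:
    """Write (header, sequence) pairs as FASTA (60-column wrap)."""
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w")
        close = True
    try:
        for header, seq in records:
            destination.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                destination.write(seq[i:i + 60] + "\n")
    finally:
        if close:
            destination.close()


def write_fastq(records: Iterable[SeqRecord], destination) -> None:
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w")
        close = True
    try:
        SeqIO.write(records, destination, "fastq")
    finally:
        if close:
            destination.close()


def write_contigs_fasta(g, destination) -> None:
    """Node sequences as `>node_<id> cov=<coverage> len=<len>` FASTA."""
    recs = ((f"node_{nid} cov={g.coverage(nid):.6g} len={len(g.seq(nid))}",
             g.seq(nid)) for nid in g.node_ids())
    write_fasta(recs, destination)


def write_transcripts_fasta(transcripts, organism: int, destination) -> None:
    """Predicted transcripts as `>tx_<organism>_<serial> ...` FASTA."""
    recs = ((f"tx_{organism}_{i} evalue={t.rank_evalue:.6g} nodes={len(t.nodes)}",
             t.seq) for i, t in enumerate(transcripts))
    write_fasta(recs, destination)


def write_retained_tsv(paths, destination) -> None:
    """Retained paths as TSV: graph, node walk, log10 e-value, partner."""
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w", newline="")
        close = True
    try:
        w = csv.writer(destination, delimiter="\t", lineterminator="\n")
        w.writerow(["graph", "nodes", "log10_evalue", "partner_nodes"])
        for p in paths:
            w.writerow([p.graph, ",".join(p.nodes), f"{p.log_evalue:.6g}",
                        ",".join(p.best_partner or ())])
    finally:
        if close:
            destination.close()


def write_evidence_tsv(shared_calls, organism: int, destination) -> None:
    """Cross-organism hit evidence for shared calls."""
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w", newline="")
        close = True
    try:
        w = csv.writer(destination, delimiter="\t", lineterminator="\n")
        w.writerow(["query", "subject", "mode", "score", "evalue",
                    "q_start", "q_end", "s_start", "s_end"])
        other = 2 if organism == 1 else 1
        for call in shared_calls:
            for j, mode, hit in call.forward_hits:
                w.writerow([
                    f"tx_{organism}_{call.index}", f"tx_{other}_{j}", mode,
                    f"{hit.score:g}", f"{hit.evalue:.6g}",
                    hit.query_range[0], hit.query_range[1],
                    hit.subject_range[0], hit.subject_range[1]])
    finally:
        if close:
            destination.close()
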