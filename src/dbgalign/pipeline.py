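"""End-to-end orchestration: trim -> build -> extend -> select -> call shared."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .align import ScoringScheme, nucleotide_scheme, translated_scheme
from .extend import ExtensionLimits, GraphPath, run_extension
from .graph import CondensedGraph, EmptyGraphError, apply_coverage_cutoff, build_graph
from .io import (trim_records, write_evidence_tsv, write_fasta,
                 write_retained_tsv, write_transcripts_fasta)
from .shared import SharedCall, call_shared
from .transcripts import PredictedTranscript, select_transcripts

logger = logging.getLogger("dbgalign")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one run; serializable to/from JSON.

    Defaults follow the package's standard protocol: seeding at e-value 0.1,
    reciprocal shared-calling at 1e-7 (1e-20 as the stringent alternative),
    both scoring modes, at most 10 pooled occurrences of a node+twin among
    selected transcripts.
    """

    k: int = 25
    cov_cutoff: float = 3.0
    seed_evalue: float = 0.1
    shared_evalue: float = 1e-7
    modes: tuple[str, ...] = ("translated", "nucleotide")
    max_per_node: int = 10
    quality_threshold: int = 15
    max_nodes_per_path: int = 500
    max_node_revisits: int = 2
    nt_match: int = 1
    nt_mismatch: int = -2
    nt_gap_open: int = 5
    nt_gap_extend: int = 2
    aa_matrix: str = "BLOSUM62"
    aa_gap_open: int = 11
    aa_gap_extend: int = 1
    word_size_nt: int | None = None
    word_size_aa: int | None = None
    threads: int = 1
    seed: int = 0

    def __post_init__(self):
        bad = [m for m in self.modes if m not in ("nucleotide", "translated")]
        if bad:
            raise ValueError(f"unknown modes: {bad}")
        if not self.seed_evalue > 0 or not self.shared_evalue > 0:
            raise ValueError("e-value cutoffs must be positive")

    def schemes(self) -> list[ScoringScheme]:
        out = []
        for m in self.modes:
            if m == "nucleotide":
                out.append(nucleotide_scheme(
                    match=self.nt_match, mismatch=self.nt_mismatch,
                    gap_open=self.nt_gap_open, gap_extend=self.nt_gap_extend,
                    word_size=self.word_size_nt))
            else:
                out.append(translated_scheme(
                    matrix_name=self.aa_matrix, gap_open=self.aa_gap_open,
                    gap_extend=self.aa_gap_extend, word_size=self.word_size_aa))
        return out

    def limits(self) -> ExtensionLimits:
        return ExtensionLimits(self.max_nodes_per_path, self.max_node_revisits)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "modes" in data:
            data["modes"] = tuple(data["modes"])
        return cls(**data)


@dataclass
class PipelineResult:
    config: RunConfig
    graph1: CondensedGraph | None
    graph2: CondensedGraph | None
    paths1: list[GraphPath] = field(default_factory=list)
    paths2: list[GraphPath] = field(default_factory=list)
    transcripts1: list[PredictedTranscript] = field(default_factory=list)
    transcripts2: list[PredictedTranscript] = field(default_factory=list)
    shared1: list[SharedCall] = field(default_factory=list)
    shared2: list[SharedCall] = field(default_factory=list)


def _as_strings(reads) -> list[str]:
    return [str(getattr(r, "seq", r)) for r in reads]


def run_pipeline(reads1, reads2, cfg: RunConfig) -> PipelineResult:
    """Run the whole method on two read sets (SeqRecords or plain strings).

    Quality trimming applies to records carrying phred qualities. An empty
    (or unusably short) read set yields clean empty outputs with a warning
    rather than an error. Results are independent of ``cfg.threads``.
    """
    reads1 = _as_strings(trim_records(reads1, cfg.quality_threshold))
    reads2 = _as_strings(trim_records(reads2, cfg.quality_threshold))

    graphs: list[CondensedGraph | None] = []
    for label, reads in ((1, reads1), (2, reads2)):
        try:
            g = apply_coverage_cutoff(build_graph(reads, cfg.k), cfg.cov_cutoff)
        except EmptyGraphError:
            logger.warning("organism %d: no usable reads; outputs will be empty",
                           label)
            g = None
        else:
            logger.info("organism %d: graph has %d nodes, %d edges",
                        label, g.n_nodes, g.n_edges)
        graphs.append(g)
    g1, g2 = graphs
    result = PipelineResult(cfg, g1, g2)
    if g1 is None or g2 is None or g1.n_nodes == 0 or g2.n_nodes == 0:
        return result

    result.paths1, result.paths2 = run_extension(
        g1, g2, cfg.schemes(), cfg.seed_evalue, cfg.limits(),
        n_jobs=cfg.threads)
    logger.info("retained paths: %d / %d", len(result.paths1), len(result.paths2))

    result.transcripts1 = select_transcripts(result.paths1, g1, cfg.max_per_node)
    result.transcripts2 = select_transcripts(result.paths2, g2, cfg.max_per_node)
    logger.info("predicted transcripts: %d / %d",
                len(result.transcripts1), len(result.transcripts2))

    result.shared1, result.shared2 = call_shared(
        result.transcripts1, result.transcripts2, cfg.schemes(),
        cfg.shared_evalue)
    logger.info("shared calls: %d / %d", len(result.shared1), len(result.shared2))
    return result


def write_outputs(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write transcripts, shared calls, retained paths and evidence files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["config"] = outdir / "config.json"
    files["config"].write_text(result.config.to_json() + "\n")

    for org in (1, 2):
        tx = getattr(result, f"transcripts{org}")
        calls = getattr(result, f"shared{org}")
        paths = getattr(result, f"paths{org}")

        f = outdir / f"transcripts_{org}.fasta"
        write_transcripts_fasta(tx, org, f)
        files[f"transcripts_{org}"] = f

        f = outdir / f"shared_{org}.fasta"
        write_fasta(((f"tx_{org}_{c.index} evalue={c.transcript.rank_evalue:.6g} "
                      f"nodes={len(c.transcript.nodes)}", c.transcript.seq)
                     for c in calls), f)
        files[f"shared_{org}"] = f

        f = outdir / f"retained_{org}.tsv"
        write_retained_tsv(paths, f)
        files[f"retained_{org}"] = f

        f = outdir / f"evidence_{org}.tsv"
        write_evidence_tsv(calls, org, f)
        files[f"evidence_{org}"] = f
    return files
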