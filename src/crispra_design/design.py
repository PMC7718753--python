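"""End-to-end guide design: I/O -> scan -> score -> rank, plus TSV/BED reports."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from . import __version__
from .genome_io import GenomeSequence, TssRecord, extract_promoter_window
from .scan import GuideCandidate, annotate, find_protospacers
from .scoring import (
    DesignConfig,
    ScoreBreakdown,
    apply_filters,
    rank_candidates,
    score_candidate,
)

logger = logging.getLogger("crispra_design")

STRAND_CONVENTION = (
    "strand_class names the DNA strand the spacer base-pairs with: "
    "NT = spacer pairs with the non-template (coding) strand "
    "(protospacer on the template strand); T = spacer pairs with the template strand"
)


@dataclass(frozen=True)
class GeneResult:
    """Ranked candidates for one TSS, or the reason none were produced."""

    tss: TssRecord
    candidates: tuple[tuple[GuideCandidate, ScoreBreakdown], ...]
    status: str = "ok"  # ok | no_pam_match | all_dropped | missing_contig | empty_window


@dataclass(frozen=True)
class DesignReport:
    results: tuple[GeneResult, ...]
    config: DesignConfig
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.results if r.status == "ok")


def _digest(items: Iterable[str]) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(item.encode())
    return h.hexdigest()[:16]


def design_guides(
    genomes: Mapping[str, GenomeSequence],
    tss_list: Iterable[TssRecord],
    cfg: DesignConfig = DesignConfig(),
) -> DesignReport:
    """Run the full design pipeline for every TSS.

    Each TSS gets an independent run: promoter window extraction, protospacer
    enumeration on both strands, annotation, filtering, scoring and ranking.
    Candidates are restricted to the configured scan region
    ``[-upstream_bp, +downstream_bp]`` of the TSS. A missing contig yields a
    per-record error entry and the run continues; an empty genome is a hard
    error. Output is deterministic and independent of input order.
    """
    if not genomes:
        raise ValueError("empty genome set")
    ordered = sorted(set(tss_list))
    results: list[GeneResult] = []
    for tss in ordered:
        genome = genomes.get(tss.contig_id)
        if genome is None:
            logger.error("gene %s: contig %s not in genome set; skipped",
                         tss.gene_id, tss.contig_id)
            results.append(GeneResult(tss, (), status="missing_contig"))
            continue
        window = extract_promoter_window(
            genome, tss, cfg.upstream_bp, cfg.downstream_bp, cfg.margin_bp
        )
        if not window.sequence:
            results.append(GeneResult(tss, (), status="empty_window"))
            continue
        hits = find_protospacers(window, cfg.spacer_len, cfg.pam)
        if not hits:
            results.append(GeneResult(tss, (), status="no_pam_match"))
            continue
        scored: list[tuple[GuideCandidate, ScoreBreakdown]] = []
        for hit in hits:
            cand = annotate(hit, tss, cfg.distance_reference)
            if not (-cfg.upstream_bp <= cand.d_tss <= cfg.downstream_bp):
                continue
            flags, keep = apply_filters(cand, cfg, window.truncated_flag)
            if not keep:
                continue
            cand = replace(cand, flags=flags)
            scored.append((cand, score_candidate(cand, cfg, window.truncated_flag)))
        if not scored:
            status = "all_dropped" if hits else "no_pam_match"
            results.append(GeneResult(tss, (), status=status))
            continue
        ranked = rank_candidates(scored, cfg)
        if cfg.top_n is not None:
            ranked = ranked[: cfg.top_n]
        results.append(GeneResult(tss, tuple(ranked)))
    metadata = {
        "tool_version": __version__,
        "strand_convention": STRAND_CONVENTION,
        "genome_digest": _digest(
            f"{cid}:{genomes[cid].sequence}" for cid in sorted(genomes)
        ),
        "tss_digest": _digest(
            f"{t.gene_id}:{t.contig_id}:{t.gene_strand}:{t.tss_pos}" for t in ordered
        ),
        "config": cfg.model_dump_json(),
    }
    report = DesignReport(tuple(results), cfg, metadata)
    if report.n_ok == 0:
        logger.error("no gene produced candidates (%d records)", len(ordered))
    return report


TSV_COLUMNS = [
    "gene_id", "contig", "gene_strand", "rank", "spacer_seq", "pam_seq",
    "protospacer_strand", "protospacer_start", "d_tss", "strand_class",
    "gc_fraction", "position_score", "composite_score", "predicted_fold", "flags",
]


def write_tsv(report: DesignReport, path: str | Path) -> None:
    """Write one row per ranked candidate; byte-identical across reruns."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for result in report.results:
            for rank, (cand, brk) in enumerate(result.candidates, start=1):
                fh.write(
                    "\t".join(
                        [
                            cand.gene_id,
                            cand.contig_id,
                            cand.gene_strand,
                            str(rank),
                            cand.spacer_seq,
                            cand.pam_seq,
                            cand.protospacer_strand,
                            str(cand.protospacer_start),
                            str(cand.d_tss),
                            cand.strand_class,
                            f"{cand.gc_fraction:.4f}",
                            f"{brk.position_score:g}",
                            f"{brk.composite:.4f}",
                            f"{brk.predicted_fold:.2f}",
                            ";".join(sorted(brk.flags)),
                        ]
                    )
                    + "\n"
                )


def write_bed(report: DesignReport, path: str | Path) -> None:
    """BED6 over protospacer spans; score = composite scaled to [0, 1000]."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for result in report.results:
            for rank, (cand, brk) in enumerate(result.candidates, start=1):
                span_end = cand.protospacer_start + len(cand.spacer_seq)
                score = min(1000, max(0, round(brk.composite * 1000)))
                fh.write(
                    f"{cand.contig_id}\t{cand.protospacer_start}\t{span_end}\t"
                    f"{cand.gene_id}|{rank}|{cand.strand_class}\t{score}\t"
                    f"{cand.protospacer_strand}\n"
                )
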