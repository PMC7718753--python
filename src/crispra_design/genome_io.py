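"""Genome and annotation I/O with explicit coordinate conventions.

All internal coordinates are 0-based, half-open. Conversions to and from the
1-based inclusive GFF3 convention and the 0-based half-open BED convention
happen only at the format boundary, in :func:`read_tss` / :func:`write_tss_bed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

logger = logging.getLogger("crispra_design")

#: IUPAC nucleotide one-letter codes accepted on input. Codes outside the
#: unambiguous A/C/G/T (plus N) are collapsed to N, since a degenerate base
#: cannot be part of a synthesizable spacer anyway.
_IUPAC_CODES = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = _IUPAC_CODES - set("ACGTN")


class GenomeIOError(ValueError):
    """Raised for malformed genome or annotation input."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: an identifier and its uppercase A/C/G/T/N sequence."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class TssRecord:
    """A transcription start site: the 0-based index of the first transcribed base.

    All guide distances in this package are measured relative to ``tss_pos``
    in the direction of transcription, upstream negative.
    """

    gene_id: str
    contig_id: str
    gene_strand: str  # '+' or '-'
    tss_pos: int

    def __post_init__(self) -> None:
        if self.gene_strand not in ("+", "-"):
            raise GenomeIOError(
                f"invalid strand {self.gene_strand!r} for gene {self.gene_id!r}"
            )
        if self.tss_pos < 0:
            raise GenomeIOError(
                f"negative TSS position {self.tss_pos} for gene {self.gene_id!r}"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter region around one TSS, held in contig (+) orientation.

    ``window_start``/``window_end`` are 0-based half-open contig coordinates;
    ``truncated_flag`` records clipping at a contig edge.
    """

    tss: TssRecord
    window_start: int
    window_end: int
    sequence: str
    truncated_flag: bool = False

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != len(self.sequence):
            raise GenomeIOError("window span does not match sequence length")


def _normalize_sequence(raw: str, contig_id: str) -> str:
    """Uppercase, validate against IUPAC codes, collapse ambiguity codes to N."""
    seq = raw.upper().replace("U", "T")
    bad = [(i, c) for i, c in enumerate(seq) if c not in _IUPAC_CODES]
    if bad:
        off, char = bad[0]
        raise GenomeIOError(
            f"contig {contig_id!r}: non-IUPAC character {char!r} at offset {off}"
        )
    n_ambig = sum(seq.count(c) for c in _AMBIGUOUS)
    if n_ambig:
        logger.warning(
            "contig %s: %d ambiguous IUPAC base(s) mapped to N", contig_id, n_ambig
        )
        table = str.maketrans({c: "N" for c in _AMBIGUOUS})
        seq = seq.translate(table)
    return seq


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a multi-record FASTA into a contig_id -> GenomeSequence mapping.

    IDs are the first whitespace-delimited token of each header. Duplicate
    IDs are a hard error; ambiguity codes are mapped to N with a warning.
    """
    genomes: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise GenomeIOError(f"duplicate contig ID {record.id!r} in {path}")
        seq = _normalize_sequence(str(record.seq), record.id)
        genomes[record.id] = GenomeSequence(record.id, seq)
    if not genomes:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return genomes


def _gff3_gene_id(feature: gffutils.Feature) -> str | None:
    for key in ("ID", "Name"):
        if key in feature.attributes and feature.attributes[key]:
            return feature.attributes[key][0]
    return None


def read_tss(
    path: str | Path,
    format: str,
    feature_types: Iterable[str] = ("gene",),
    genomes: Mapping[str, GenomeSequence] | None = None,
) -> list[TssRecord]:
    """Extract TSS records from a GFF3 or BED6 annotation.

    GFF3 features are 1-based inclusive: the TSS of a + strand feature is
    ``start - 1`` in 0-based coordinates and the TSS of a - strand feature is
    ``end - 1`` (its last coordinate, where transcription begins). BED is
    already 0-based half-open: TSS = ``start`` on +, ``end - 1`` on -.

    Records missing a strand are skipped with a warning. Identical
    (gene_id, contig, strand, tss_pos) tuples are deduplicated; distinct TSSs
    of one gene are kept as separate records. If ``genomes`` is given, TSS
    coordinates outside the contig are a hard error.
    """
    if format not in ("gff3", "bed"):
        raise GenomeIOError(f"unknown annotation format {format!r}")
    records: list[TssRecord] = []
    if format == "gff3":
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        wanted = set(feature_types)
        for feat in db.all_features():
            if feat.featuretype not in wanted:
                continue
            gene_id = _gff3_gene_id(feat)
            if gene_id is None:
                logger.warning("GFF3 feature without ID/Name at %s:%d skipped",
                               feat.seqid, feat.start)
                continue
            if feat.strand not in ("+", "-"):
                logger.warning("gene %s: missing strand, skipped", gene_id)
                continue
            tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
            records.append(TssRecord(gene_id, feat.seqid, feat.strand, tss))
    else:
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise GenomeIOError(f"{path}:{ln}: BED6 requires 6 columns")
            contig, start, end, name, _score, strand = cols[:6]
            if strand not in ("+", "-"):
                logger.warning("%s:%d: missing strand, record skipped", path, ln)
                continue
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i - 1
            records.append(TssRecord(name, contig, strand, tss))

    if genomes is not None:
        for rec in records:
            contig = genomes.get(rec.contig_id)
            if contig is not None and not (0 <= rec.tss_pos < contig.length):
                raise GenomeIOError(
                    f"gene {rec.gene_id}: TSS {rec.tss_pos} outside contig "
                    f"{rec.contig_id} (length {contig.length})"
                )

    seen: set[TssRecord] = set()
    unique: list[TssRecord] = []
    for rec in records:
        if rec not in seen:
            seen.add(rec)
            unique.append(rec)
    return unique


def write_tss_bed(records: Iterable[TssRecord], path: str | Path) -> None:
    """Write TSS records as single-base BED6 intervals (round-trips with read_tss)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                f"{rec.contig_id}\t{rec.tss_pos}\t{rec.tss_pos + 1}\t"
                f"{rec.gene_id}\t0\t{rec.gene_strand}\n"
            )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalized A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoter_window(
    genome: GenomeSequence,
    tss: TssRecord,
    upstream_bp: int,
    downstream_bp: int,
    margin_bp: int,
) -> PromoterWindow:
    """Extract the promoter scan region around a TSS.

    The window spans ``[-upstream_bp - margin, +downstream_bp + margin)``
    around the TSS in the direction of transcription; the margin lets
    protospacers straddling the nominal boundary be found. The sequence is
    returned in contig (+) orientation regardless of gene strand, and the
    span is clipped at contig edges with ``truncated_flag`` set.
    """
    if upstream_bp < 0 or downstream_bp < 0 or margin_bp < 0:
        raise GenomeIOError("window extents must be non-negative")
    if tss.gene_strand == "+":
        lo = tss.tss_pos - upstream_bp - margin_bp
        hi = tss.tss_pos + downstream_bp + margin_bp
    else:
        # Transcription runs right-to-left: upstream is at higher coordinates.
        lo = tss.tss_pos - downstream_bp - margin_bp + 1
        hi = tss.tss_pos + upstream_bp + margin_bp + 1
    clipped_lo = max(lo, 0)
    clipped_hi = min(hi, genome.length)
    truncated = clipped_lo != lo or clipped_hi != hi
    if clipped_lo >= clipped_hi:
        logger.warning("gene %s: promoter window entirely off contig %s",
                       tss.gene_id, genome.contig_id)
        return PromoterWindow(tss, 0, 0, "", truncated_flag=True)
    return PromoterWindow(
        tss, clipped_lo, clipped_hi,
        genome.sequence[clipped_lo:clipped_hi],
        truncated_flag=truncated,
    )
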