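"""Protospacer enumeration and per-candidate annotation.

Scans a promoter window on both strands for spacer + PAM placements (SpCas9
NGG by default) and annotates each hit with its signed distance to the TSS,
GC fraction, and targeted-strand class.

Strand-class naming: a guide is classed by the DNA strand its spacer
base-pairs with. The spacer is identical in sequence to the protospacer, so
it hybridizes with the strand *opposite* the protospacer-bearing strand.
When the protospacer lies on the gene's own (coding) strand the spacer pairs
with the template strand — class T; when the protospacer lies on the
opposite strand the spacer pairs with the non-template strand — class NT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import PromoterWindow, TssRecord, reverse_complement

logger = logging.getLogger("crispra_design")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RawHit:
    """An un-annotated protospacer placement on the contig.

    ``spacer_seq`` and ``pam_seq`` are 5'->3' on the protospacer strand (the
    spacer as it would be synthesized); ``start`` is the 0-based contig
    coordinate of the protospacer's leftmost base.
    """

    spacer_seq: str
    pam_seq: str
    strand: str  # contig strand carrying the protospacer
    start: int


@dataclass(frozen=True)
class GuideCandidate:
    gene_id: str
    contig_id: str
    gene_strand: str
    spacer_seq: str
    pam_seq: str
    protospacer_strand: str
    protospacer_start: int
    d_tss: int
    gc_fraction: float
    strand_class: str  # 'NT' or 'T'
    flags: frozenset[str] = field(default_factory=frozenset)


def _pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC.get(p, "") for b, p in zip(seq, pattern)
    )


def find_protospacers(
    window: PromoterWindow, spacer_len: int = 20, pam: str = "NGG"
) -> list[RawHit]:
    """Enumerate every spacer+PAM placement in a window, on both strands.

    A hit on the + strand reads left-to-right: spacer then PAM. A hit on the
    - strand appears in the window as reverse-complemented PAM then
    reverse-complemented spacer; its reported sequences are on the - strand.
    Candidates containing N in spacer or PAM are dropped with a counted
    warning. Coordinates are contig coordinates.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    seq = window.sequence
    plen = len(pam)
    total = spacer_len + plen
    hits: list[RawHit] = []
    n_dropped = 0
    for i in range(len(seq) - total + 1):
        # + strand: [spacer][PAM]
        spacer = seq[i : i + spacer_len]
        pam_seq = seq[i + spacer_len : i + total]
        if _pam_matches(pam_seq, pam):
            if "N" in spacer or "N" in pam_seq:
                n_dropped += 1
            else:
                hits.append(RawHit(spacer, pam_seq, "+", window.window_start + i))
        # - strand: [revcomp(PAM)][revcomp(spacer)]
        rc_pam = seq[i : i + plen]
        rc_spacer = seq[i + plen : i + total]
        pam_rev = reverse_complement(rc_pam)
        if _pam_matches(pam_rev, pam):
            if "N" in rc_spacer or "N" in rc_pam:
                n_dropped += 1
            else:
                hits.append(
                    RawHit(
                        reverse_complement(rc_spacer),
                        pam_rev,
                        "-",
                        window.window_start + i + plen,
                    )
                )
    if n_dropped:
        logger.warning(
            "gene %s: %d candidate(s) dropped for N in spacer/PAM",
            window.tss.gene_id, n_dropped,
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pam_proximal_base(start: int, strand: str, spacer_len: int) -> int:
    """Contig coordinate of the protospacer base adjacent to the PAM."""
    return start + spacer_len - 1 if strand == "+" else start


def distance_to_tss(
    start: int,
    strand: str,
    spacer_len: int,
    tss: TssRecord,
    reference: str = "pam_proximal",
) -> int:
    """Signed distance from the TSS to a protospacer reference point.

    Measured in the gene's transcription direction: upstream negative, 0 is
    the TSS base itself. The default reference point is the PAM-proximal
    base of the protospacer; ``midpoint`` and ``five_prime`` (the spacer's
    5' end, i.e. the PAM-distal base) are alternatives.
    """
    if reference == "pam_proximal":
        pos = pam_proximal_base(start, strand, spacer_len)
    elif reference == "midpoint":
        pos = start + spacer_len // 2
    elif reference == "five_prime":
        pos = start if strand == "+" else start + spacer_len - 1
    else:
        raise ValueError(f"unknown distance reference {reference!r}")
    if tss.gene_strand == "+":
        return pos - tss.tss_pos
    return tss.tss_pos - pos


def classify_strand(protospacer_strand: str, gene_strand: str) -> str:
    """NT when the protospacer lies opposite the gene strand, else T.

    The spacer base-pairs with the strand complementary to the one bearing
    the protospacer, so a protospacer on the gene (coding) strand means the
    spacer hybridizes with the template strand (class T).
    """
    return "T" if protospacer_strand == gene_strand else "NT"


def gc_fraction(seq: str) -> float:
    """Fraction of G or C bases in an A/C/G/T sequence."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def annotate(hit: RawHit, tss: TssRecord, reference: str = "pam_proximal") -> GuideCandidate:
    """Attach distance, GC and strand-class annotations to a raw hit."""
    d = distance_to_tss(hit.start, hit.strand, len(hit.spacer_seq), tss, reference)
    return GuideCandidate(
        gene_id=tss.gene_id,
        contig_id=tss.contig_id,
        gene_strand=tss.gene_strand,
        spacer_seq=hit.spacer_seq,
        pam_seq=hit.pam_seq,
        protospacer_strand=hit.strand,
        protospacer_start=hit.start,
        d_tss=d,
        gc_fraction=gc_fraction(hit.spacer_seq),
        strand_class=classify_strand(hit.strand, tss.gene_strand),
    )
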