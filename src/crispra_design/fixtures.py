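"""Seeded synthetic genomes with planted protospacers and exact ground truth.

The generator builds one contig per gene and plants protospacers at
controlled distance-to-TSS, GC count and strand class. Background sequence
is drawn i.i.d. at a configurable GC level but with GG/CC dinucleotides
rejected, so no incidental NGG (or its - strand CCN mirror) exists anywhere
outside the planted footprints: a re-scan of the promoter window finds the
planted candidates and nothing else, giving exact rather than probabilistic
ground truth. Planted spacers place their G/C bases in alternating G,C order
(and A/T filler in alternating A,T order) for the same reason; GC placement
within the spacer is irrelevant to the scoring model, so any arrangement
with the intended GC count is a faithful plant.

Every fixture is verified by re-scanning with the production scanner; on an
unexpected candidate the background is resampled (bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, PromoterWindow, TssRecord, reverse_complement
from .scan import annotate, find_protospacers
from .scoring import DesignConfig, rank_candidates, score_candidate

#: (d_tss, gc_count, strand_class) for one planted guide
PlantSpec = tuple[int, int, str]

_GENE_BODY_BP = 60
_MAX_RESAMPLE = 25


class FixtureError(ValueError):
    """Raised for infeasible plant specifications."""


@dataclass(frozen=True)
class Fixture:
    """A synthetic genome set with its TSS records and ground-truth table.

    ``truth`` has one row per planted guide: gene_id, d_tss, gc_count,
    strand_class, spacer_seq, expected_rank_hint ('best' for the guide the
    scoring rules should rank first within its gene, 'decoy' otherwise).
    """

    genomes: dict[str, GenomeSequence]
    tss_records: tuple[TssRecord, ...]
    truth: pd.DataFrame
    seed: int

    def write(self, prefix: str | Path) -> tuple[Path, Path, Path]:
        """Write prefix.fasta, prefix.gff3 and prefix.truth.tsv."""
        prefix = Path(prefix)
        fasta = prefix.with_suffix(".fasta")
        gff3 = prefix.with_suffix(".gff3")
        truth = prefix.with_name(prefix.name + ".truth.tsv")
        with open(fasta, "w", encoding="utf-8") as fh:
            for cid in sorted(self.genomes):
                fh.write(f">{cid}\n{self.genomes[cid].sequence}\n")
        with open(gff3, "w", encoding="utf-8") as fh:
            fh.write("##gff-version 3\n")
            for tss in self.tss_records:
                length = self.genomes[tss.contig_id].length
                if tss.gene_strand == "+":
                    start = tss.tss_pos + 1
                    end = min(length, tss.tss_pos + _GENE_BODY_BP)
                else:
                    end = tss.tss_pos + 1
                    start = max(1, end - _GENE_BODY_BP + 1)
                fh.write(
                    f"{tss.contig_id}\t.\tgene\t{start}\t{end}\t.\t"
                    f"{tss.gene_strand}\t.\tID={tss.gene_id}\n"
                )
        self.truth.to_csv(truth, sep="\t", index=False)
        return fasta, gff3, truth


def _spacer_with_gc(gc_count: int, spacer_len: int, rng: np.random.Generator) -> str:
    """A spacer with exactly gc_count G/C bases and no GG/CC dinucleotide."""
    if not 0 <= gc_count <= spacer_len:
        raise FixtureError(f"gc_count {gc_count} outside [0, {spacer_len}]")
    is_gc = np.zeros(spacer_len, dtype=bool)
    is_gc[rng.choice(spacer_len, size=gc_count, replace=False)] = True
    bases, gc_toggle, at_toggle = [], 0, 0
    for flag in is_gc:
        if flag:
            bases.append("GC"[gc_toggle])
            gc_toggle ^= 1
        else:
            bases.append("AT"[at_toggle])
            at_toggle ^= 1
    return "".join(bases)


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. background at the given GC level, GG/CC dinucleotides rejected.

    Draws the whole array vectorized, then iteratively redraws the second
    base of any GG/CC pair until none remain.
    """
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.array(list("ACGT"))
    codes = rng.choice(4, size=length, p=probs)
    while True:
        same = (codes[1:] == codes[:-1]) & np.isin(codes[1:], (1, 2))
        bad = np.flatnonzero(same) + 1
        if bad.size == 0:
            break
        codes[bad] = rng.choice(4, size=bad.size, p=probs)
    return alphabet[codes]


def _plant_footprint(p: int, strand_class: str, spacer_len: int) -> tuple[int, int]:
    """Footprint (spacer + PAM) in forward coordinates, p = PAM-proximal base."""
    if strand_class == "T":  # protospacer on the gene strand, PAM to the right
        return p - spacer_len + 1, p + 4
    return p - 3, p + spacer_len  # NT: protospacer opposite, PAM to the left


def make_fixture(
    n_genes: int,
    background_gc: float,
    seed: int,
    plant_spec: list[PlantSpec],
    cfg: DesignConfig = DesignConfig(),
) -> Fixture:
    """Build a genome of ``n_genes`` contigs, each with the same plants.

    Each gene sits on its own contig (strands alternate +/- across genes)
    and receives every plant in ``plant_spec`` in its promoter, with an
    independently sampled background and independently arranged spacers.
    Deterministic for a fixed seed. Overlapping plants are an error.
    """
    if n_genes < 1:
        raise FixtureError("n_genes must be >= 1")
    if not 0.0 <= background_gc <= 1.0:
        raise FixtureError("background_gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = cfg.spacer_len
    tp = cfg.upstream_bp + cfg.margin_bp + 10  # forward-coordinate TSS position
    contig_len = tp + max(_GENE_BODY_BP, cfg.downstream_bp + cfg.margin_bp + 10)

    # validate plants once: inside the scan window, inside the contig, no overlap
    footprints: list[tuple[int, int]] = []
    for d, gc_count, strand_class in plant_spec:
        if strand_class not in ("NT", "T"):
            raise FixtureError(f"strand_class must be NT or T, got {strand_class!r}")
        if not (-cfg.upstream_bp <= d <= cfg.downstream_bp):
            raise FixtureError(
                f"plant at d={d} outside scan window "
                f"[-{cfg.upstream_bp}, {cfg.downstream_bp}]"
            )
        lo, hi = _plant_footprint(tp + d, strand_class, L)
        if lo < 0 or hi > contig_len:
            raise FixtureError(f"plant at d={d} footprint off contig")
        footprints.append((lo, hi))
    for i, (lo_a, hi_a) in enumerate(footprints):
        for lo_b, hi_b in footprints[i + 1 :]:
            if lo_a < hi_b and lo_b < hi_a:
                raise FixtureError("infeasible plant_spec: overlapping plants")

    genomes: dict[str, GenomeSequence] = {}
    tss_records: list[TssRecord] = []
    rows: list[dict] = []
    for gi in range(n_genes):
        gene_id, contig_id = f"g{gi + 1}", f"chr{gi + 1}"
        gene_strand = "+" if gi % 2 == 0 else "-"
        for _attempt in range(_MAX_RESAMPLE):
            arr = _background(contig_len, background_gc, rng)
            spacers: list[str] = []
            expected: set[tuple[str, int]] = set()  # (strand, start) forward coords
            for d, gc_count, strand_class in plant_spec:
                p = tp + d
                spacer = _spacer_with_gc(gc_count, L, rng)
                spacers.append(spacer)
                if strand_class == "T":
                    arr[p - L + 1 : p + 1] = list(spacer)
                    arr[p + 1 : p + 4] = list("TGG")
                    expected.add(("+", p - L + 1))
                else:
                    arr[p - 3 : p] = list("CCA")
                    arr[p : p + L] = list(reverse_complement(spacer))
                    expected.add(("-", p))
            # neutralize GG/CC pairs created at footprint/background junctions
            # (never touching a base inside another footprint)
            def _in_footprint(pos: int) -> bool:
                return any(lo <= pos < hi for lo, hi in footprints)

            for lo, hi in footprints:
                for edge, bg in ((lo, lo - 1), (hi - 1, hi)):
                    if (
                        0 <= bg < contig_len
                        and not _in_footprint(bg)
                        and arr[bg] == arr[edge]
                        and arr[bg] in "GC"
                    ):
                        arr[bg] = "A"
            seq = "".join(arr)
            if gene_strand == "-":
                seq = reverse_complement(seq)
                tss_pos = contig_len - 1 - tp
                expected = {
                    ("-" if s == "+" else "+", contig_len - (start + L))
                    for s, start in expected
                }
            else:
                tss_pos = tp
            genome = GenomeSequence(contig_id, seq)
            tss = TssRecord(gene_id, contig_id, gene_strand, tss_pos)
            window = extract_scan_window(genome, tss, cfg)
            found = {(h.strand, h.start) for h in find_protospacers(window, L, cfg.pam)}
            if found == expected:
                break
        else:
            raise FixtureError(
                f"gene {gene_id}: could not build collision-free background "
                f"after {_MAX_RESAMPLE} attempts"
            )
        genomes[contig_id] = genome
        tss_records.append(tss)

        # rank the plants under the scoring rules to label 'best' vs 'decoy'
        scored = []
        for (d, gc_count, strand_class), spacer in zip(plant_spec, spacers):
            hit_strand, hit_start = _plant_coords(
                d, strand_class, tp, contig_len, L, gene_strand
            )
            cand = annotate(
                _rehit(window, hit_strand, hit_start, L, cfg), tss,
                cfg.distance_reference,
            )
            scored.append((cand, score_candidate(cand, cfg)))
        ranked = rank_candidates(scored, cfg)
        best_key = (ranked[0][0].protospacer_strand, ranked[0][0].protospacer_start)
        for (d, gc_count, strand_class), spacer in zip(plant_spec, spacers):
            hit = _plant_coords(d, strand_class, tp, contig_len, L, gene_strand)
            rows.append(
                {
                    "gene_id": gene_id,
                    "d_tss": d,
                    "gc_count": gc_count,
                    "strand_class": strand_class,
                    "spacer_seq": spacer,
                    "expected_rank_hint": "best" if hit == best_key else "decoy",
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "d_tss", "gc_count", "strand_class",
            "spacer_seq", "expected_rank_hint",
        ],
    )
    return Fixture(genomes, tuple(tss_records), truth, seed)


def extract_scan_window(
    genome: GenomeSequence, tss: TssRecord, cfg: DesignConfig
) -> PromoterWindow:
    """Promoter window under a config (margin included), via genome_io."""
    from .genome_io import extract_promoter_window

    return extract_promoter_window(
        genome, tss, cfg.upstream_bp, cfg.downstream_bp, cfg.margin_bp
    )


def _plant_coords(
    d: int, strand_class: str, tp: int, contig_len: int, L: int, gene_strand: str
) -> tuple[str, int]:
    """Contig (strand, protospacer_start) of a plant on either gene strand."""
    p = tp + d
    strand, start = ("+", p - L + 1) if strand_class == "T" else ("-", p)
    if gene_strand == "-":
        strand = "-" if strand == "+" else "+"
        start = contig_len - (start + L)
    return strand, start


def _rehit(window: PromoterWindow, strand: str, start: int, L: int, cfg: DesignConfig):
    """Recover the RawHit at known coordinates from the scanned window."""
    for hit in find_protospacers(window, L, cfg.pam):
        if hit.strand == strand and hit.start == start:
            return hit
    raise FixtureError("planted candidate not found on re-scan")


@dataclass(frozen=True)
class PanelFixture:
    """One canonical test panel: a fixture plus the config it is scanned with."""

    name: str
    fixture: Fixture
    config: DesignConfig


def make_panel(seed: int) -> dict[str, PanelFixture]:
    """The three canonical panels mirroring the experimental comparisons.

    ``gc_ladder``: five same-strand guides in the optimal window with GC
    counts 2..18 — rank order must equal GC order. ``dominance``: an
    in-window 45%-GC guide against a 75%-GC guide past the -600 bp cutoff
    (scanned with an 800 bp window so the decoy is enumerated) — the
    in-window guide must win. ``strand_preference``: same-GC NT vs T pair at
    near-identical distances — NT must win. Each panel's truth table labels
    the guide the scoring rules should rank first as 'best'.
    """
    default = DesignConfig()
    wide = DesignConfig(upstream_bp=800)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    panels = {
        "gc_ladder": PanelFixture(
            "gc_ladder",
            make_fixture(
                1, 0.4, int(seeds[0]),
                [(-320, 18, "NT"), (-240, 14, "NT"), (-160, 10, "NT"),
                 (-280, 6, "NT"), (-200, 2, "NT")],
                default,
            ),
            default,
        ),
        "dominance": PanelFixture(
            "dominance",
            make_fixture(1, 0.4, int(seeds[1]), [(-200, 9, "NT"), (-700, 15, "NT")],
                         wide),
            wide,
        ),
        "strand_preference": PanelFixture(
            "strand_preference",
            make_fixture(1, 0.4, int(seeds[2]), [(-190, 12, "NT"), (-210, 12, "T")],
                         default),
            default,
        ),
    }
    return panels
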