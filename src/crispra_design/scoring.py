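"""Design criteria for CRISPRa guides: position, GC and strand scoring.

The scoring model encodes three empirical findings about dCas9-activator
recruitment at promoters:

* **Position dominates.** Guides landing in the optimal upstream window
  (default -450..-150 bp from the TSS) get full position score; the flanking
  regions (down to the hard cutoff at -600 bp, and the proximal stretch up
  to the TSS) score 0.5; anything beyond -600 bp or downstream of the TSS
  scores 0, and a zero position score zeroes the composite regardless of GC
  content or strand — a high-GC guide placed past the cutoff is worthless.
* **GC content helps monotonically**, with no dependence on where in the
  spacer the G/C bases sit; the GC score is simply the GC fraction.
* **NT-strand guides outperform T-strand guides**, so candidates whose
  spacer pairs with the non-template strand receive a bonus.

Composite score: ``S = P * (w0 + w_gc * gc + w_nt * nt)`` with nonnegative
weights summing to one, so S is in [0, 1] and P = 0 forces S = 0.

A separate calibration maps GC fraction to an indicative fold-activation via
log-linear interpolation between two measured anchors (2-fold at GC 0,
35-fold at GC 0.9); values extrapolated above the upper anchor are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .scan import GuideCandidate


class DesignConfig(BaseModel):
    """All tunable parameters of the design pipeline, with field-standard defaults."""

    model_config = ConfigDict(frozen=True)

    upstream_bp: int = Field(default=600, ge=0)
    downstream_bp: int = Field(default=0, ge=0)
    spacer_len: int = Field(default=20, ge=1)
    pam: str = "NGG"
    #: closed interval of d_tss (bp, upstream negative) scoring 1.0
    optimal_window: tuple[int, int] = (-450, -150)
    #: beyond this distance upstream the position score is 0
    hard_cutoff_bp: int = -600
    #: score for the flank regions between cutoff/TSS and the optimal window
    flank_score: float = Field(default=0.5, ge=0.0, le=1.0)
    #: tie-break target: guides nearer this distance rank first at equal score
    optimum_center: int = -200
    w0: float = Field(default=0.2, ge=0.0)
    w_gc: float = Field(default=0.6, gt=0.0)
    w_nt: float = Field(default=0.2, ge=0.0)
    polyt_filter: str = Field(default="flag", pattern="^(off|flag|drop)$")
    distance_reference: str = Field(
        default="pam_proximal", pattern="^(pam_proximal|midpoint|five_prime)$"
    )
    calib_gc_low: float = 0.0
    calib_fold_low: float = 2.0
    calib_gc_high: float = 0.9
    calib_fold_high: float = 35.0
    top_n: int | None = None

    @property
    def margin_bp(self) -> int:
        """Scan margin so protospacers straddling the window edge are found."""
        return self.spacer_len + len(self.pam) - 1

    @model_validator(mode="after")
    def _check(self) -> "DesignConfig":
        if abs(self.w0 + self.w_gc + self.w_nt - 1.0) > 1e-9:
            raise ValueError("weights w0 + w_gc + w_nt must sum to 1")
        lo, hi = self.optimal_window
        if not (self.hard_cutoff_bp < lo <= hi < 0):
            raise ValueError(
                "optimal_window must be nested strictly inside [hard_cutoff_bp, 0]"
            )
        if not (0 < self.calib_fold_low < self.calib_fold_high):
            raise ValueError("calibration folds must be positive and increasing")
        if not (0 <= self.calib_gc_low < self.calib_gc_high <= 1):
            raise ValueError("calibration GC anchors must be ordered in [0, 1]")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        """Load a flat ``key = value`` config file; unset keys keep defaults.

        ``optimal_window`` is given as two comma-separated integers.
        """
        overrides: dict[str, object] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "optimal_window":
                overrides[key] = tuple(int(v) for v in value.split(","))
            else:
                overrides[key] = value
        return cls(**overrides)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ScoreBreakdown:
    position_score: float
    gc_score: float
    nt_indicator: int
    composite: float
    predicted_fold: float
    flags: frozenset[str] = field(default_factory=frozenset)


def position_score(d_tss: int, cfg: DesignConfig) -> float:
    """Piecewise-constant placement score.

    1.0 inside the optimal window (closed interval), ``flank_score`` in the
    flanks between the hard cutoff and the window and between the window and
    the TSS, 0.0 at or downstream of the TSS and beyond the cutoff.
    """
    if d_tss >= 0 or d_tss < cfg.hard_cutoff_bp:
        return 0.0
    lo, hi = cfg.optimal_window
    if lo <= d_tss <= hi:
        return 1.0
    return cfg.flank_score


def gc_score(gc: float) -> float:
    """Identity mapping: the GC fraction itself (strictly monotone, placement-agnostic)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    return gc


def composite_score(p: float, gc: float, nt_indicator: int, cfg: DesignConfig) -> float:
    """S = P * (w0 + w_gc*gc + w_nt*nt); position multiplies, so P=0 forces S=0."""
    return p * (cfg.w0 + cfg.w_gc * gc_score(gc) + cfg.w_nt * nt_indicator)


def predicted_fold_activation(gc: float, cfg: DesignConfig = DesignConfig()) -> float:
    """Indicative fold-activation from GC fraction, log-linear between anchors.

    fold(g) = f_lo * (f_hi / f_lo) ** ((g - g_lo) / (g_hi - g_lo)); with the
    default anchors fold(0) = 2 and fold(0.9) = 35. Values above the upper
    anchor are extrapolations and get flagged by :func:`apply_filters`.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    ratio = cfg.calib_fold_high / cfg.calib_fold_low
    t = (gc - cfg.calib_gc_low) / (cfg.calib_gc_high - cfg.calib_gc_low)
    return cfg.calib_fold_low * ratio**t


def apply_filters(
    candidate: GuideCandidate, cfg: DesignConfig, window_truncated: bool = False
) -> tuple[frozenset[str], bool]:
    """Return (flags, keep) for a candidate.

    ``polyT``: the spacer contains TTTT, a pol III terminator risk for
    U6-driven sgRNA cassettes (dropped only in ``drop`` mode).
    ``extrapolated_gc``: GC above the upper calibration anchor.
    ``truncated_window``: inherited from a clipped promoter window.
    """
    flags: set[str] = set()
    keep = True
    if cfg.polyt_filter != "off" and "TTTT" in candidate.spacer_seq:
        flags.add("polyT")
        if cfg.polyt_filter == "drop":
            keep = False
    if candidate.gc_fraction > cfg.calib_gc_high:
        flags.add("extrapolated_gc")
    if window_truncated:
        flags.add("truncated_window")
    return frozenset(flags), keep


def score_candidate(
    candidate: GuideCandidate, cfg: DesignConfig, window_truncated: bool = False
) -> ScoreBreakdown:
    flags, _keep = apply_filters(candidate, cfg, window_truncated)
    p = position_score(candidate.d_tss, cfg)
    gc = gc_score(candidate.gc_fraction)
    nt = 1 if candidate.strand_class == "NT" else 0
    return ScoreBreakdown(
        position_score=p,
        gc_score=gc,
        nt_indicator=nt,
        composite=composite_score(p, candidate.gc_fraction, nt, cfg),
        predicted_fold=predicted_fold_activation(candidate.gc_fraction, cfg),
        flags=flags,
    )


def rank_candidates(
    scored: Iterable[tuple[GuideCandidate, ScoreBreakdown]],
    cfg: DesignConfig,
) -> list[tuple[GuideCandidate, ScoreBreakdown]]:
    """Deterministic total order over scored candidates.

    Composite score descending; then distance to the optimum center
    ascending (the empirically best placement breaks ties); then GC
    descending; NT before T; contig coordinate ascending; + strand before -.
    Independent of input order.
    """

    def key(item: tuple[GuideCandidate, ScoreBreakdown]):
        cand, brk = item
        return (
            -brk.composite,
            abs(cand.d_tss - cfg.optimum_center),
            -cand.gc_fraction,
            0 if cand.strand_class == "NT" else 1,
            cand.contig_id,
            cand.protospacer_start,
            0 if cand.protospacer_strand == "+" else 1,
        )

    return sorted(scored, key=key)
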