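"""Score one user-supplied guide and show how each criterion contributes.

A guide is described by its 20-nt spacer, its distance to the TSS (measured
to the PAM-proximal base, upstream negative) and the contig strand carrying
the protospacer relative to the gene. The composite score multiplies the
position score by a weighted sum of GC and strand terms, so a bad position
zeroes everything.
"""

from crispra_design import (
    DesignConfig,
    classify_strand,
    composite_score,
    gc_fraction,
    position_score,
    predicted_fold_activation,
)

cfg = DesignConfig()
spacer = "GCGCGCGCATATGCGCATGC"
gc = gc_fraction(spacer)

for d_tss, proto_strand in [(-200, "-"), (-200, "+"), (-100, "-"), (-700, "-")]:
    strand_class = classify_strand(proto_strand, gene_strand="+")
    p = position_score(d_tss, cfg)
    nt = 1 if strand_class == "NT" else 0
    s = composite_score(p, gc, nt, cfg)
    print(f"d={d_tss:>5}  class={strand_class:<2}  position={p:<4}"
          f"  composite={s:.3f}  predicted_fold={predicted_fold_activation(gc):.1f}")

# The same 70%-GC spacer scores 0.82 at -200 bp on the NT strand, drops to
# 0.62 when its protospacer sits on the gene strand (class T, no strand
# bonus), halves in the proximal flank, and scores 0 beyond -600 bp: the
# placement term dominates GC and strand. The fold value depends on GC only.
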