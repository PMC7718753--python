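"""Reproduce the three ordinal comparisons the scoring rules encode.

make_panel builds three seeded fixtures: a same-region GC ladder (rank order
must follow GC), an in-window 45%-GC guide against a 75%-GC guide beyond the
-600 bp cutoff (placement must dominate), and an NT/T pair of equal GC
(the non-template-strand guide must win).
"""

from crispra_design import design_guides, make_panel

for name, pf in make_panel(seed=7).items():
    report = design_guides(pf.fixture.genomes, pf.fixture.tss_records, pf.config)
    print(f"\n{name}:")
    for rank, (cand, brk) in enumerate(report.results[0].candidates, start=1):
        print(f"  rank {rank}: d={cand.d_tss:>5}  GC={cand.gc_fraction:.2f}  "
              f"{cand.strand_class:<2}  score={brk.composite:.3f}")

# gc_ladder ranks strictly by GC; dominance puts the in-window guide first
# with the beyond-cutoff 75%-GC guide scored 0; strand_preference puts NT
# above T at equal GC.
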