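"""Shared fixtures and the independent brute-force protospacer oracle.

The oracle is a regex lookahead scan over the window and its reverse
complement, written without reference to the production scanner so the two
can disagree.
"""

from __future__ import annotations

import re

import pytest

from crispra_design.genome_io import PromoterWindow, TssRecord

_RC = str.maketrans("ACGTN", "TGCAN")

_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def oracle_scan(window_seq: str, window_start: int, spacer_len: int = 20,
                pam: str = "NGG") -> set[tuple[str, str, str, int]]:
    """All (spacer, pam, strand, contig_start) placements, by regex lookahead.

    The forward scan matches spacer+PAM left to right; the reverse scan runs
    the same regex over the reverse complement and maps match positions back
    to contig coordinates.
    """
    pam_re = "".join(_IUPAC_RE[c] for c in pam)
    pattern = re.compile(rf"(?=([ACGT]{{{spacer_len}}})({pam_re}))")
    hits: set[tuple[str, str, str, int]] = set()
    for m in pattern.finditer(window_seq):
        hits.add((m.group(1), m.group(2), "+", window_start + m.start()))
    rc = window_seq.translate(_RC)[::-1]
    n = len(window_seq)
    for m in pattern.finditer(rc):
        # spacer occupies rc[j : j+L]; on the contig that is
        # [n - j - L, n - j) shifted by window_start
        j = m.start()
        hits.add((m.group(1), m.group(2), "-",
                  window_start + n - j - spacer_len))
    return hits


def random_window(rng, length: int = 1000, gc: float = 0.5,
                  window_start: int = 0) -> PromoterWindow:
    """A random promoter window with i.i.d. bases at the given GC level."""
    import numpy as np

    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
    tss = TssRecord("g", "c", "+", window_start + length - 1)
    return PromoterWindow(tss, window_start, window_start + length, seq)


@pytest.fixture
def plus_tss() -> TssRecord:
    return TssRecord("g1", "c1", "+", 1000)


@pytest.fixture
def minus_tss() -> TssRecord:
    return TssRecord("g2", "c1", "-", 1000)
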