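"""Independent brute-force oracles used to freeze expected values.

These deliberately share no code with the package: motif matching tests
every window character by character against literal degenerate sets, and
the hypergeometric tail is an exact integer enumeration.
"""

from fractions import Fraction
from math import comb

DEGENERATE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "M": "AC", "K": "GT", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def window_matches(consensus: str, window: str) -> bool:
    return len(window) == len(consensus) and all(
        b in DEGENERATE[c] for c, b in zip(consensus.upper(), window.upper())
    )


def brute_scan(consensus: str, seq: str, both_strands: bool = True):
    """All (start, strand) occurrences, testing each window directly.

    The minus strand is checked by reverse-complementing the *window* and
    matching it against the consensus.
    """
    l = len(consensus)
    out = []
    for start in range(len(seq) - l + 1):
        window = seq[start:start + l].upper()
        if window_matches(consensus, window):
            out.append((start, "+"))
        if both_strands:
            rc = "".join(COMP.get(b, "?") for b in reversed(window))
            if window_matches(consensus, rc):
                out.append((start, "-"))
    return out


def exact_hypergeom_upper(m: int, M: int, k: int, K: int) -> float:
    """P(X >= m) by exact integer enumeration of the hypergeometric pmf."""
    num = sum(comb(k, i) * comb(K - k, M - i)
              for i in range(m, min(k, M) + 1)
              if M - i <= K - k)
    return float(Fraction(num, comb(K, M)))
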