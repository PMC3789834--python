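"""IUPAC consensus motifs and occurrence scanning over promoter sets.

A motif is a short consensus word over ``A, C, G, T`` plus the wobble codes
``r`` (A/G), ``y`` (C/T), ``s`` (G/C), ``w`` (A/T), ``m`` (A/C), ``k`` (G/T)
and ``n`` (any base).  Scanning enumerates *all* (possibly overlapping)
windows that match the consensus; each hit is reported with the midpoint of
the matched window on the TSS-anchored promoter axis.  An ``N`` in the
sequence matches nothing, including the wobble ``n`` in the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Set, Tuple

from .promoters import PromoterSet

__all__ = ["Motif", "MotifHit", "parse_motif", "scan", "presence_counts"]

# Degenerate-base map, exactly the wobble alphabet used for plant promoter
# motifs; B/D/H/V are deliberately not accepted.
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "M": "AC", "K": "GT", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWMKN", "TGCAYRSWKMN")


@dataclass(frozen=True)
class Motif:
    """A validated IUPAC consensus word.

    Attributes
    ----------
    consensus : str
        The consensus, stored uppercase.
    name : str
        A label used in output tables (defaults to the consensus itself).
    """

    consensus: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", self.consensus.upper())
        if not self.name:
            object.__setattr__(self, "name", self.consensus)
        for ch in self.consensus:
            if ch not in IUPAC:
                raise ValueError(
                    f"illegal IUPAC symbol {ch!r} in motif {self.consensus!r}"
                )
        if len(self.consensus) < 2:
            raise ValueError(
                f"motif {self.consensus!r} too short (length must be >= 2)"
            )

    @property
    def length(self) -> int:
        return len(self.consensus)

    def reverse_complement(self) -> str:
        """Consensus of the reverse complement (degenerate codes mapped)."""
        return self.consensus.translate(_COMPLEMENT)[::-1]

    def matches(self, window: str) -> bool:
        """Character-by-character degenerate match (window on + strand)."""
        if len(window) != self.length:
            return False
        return all(b in IUPAC[c] for c, b in zip(self.consensus, window.upper()))


class MotifHit(NamedTuple):
    """One motif occurrence on a promoter.

    ``midpoint`` is the center of the matched window relative to the TSS
    (0 at the TSS, negative upstream); an even-length motif gives a
    half-integer midpoint.  A minus-strand hit carries the same midpoint as
    its plus-strand coordinates — position relative to the TSS is
    strand-free.
    """

    gene_id: str
    midpoint: float
    strand: str


def parse_motif(consensus: str, name: str = "") -> Motif:
    """Validate an IUPAC consensus string and return a :class:`Motif`."""
    if not consensus:
        raise ValueError("empty motif consensus")
    return Motif(consensus=consensus, name=name)


def _regex(consensus: str) -> re.Pattern:
    # Lookahead so overlapping windows are all found.  Character classes
    # contain only A/C/G/T, so sequence N never matches.
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in consensus) + ")")


def _midpoint(seq_len: int, start: int, l: int) -> float:
    # Bases are counted 1, 2, ... upstream from the TSS (3' end of record);
    # the window center is -(dist_5' + dist_3')/2.
    return -(2 * seq_len - 2 * start - l + 1) / 2


def scan(
    motif: Motif,
    promoters: PromoterSet,
    strand_mode: str = "both",
) -> Dict[str, List[MotifHit]]:
    """Enumerate all motif occurrences per gene.

    Parameters
    ----------
    strand_mode : {"both", "forward"}
        ``both`` additionally matches the reverse complement of each window
        against the consensus; a palindromic motif then reports two hits at
        the same midpoint.

    Returns
    -------
    dict mapping every gene id to its (possibly empty) hit list, ordered
    5'->3' with ``+`` before ``-`` at equal start.
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"strand_mode must be 'both' or 'forward', got {strand_mode!r}")
    l = motif.length
    fwd = _regex(motif.consensus)
    rev = _regex(motif.reverse_complement()) if strand_mode == "both" else None
    hits: Dict[str, List[MotifHit]] = {}
    for gene, seq in promoters.items():
        found: List[Tuple[int, int]] = [(m.start(), 0) for m in fwd.finditer(seq)]
        if rev is not None:
            found.extend((m.start(), 1) for m in rev.finditer(seq))
        found.sort()
        n = len(seq)
        hits[gene] = [
            MotifHit(gene, _midpoint(n, start, l), "+" if s == 0 else "-")
            for start, s in found
        ]
    return hits


def presence_counts(
    motif: Motif,
    promoters: PromoterSet,
    gene_subset: Optional[Iterable[str]] = None,
    strand_mode: str = "both",
    hits: Optional[Dict[str, List[MotifHit]]] = None,
) -> Tuple[Set[str], int, int]:
    """Presence/absence summary over a promoter set.

    Returns ``(m_set, k, K)`` where ``K`` is the total number of promoters
    in the whole set, ``k`` the number containing at least one occurrence,
    and ``m_set`` the genes of ``gene_subset`` (default: all) with a hit.
    Precomputed ``hits`` from :func:`scan` may be passed to avoid rescanning.
    """
    if hits is None:
        hits = scan(motif, promoters, strand_mode=strand_mode)
    present = {g for g, hs in hits.items() if hs}
    K = len(promoters)
    k = len(present)
    if gene_subset is None:
        m_set = set(present)
    else:
        m_set = present.intersection(gene_subset)
    return m_set, k, K
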