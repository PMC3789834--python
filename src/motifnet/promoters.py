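"""Promoter sequence sets anchored at the transcription start site.

Every downstream position computation relies on one coordinate convention,
fixed here: the *last* base of each stored sequence abuts the TSS.  A position
``p`` on the promoter axis is measured in bp relative to the TSS, with
``p = 0`` at the TSS and negative values upstream, so a nominal-length
promoter spans ``[-L, 0]``.  Sequences shorter than the nominal length
(truncated upstream regions) are kept and remain anchored at their 3' end.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterSet",
    "tair_locus_id",
    "read_promoters",
    "write_promoters",
    "promoter_length",
]

_VALID = re.compile(r"^[ACGTN]*$")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


def tair_locus_id(header: str) -> str:
    """Extract a locus identifier from a TAIR-style FASTA header.

    Takes the token before the first ``|`` or whitespace, uppercases it and
    strips a trailing transcript suffix (``AT1G01010.1`` -> ``AT1G01010``).
    """
    token = re.split(r"[\s|]", header.strip(), maxsplit=1)[0]
    return _TRANSCRIPT_SUFFIX.sub("", token.upper())


@dataclass
class PromoterSet:
    """Gene-indexed upstream sequences with a TSS-anchored coordinate axis.

    Parameters
    ----------
    records : dict
        Maps gene id to an uppercase DNA string over ``{A, C, G, T, N}``.
    nominal_length : int
        The nominal promoter length ``L`` in bp (default 1000).  Individual
        records may be shorter; none should be longer.
    """

    records: Dict[str, str] = field(default_factory=dict)
    nominal_length: int = 1000

    def __post_init__(self) -> None:
        for gene, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for gene {gene!r}")
            if not _VALID.match(seq):
                bad = _NON_ACGTN.search(seq).group()
                raise ValueError(
                    f"sequence for gene {gene!r} contains invalid character {bad!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> str:
        return self.records[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def items(self):
        return self.records.items()


def read_promoters(
    path,
    id_parser: Callable[[str], str] = tair_locus_id,
    nominal_length: int = 1000,
    invalid_chars: str = "error",
) -> PromoterSet:
    """Read a multi-record promoter FASTA into a :class:`PromoterSet`.

    Parameters
    ----------
    path : str or Path
        FASTA file, wrapped or unwrapped lines.
    id_parser : callable
        Maps a raw FASTA header to a gene id.  Default is the TAIR dialect.
    nominal_length : int
        Nominal promoter length ``L``.
    invalid_chars : {"error", "mask"}
        Whether characters outside ``{A,C,G,T,N}`` abort the read or are
        mapped to ``N``.

    Raises
    ------
    ValueError
        On an empty file, or when two records with identical raw ids map to
        the same gene id.  Distinct records (e.g. two transcript models of
        one locus) that collapse to one id keep the first and warn.
    """
    if invalid_chars not in ("error", "mask"):
        raise ValueError(f"invalid_chars must be 'error' or 'mask', got {invalid_chars!r}")
    records: Dict[str, str] = {}
    raw_ids: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = id_parser(rec.description)
        seq = str(rec.seq).upper()
        if invalid_chars == "mask":
            seq = _NON_ACGTN.sub("N", seq)
        if gene in records:
            if rec.id == raw_ids[gene]:
                raise ValueError(f"duplicate gene id {gene!r} (record {rec.id!r})")
            warnings.warn(
                f"multiple records map to locus {gene!r}; keeping the first ({raw_ids[gene]!r})",
                stacklevel=2,
            )
            continue
        records[gene] = seq
        raw_ids[gene] = rec.id
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return PromoterSet(records=records, nominal_length=nominal_length)


def write_promoters(promoters: PromoterSet, path) -> None:
    """Write a PromoterSet back to FASTA (one unwrapped sequence per record)."""
    recs = (
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.items()
    )
    SeqIO.write(recs, str(path), "fasta-2line")


def promoter_length(promoters: PromoterSet, gene: str) -> int:
    """Actual sequence length for ``gene`` (may be < nominal_length)."""
    try:
        return len(promoters.records[gene])
    except KeyError:
        raise KeyError(f"gene {gene!r} has no promoter record") from None
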