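"""Term over-representation in called modules.

Reuses the same upper-tail hypergeometric statistic as the motif enrichment:
for a module of M genes and an annotation term covering k of the K universe
genes, the pValue is P(overlap >= m).  Raw pValues are reported; a
Benjamini-Hochberg column is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import pandas as pd
from scipy.stats import false_discovery_control

from .stats import hypergeom_pvalue

__all__ = ["AnnotationMap", "read_annotation", "enrich_module"]


@dataclass
class AnnotationMap:
    """Term -> gene-set map over a gene universe.

    Terms with no annotated gene inside the universe are dropped; every
    annotated gene is clipped to the universe.
    """

    terms: Dict[str, Set[str]]
    universe: Set[str]
    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clipped = {}
        for term, genes in self.terms.items():
            inside = set(genes) & self.universe
            if inside:
                clipped[term] = inside
        self.terms = clipped

    def __len__(self) -> int:
        return len(self.terms)


def read_annotation(
    path,
    universe: Optional[Iterable[str]] = None,
) -> AnnotationMap:
    """Read a 2-column (gene, term) TSV; a third column, if present, is the
    term label.  When ``universe`` is omitted it defaults to all annotated
    genes."""
    terms: Dict[str, Set[str]] = {}
    labels: Dict[str, str] = {}
    genes_seen: Set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            gene, term = parts[0], parts[1]
            terms.setdefault(term, set()).add(gene)
            genes_seen.add(gene)
            if len(parts) >= 3 and parts[2]:
                labels[term] = parts[2]
    uni = set(universe) if universe is not None else genes_seen
    return AnnotationMap(terms=terms, universe=uni, labels=labels)


def enrich_module(
    module: Iterable[str],
    annot: AnnotationMap,
    bh: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term in one module.

    Module genes outside the universe are dropped (their count is exposed in
    the ``dropped`` attribute of the returned frame).  Rows are sorted by
    ascending pValue, then term id.  With ``bh=True`` a ``qValue`` column of
    Benjamini-Hochberg adjusted pValues is appended.
    """
    module_set = set(module)
    inside = module_set & annot.universe
    dropped = len(module_set) - len(inside)
    K = len(annot.universe)
    M = len(inside)
    rows = []
    for term in sorted(annot.terms):
        term_genes = annot.terms[term]
        k = len(term_genes)
        m = len(inside & term_genes)
        pvalue = hypergeom_pvalue(m, M, k, K) if M > 0 else 1.0
        rows.append(
            (term, annot.labels.get(term, ""), m, M, k, K, pvalue)
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "label", "overlap", "module_size", "term_size",
                 "universe_size", "pValue"],
    )
    if M == 0:
        df = df.iloc[0:0]
    df = df.sort_values(["pValue", "term"], kind="mergesort").reset_index(drop=True)
    if bh and len(df):
        df["qValue"] = false_discovery_control(df["pValue"], method="bh")
    df.attrs["dropped"] = dropped
    return df
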