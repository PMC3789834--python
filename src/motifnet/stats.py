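"""Per-gene motif statistics over network neighborhoods.

For every gene in the network, the gene together with its directly connected
neighbors forms a group of M promoters, m of which contain the motif.  Among
all K promoters genome-wide the motif occurs in k.  Two independent scores
rank genes by their chance of sitting in an expression module driven by the
motif:

* **Enrichment pValue** — the upper tail P(X >= m) of the hypergeometric
  distribution with population K, k successes and M draws.

* **Position-bias z-score** — pool all n motif midpoints in the group's
  promoters; under the null the midpoint of an l-bp motif in an L-bp
  promoter is uniform on [-L + l/2, -l/2], so the mean has expectation
  mu0 = -L/2 and standard deviation (L - l)/sqrt(12)/sqrt(n).  Then

      z = (p_bar - mu0) * sqrt(n) / ((L - l)/sqrt(12)),

  positive when hits crowd toward the TSS, near zero for an even spread.

Seed selection applies an inclusive cutoff (pValue <= c, or z >= c), with an
optional instance floor for intermediate z values and OR-combination across
motif variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .motifs import Motif, MotifHit, presence_counts, scan
from .network import CoexpressionNetwork, degree_filter, neighborhood
from .promoters import PromoterSet

__all__ = [
    "GeneMotifStat",
    "hypergeom_pvalue",
    "position_zscore",
    "score_gene",
    "score_all",
    "select_seeds",
]

STAT_COLUMNS = ["gene", "motif", "M", "m", "k", "K", "pValue", "n", "p_bar", "z"]


@dataclass(frozen=True)
class GeneMotifStat:
    """Joint record of both statistics for one (gene, motif) pair."""

    gene_id: str
    motif: str
    M: int
    m: int
    k: int
    K: int
    pValue: float
    n: int
    p_bar: float  # nan when n == 0
    z: float      # nan when n == 0


def hypergeom_pvalue(m: int, M: int, k: int, K: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    X counts motif-containing promoters in a draw of M from a population of
    K promoters of which k contain the motif.
    """
    if not (0 <= m <= M <= K):
        raise ValueError(f"need 0 <= m <= M <= K, got m={m}, M={M}, K={K}")
    if not (m <= k <= K):
        raise ValueError(f"need m <= k <= K, got m={m}, k={k}, K={K}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, K, k, M))


def position_zscore(
    positions: Sequence[float],
    L: int,
    l: int,
    discrete: bool = False,
) -> Tuple[int, float, float]:
    """Standardize the mean motif midpoint against the uniform null.

    Parameters
    ----------
    positions : sequence of float
        Motif midpoints in bp relative to the TSS, each in [-L, 0].
    L, l : int
        Promoter and motif lengths in bp (l < L).
    discrete : bool
        Use the discrete-uniform variance ((L-l+1)^2 - 1)/12 instead of the
        continuous (L-l)^2/12.  At L = 1000 the two differ by < 0.1%.

    Returns
    -------
    (n, p_bar, z); ``p_bar`` and ``z`` are nan when n == 0.
    """
    if not l < L:
        raise ValueError(f"need motif length l < promoter length L, got l={l}, L={L}")
    n = len(positions)
    if n == 0:
        return 0, math.nan, math.nan
    arr = np.asarray(positions, dtype=float)
    if arr.min() < -L or arr.max() > 0:
        raise ValueError(
            f"positions must lie in [-{L}, 0], got range "
            f"[{arr.min():g}, {arr.max():g}]"
        )
    p_bar = float(arr.mean())
    mu0 = -L / 2
    if discrete:
        sigma0 = math.sqrt(((L - l + 1) ** 2 - 1) / 12)
    else:
        sigma0 = (L - l) / math.sqrt(12)
    z = (p_bar - mu0) * math.sqrt(n) / sigma0
    return n, p_bar, z


def _group_stats(
    group: Iterable[str],
    promoters: PromoterSet,
    hits: Dict[str, List[MotifHit]],
    k: int,
    K: int,
    motif: Motif,
    L: int,
    discrete: bool = False,
) -> Tuple[int, int, float, int, float, float]:
    """(M, m, pValue, n, p_bar, z) for one neighborhood group.

    Group members without a promoter record are excluded from M and from
    position pooling; promoters shorter than 2*l are kept for presence
    counting but skipped for position pooling.
    """
    members = [g for g in group if g in promoters]
    M = len(members)
    if M == 0:
        raise ValueError("no group member has a promoter record")
    m = sum(1 for g in members if hits.get(g))
    pvalue = hypergeom_pvalue(m, M, k, K)
    positions: List[float] = []
    min_len = 2 * motif.length
    for g in members:
        if len(promoters[g]) < min_len:
            continue
        positions.extend(h.midpoint for h in hits.get(g, ()))
    n, p_bar, z = position_zscore(positions, L, motif.length, discrete=discrete)
    return M, m, pvalue, n, p_bar, z


def score_gene(
    net: CoexpressionNetwork,
    promoters: PromoterSet,
    motif: Motif,
    gene: str,
    strand_mode: str = "both",
    discrete: bool = False,
    _hits: Optional[Dict[str, List[MotifHit]]] = None,
    _presence: Optional[Tuple[set, int, int]] = None,
) -> GeneMotifStat:
    """Score a single gene's neighborhood group for one motif.

    The gene need not have a promoter record itself as long as at least one
    group member does.  ``_hits``/``_presence`` allow reuse of a genome-wide
    scan across calls.
    """
    hits = _hits if _hits is not None else scan(motif, promoters, strand_mode)
    if _presence is not None:
        _, k, K = _presence
    else:
        _, k, K = presence_counts(motif, promoters, hits=hits)
    group = neighborhood(net, gene)
    L = promoters.nominal_length
    M, m, pvalue, n, p_bar, z = _group_stats(
        group, promoters, hits, k, K, motif, L, discrete=discrete
    )
    return GeneMotifStat(gene, motif.name, M, m, k, K, pvalue, n, p_bar, z)


def score_all(
    net: CoexpressionNetwork,
    promoters: PromoterSet,
    motifs: Sequence[Motif],
    min_degree: int = 5,
    strand_mode: str = "both",
    discrete: bool = False,
) -> pd.DataFrame:
    """Score every qualifying gene against every motif.

    Returns one row per (gene with degree >= ``min_degree``) x motif, ordered
    by motif then gene, with columns
    ``gene, motif, M, m, k, K, pValue, n, p_bar, z``.
    """
    genes = degree_filter(net, min_degree)
    L = promoters.nominal_length
    rows = []
    for motif in motifs:
        hits = scan(motif, promoters, strand_mode=strand_mode)
        _, k, K = presence_counts(motif, promoters, hits=hits)
        for gene in genes:
            group = neighborhood(net, gene)
            members = [g for g in group if g in promoters]
            if not members:
                continue
            M, m, pvalue, n, p_bar, z = _group_stats(
                group, promoters, hits, k, K, motif, L, discrete=discrete
            )
            rows.append((gene, motif.name, M, m, k, K, pvalue, n, p_bar, z))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def select_seeds(
    stats: pd.DataFrame,
    mode: str,
    cutoff: float,
    min_instances_rule: Optional[Tuple[float, float, int]] = None,
) -> List[str]:
    """Select seed genes from a score table, inclusively at the cutoff.

    ``mode="pvalue"`` keeps genes with pValue <= cutoff; ``mode="zscore"``
    keeps genes with z >= cutoff, and, when ``min_instances_rule =
    (z_low, z_high, n_min)`` is given, genes with z in [z_low, z_high)
    additionally need n >= n_min pooled instances.  With several motif
    variants in the table a gene is selected if ANY variant passes.
    Returns a sorted gene list.
    """
    if mode == "pvalue":
        mask = stats["pValue"] <= cutoff
    elif mode == "zscore":
        z = stats["z"]
        mask = z >= cutoff
        if min_instances_rule is not None:
            z_low, z_high, n_min = min_instances_rule
            in_band = (z >= z_low) & (z < z_high)
            mask &= ~in_band | (stats["n"] >= n_min)
    else:
        raise ValueError(f"unknown selection mode {mode!r} (use 'pvalue' or 'zscore')")
    return sorted(stats.loc[mask, "gene"].unique())
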