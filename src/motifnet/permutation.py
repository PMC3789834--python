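"""Promoter-randomization null and permutation FDR estimation.

Each replicate randomizes the promoter set in two steps: every sequence is
shuffled within itself (base composition per sequence preserved exactly),
and the shuffled sequences are then reassigned to gene ids by a uniform
random bijection.  Running the full scoring + selection + module-calling
pipeline on such replicates yields how many seed genes and modules arise by
chance; the FDR is the ratio of the replicate mean to the observed count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .motifs import Motif
from .network import CoexpressionNetwork, detect_modules, extract_subnetwork
from .promoters import PromoterSet
from .stats import score_all, select_seeds

__all__ = ["PermutationResult", "shuffle_promoters", "estimate_fdr"]


@dataclass
class PermutationResult:
    """Counts from a promoter-randomization experiment.

    ``fdr_genes`` is mean(replicate seed counts) / observed seed count;
    ``fdr_modules`` likewise for module counts at the configured size floor
    (nan when no module was observed).  Plain ratios of means, with no
    smoothing, so values above 1 are possible under the null.
    """

    n_perm: int
    gene_counts: List[int]
    module_counts: List[int]
    observed_genes: int
    observed_modules: int
    fdr_genes: float
    fdr_modules: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "gene_counts": self.gene_counts,
            "module_counts": self.module_counts,
            "observed_genes": self.observed_genes,
            "observed_modules": self.observed_modules,
            "fdr_genes": self.fdr_genes,
            "fdr_modules": self.fdr_modules,
            "seed": self.seed,
        }


def shuffle_promoters(
    promoters: PromoterSet,
    seed: Union[int, np.random.Generator],
) -> PromoterSet:
    """Within-sequence shuffle followed by bijective reassignment to genes.

    The multiset of per-sequence (length, base-count) vectors is conserved
    exactly; the same seed always yields the same output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(promoters.records)
    shuffled = []
    for g in genes:
        arr = np.frombuffer(promoters[g].encode("ascii"), dtype=np.uint8)
        shuffled.append(rng.permutation(arr).tobytes().decode("ascii"))
    order = rng.permutation(len(genes))
    records = {genes[i]: shuffled[order[i]] for i in range(len(genes))}
    return PromoterSet(records=records, nominal_length=promoters.nominal_length)


def estimate_fdr(
    net: CoexpressionNetwork,
    promoters: PromoterSet,
    motifs: Sequence[Motif],
    mode: str,
    cutoff: float,
    min_instances_rule: Optional[Tuple[float, float, int]] = None,
    n_perm: int = 15,
    min_module_size: int = 5,
    min_degree: int = 5,
    strand_mode: str = "both",
    seed: int = 0,
) -> PermutationResult:
    """Estimate gene- and module-level FDR by promoter randomization.

    The observed analysis and every replicate run the identical pipeline:
    score all qualifying genes, select seeds at the inclusive cutoff,
    extract the seed-induced sub-network and count modules of at least
    ``min_module_size`` genes.

    Raises
    ------
    ValueError
        If the observed analysis selects zero genes — the gene-level FDR is
        then undefined.
    """

    def run_pipeline(pset: PromoterSet) -> Tuple[int, int]:
        stats = score_all(net, pset, motifs, min_degree=min_degree, strand_mode=strand_mode)
        seeds = select_seeds(stats, mode, cutoff, min_instances_rule)
        sub = extract_subnetwork(net, seeds)
        mods = detect_modules(sub, min_size=min_module_size)
        return len(seeds), len(mods)

    observed_genes, observed_modules = run_pipeline(promoters)
    if observed_genes == 0:
        raise ValueError("observed selection is empty; FDR is undefined")

    child_seeds = np.random.SeedSequence(seed).spawn(n_perm)
    gene_counts: List[int] = []
    module_counts: List[int] = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        gc, mc = run_pipeline(shuffle_promoters(promoters, rng))
        gene_counts.append(gc)
        module_counts.append(mc)

    fdr_genes = float(np.mean(gene_counts)) / observed_genes
    if observed_modules > 0:
        fdr_modules = float(np.mean(module_counts)) / observed_modules
    else:
        fdr_modules = math.nan
    return PermutationResult(
        n_perm=n_perm,
        gene_counts=gene_counts,
        module_counts=module_counts,
        observed_genes=observed_genes,
        observed_modules=observed_modules,
        fdr_genes=fdr_genes,
        fdr_modules=fdr_modules,
        seed=seed,
    )
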