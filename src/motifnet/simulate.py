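"""Synthetic promoter sets and co-expression networks with planted modules.

The generator emulates the study conditions every pipeline stage is tested
against: i.i.d. background promoters at a fixed (AT-rich) base composition,
a sparse Erdős–Rényi background network, and a handful of planted modules —
densely wired gene groups whose promoters carry extra motif occurrences,
placed either uniformly (enrichment-only regime) or with a truncated-
exponential pull toward the TSS (position-bias regime).  The ground truth
(module memberships and planted midpoints) is recorded so recovery can be
scored.

Planted instances may collide with spontaneous background matches; truth
records planted positions only, and recovery is judged on gene-level module
membership, never per-hit identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .motifs import IUPAC, Motif, parse_motif
from .network import CoexpressionNetwork
from .promoters import PromoterSet

__all__ = ["SimulationConfig", "SyntheticTruth", "generate", "write_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 2,000 genes, three planted modules of 20 genes each, 1,000-bp
    promoters with base frequencies A/T = 0.33 and C/G = 0.17 (AT-rich plant
    promoters), on average two planted motif instances per module gene pulled
    toward the TSS with a 100-bp exponential scale, module wiring density
    0.4 against background density 0.002.
    """

    n_genes: int = 2000
    module_sizes: Tuple[int, ...] = (20, 20, 20)
    motif: str = "CACGTG"
    motif_name: str = ""
    promoter_length: int = 1000
    base_freqs: Tuple[float, float, float, float] = (0.33, 0.17, 0.17, 0.33)
    lambda_planted: float = 2.0
    tau: float = 100.0
    placement: str = "tss"  # "tss" (biased) or "uniform" (enrichment-only)
    p_module: float = 0.4
    p_background: float = 0.002
    pcor_threshold: float = 0.05

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("planted modules exceed the gene count")
        for p in (self.p_module, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.placement not in ("tss", "uniform"):
            raise ValueError("placement must be 'tss' or 'uniform'")
        motif = parse_motif(self.motif, self.motif_name)  # validates
        if motif.length > self.promoter_length:
            raise ValueError("motif longer than the promoter")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute any planted quantity."""

    module_members: List[List[str]]
    planted_positions: Dict[str, List[float]]  # gene -> planted midpoints
    config: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(**d)


def _resolve_wobbles(consensus: str, rng: np.random.Generator) -> str:
    """One concrete instantiation of the consensus (wobbles drawn uniformly)."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in consensus
    )


def generate(
    config: SimulationConfig,
    seed: int,
) -> Tuple[PromoterSet, CoexpressionNetwork, SyntheticTruth]:
    """Draw one dataset: promoters, network and ground truth.

    The first ``sum(module_sizes)`` genes are the planted module members.
    Planted occurrence counts are Poisson(``lambda_planted``) per module
    gene; start positions are uniform, or, in the ``tss`` regime, the
    distance of the motif's 3' end from the TSS is truncated-exponential
    with scale ``tau``.  Module gene pairs gain an edge with probability
    ``p_module``, all pairs with probability ``p_background``.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    L = cfg.promoter_length
    motif = parse_motif(cfg.motif, cfg.motif_name)
    l = motif.length
    n = cfg.n_genes
    width = len(str(max(n - 1, 1)))
    genes = [f"G{i:0{width}d}" for i in range(n)]

    # --- promoters: i.i.d. background bases
    idx = rng.choice(4, size=(n, L), p=list(cfg.base_freqs))
    seqs = _BASES[idx]  # (n, L) uint8

    # --- planted modules
    module_members: List[List[str]] = []
    start = 0
    for size in cfg.module_sizes:
        module_members.append(genes[start:start + size])
        start += size
    member_index = {g: i for i, g in enumerate(genes)}

    planted: Dict[str, List[float]] = {}
    for members in module_members:
        for g in members:
            count = rng.poisson(cfg.lambda_planted)
            if count == 0:
                continue
            row = member_index[g]
            midpoints = []
            for _ in range(count):
                if cfg.placement == "uniform":
                    j = int(rng.integers(0, L - l + 1))
                else:
                    # distance of the 3'-most base from the TSS, in (0, L-l]
                    d = rng.exponential(cfg.tau)
                    while d > L - l:
                        d = rng.exponential(cfg.tau)
                    j = L - l - int(d)
                word = _resolve_wobbles(motif.consensus, rng)
                seqs[row, j:j + l] = np.frombuffer(word.encode(), dtype=np.uint8)
                midpoints.append(-(2 * L - 2 * j - l + 1) / 2)
            planted[g] = sorted(midpoints)

    records = {
        g: seqs[i].tobytes().decode("ascii") for i, g in enumerate(genes)
    }
    promoters = PromoterSet(records=records, nominal_length=L)

    # --- network: ER background plus dense within-module edges
    g = nx.Graph()
    g.add_nodes_from(genes)
    n_pairs = n * (n - 1) // 2
    # background edges by index over the upper triangle
    mask = rng.random(n_pairs) < cfg.p_background
    pair_ids = np.nonzero(mask)[0]
    # decode triangular index -> (i, j), i < j
    i_idx = (n - 2 - np.floor(
        np.sqrt(-8 * pair_ids.astype(float) + 4 * n * (n - 1) - 7) / 2 - 0.5
    )).astype(int)
    j_idx = (pair_ids + i_idx + 1 - i_idx * (2 * n - i_idx - 1) // 2).astype(int)
    for i, j in zip(i_idx, j_idx):
        w = rng.uniform(cfg.pcor_threshold, 0.15) * rng.choice([-1.0, 1.0])
        g.add_edge(genes[i], genes[j], pcor=float(w))
    for members in module_members:
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if rng.random() < cfg.p_module:
                    w = rng.uniform(0.1, 0.5)
                    g.add_edge(members[a_i], members[b_i], pcor=float(w))
    net = CoexpressionNetwork(graph=g, pcor_threshold=cfg.pcor_threshold)

    truth = SyntheticTruth(
        module_members=module_members,
        planted_positions=planted,
        config=asdict(cfg),
        seed=seed,
    )
    return promoters, net, truth


def write_dataset(outdir, promoters: PromoterSet, net: CoexpressionNetwork,
                  truth: SyntheticTruth) -> None:
    """Write FASTA + edge TSV + truth JSON into ``outdir``."""
    import os

    from .promoters import write_promoters

    os.makedirs(outdir, exist_ok=True)
    write_promoters(promoters, os.path.join(outdir, "promoters.fa"))
    with open(os.path.join(outdir, "network.tsv"), "w") as fh:
        fh.write("geneA\tgeneB\tpcor\n")
        for a, b, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['pcor']:.6g}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
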