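"""Inverse miRNA-target pairing, hub-miRNA selection and edge pruning.

Candidate miRNAs of one role are paired against candidate genes of the
opposite role through a static interaction table (miRDIP-like, opaque
confidence in [0, 1]): TS miRNAs against OG genes, OG miRNAs against TS
genes. The miRNAs with the most candidate targets become the network hubs
(default: top 5); per gene, only the highest-confidence incident edges are
kept (default: top 2) so the rendered network stays legible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import InteractionTable
from .errors import ParameterError
from .survival import CandidateSet

logger = logging.getLogger(__name__)


@dataclass
class PairingResult:
    """miRNA -> [(gene, confidence)] restricted to candidate genes."""

    targets: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def n_targets(self, mirna: str) -> int:
        return len(self.targets.get(mirna, []))

    def summed_confidence(self, mirna: str) -> float:
        return sum(c for _, c in self.targets.get(mirna, []))

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (m, g, c)
            for m in sorted(self.targets)
            for g, c in sorted(self.targets[m])
        ]


def inverse_pairing(
    mirnas: CandidateSet,
    genes: CandidateSet,
    interactions: InteractionTable,
    min_confidence: float = 0.0,
) -> PairingResult:
    """Keep interaction edges joining a candidate miRNA to an opposite-role
    candidate gene at confidence >= ``min_confidence``."""
    if mirnas.role == genes.role:
        raise ParameterError(
            f"inverse pairing requires opposite roles, got {mirnas.role} miRNAs "
            f"and {genes.role} genes"
        )
    if not (0 <= min_confidence <= 1):
        raise ParameterError(f"min_confidence {min_confidence} outside [0, 1]")
    mirna_ids = set(mirnas.feature_ids)
    gene_ids = set(genes.feature_ids)
    df = interactions.data
    keep = (
        df["mirna_id"].isin(mirna_ids)
        & df["gene_id"].isin(gene_ids)
        & (df["confidence"] >= min_confidence)
    )
    result = PairingResult()
    for _, row in df[keep].iterrows():
        result.targets.setdefault(row["mirna_id"], []).append(
            (row["gene_id"], float(row["confidence"]))
        )
    logger.info(
        "inverse_pairing: %d edges kept (%s miRNAs -> %s genes)",
        int(keep.sum()), mirnas.role, genes.role,
    )
    return result


def top_mirnas(pairing: PairingResult, n: int = 5) -> list[str]:
    """The n miRNAs with most candidate targets; ties break by larger summed
    confidence, then lexicographic id."""
    if n <= 0:
        raise ParameterError(f"n must be >= 1, got {n}")
    ranked = sorted(
        pairing.targets,
        key=lambda m: (-pairing.n_targets(m), -pairing.summed_confidence(m), m),
    )
    if len(ranked) < n:
        logger.warning("top_mirnas: only %d miRNAs available (requested %d)", len(ranked), n)
    return ranked[:n]


def prune_edges(
    pairing: PairingResult,
    selected_mirnas: list[str],
    max_per_gene: int = 2,
) -> list[tuple[str, str, float]]:
    """Restrict to selected miRNAs, then keep per gene the ``max_per_gene``
    highest-confidence incident edges (ties: lexicographically smaller
    miRNA id wins). Returns (mirna, gene, confidence) triples."""
    if max_per_gene < 1:
        raise ParameterError(f"max_per_gene must be >= 1, got {max_per_gene}")
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for m in selected_mirnas:
        for g, c in pairing.targets.get(m, []):
            by_gene.setdefault(g, []).append((m, c))
    pruned = []
    for g in sorted(by_gene):
        incident = sorted(by_gene[g], key=lambda mc: (-mc[1], mc[0]))
        for m, c in incident[:max_per_gene]:
            pruned.append((m, g, c))
    pruned.sort(key=lambda e: (e[0], e[1]))
    return pruned


def pairing_to_frame(pairing: PairingResult, kept_edges=None) -> pd.DataFrame:
    """Tabular export: (mirna, gene, confidence, kept_flag)."""
    kept = {(m, g) for m, g, _ in kept_edges} if kept_edges is not None else None
    rows = [
        {
            "mirna_id": m,
            "gene_id": g,
            "confidence": c,
            "kept": True if kept is None else (m, g) in kept,
        }
        for m, g, c in pairing.edges()
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence", "kept"])
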