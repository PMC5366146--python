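"""End-to-end helpers tying the similarity, kernel and network stages together."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cofunction import TripartiteNetwork
from .similarity import (
    DEFAULT_ALPHA,
    DEFAULT_LAMBDA,
    DEFAULT_W,
    OntologyDAG,
    SimilarityMatrix,
    combine_similarity,
    geneset_functional_similarity,
    semantic_similarity,
    sequence_similarity,
)


def _with_unit_diagonal(sim: SimilarityMatrix) -> SimilarityMatrix:
    values = sim.values.copy()
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(sim.ids, values)


def disease_similarity(
    network: TripartiteNetwork,
    ontology: OntologyDAG,
    alpha: float = DEFAULT_ALPHA,
    diseases: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """DisSim = alpha * FunSim(disease gene sets) + (1 - alpha) * SemSim(ontology).

    The self-similarity of every disease is set to 1 (needed for kernel
    diagonals).
    """
    if diseases is None:
        diseases = sorted(d for d in network.diseases if network.genes_of_disease(d))
    diseases = list(diseases)
    fun = geneset_functional_similarity(network.disease_genes, diseases)
    sem = semantic_similarity(ontology, diseases)
    return _with_unit_diagonal(combine_similarity(fun, sem, alpha))


def mirna_similarity(
    network: TripartiteNetwork,
    sequences: Sequence[tuple[str, str]],
    alpha: float = DEFAULT_ALPHA,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_W,
) -> SimilarityMatrix:
    """MiRSim = alpha * funSim(target sets) + (1 - alpha) * SeqSim(sequences).

    Covers the miRNAs that have both a sequence record and a non-empty target
    set; self-similarity is 1.
    """
    with_seq = {rid for rid, _ in sequences}
    mirnas = sorted(
        r for r in network.mirnas if r in with_seq and network.mirna_targets.get(r)
    )
    seq_by_id = dict(sequences)
    fun = geneset_functional_similarity(network.mirna_targets, mirnas)
    seq = sequence_similarity([(r, seq_by_id[r]) for r in mirnas], lam, w)
    return _with_unit_diagonal(combine_similarity(fun, seq, alpha))
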