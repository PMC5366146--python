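"""Tripartite disease-gene-miRNA networks and co-functional miRNA pairs.

A co-functional miRNA pair is two miRNAs proposed to dysregulate the same
genes across the development of a series of diseases.  On a tripartite
network with disease, gene and miRNA node sets, the pair (R1, R2) is scored
by the product of three [0, 1] terms:

- ``psg``:  Jaccard index of the two target-gene sets G1, G2;
- ``rd``:   Jaccard index of the two disease sets D1, D2, scaled by the
            fraction of all network diseases the pair shares;
- ``psgc``: fraction of the shared targets that are disease genes of at
            least one shared disease (0 when no targets are shared).

``cfScore = psg * rd * psgc``.  Pairs sharing at least ``min_diseases``
diseases (default 10) and scoring above zero are ranked by cfScore.  For a
pair, each shared target gene g gets a co-functional-target probability
p(g) = (shared diseases linked to g) / (shared diseases).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .association import PredictionRecord
from .errors import InvalidInputError, InvalidPairError, UnknownIdError

logger = logging.getLogger(__name__)

DEFAULT_MIN_DISEASES = 10
DEFAULT_TOP_N = 3000

Edge = tuple[str, str]


@dataclass
class TripartiteNetwork:
    """Diseases, genes and miRNAs with three bipartite edge sets.

    Disease-miRNA edges carry provenance: ``("known", None)`` or
    ``("predicted", probability)``.
    """

    diseases: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    mirnas: set[str] = field(default_factory=set)
    disease_genes: dict[str, set[str]] = field(default_factory=dict)
    mirna_targets: dict[str, set[str]] = field(default_factory=dict)
    disease_mirnas: dict[str, set[str]] = field(default_factory=dict)
    mirna_diseases: dict[str, set[str]] = field(default_factory=dict)
    dm_provenance: dict[Edge, tuple[str, float | None]] = field(default_factory=dict)

    # -- construction -------------------------------------------------------
    def add_disease_gene(self, disease: str, gene: str) -> None:
        self.diseases.add(disease)
        self.genes.add(gene)
        self.disease_genes.setdefault(disease, set()).add(gene)

    def add_mirna_target(self, mirna: str, gene: str) -> None:
        self.mirnas.add(mirna)
        self.genes.add(gene)
        self.mirna_targets.setdefault(mirna, set()).add(gene)

    def add_disease_mirna(
        self, disease: str, mirna: str, provenance: str = "known", probability: float | None = None
    ) -> bool:
        """Add a disease-miRNA edge; returns False if the edge already exists.

        Existing edges are never overwritten (a known edge keeps its
        provenance even if re-added as predicted).
        """
        if (disease, mirna) in self.dm_provenance:
            return False
        self.diseases.add(disease)
        self.mirnas.add(mirna)
        self.disease_mirnas.setdefault(disease, set()).add(mirna)
        self.mirna_diseases.setdefault(mirna, set()).add(disease)
        self.dm_provenance[(disease, mirna)] = (provenance, probability)
        return True

    # -- accessors ----------------------------------------------------------
    def targets_of(self, mirna: str) -> set[str]:
        if mirna not in self.mirnas:
            raise UnknownIdError(f"miRNA {mirna!r} not in network")
        return self.mirna_targets.get(mirna, set())

    def diseases_of(self, mirna: str) -> set[str]:
        if mirna not in self.mirnas:
            raise UnknownIdError(f"miRNA {mirna!r} not in network")
        return self.mirna_diseases.get(mirna, set())

    def genes_of_disease(self, disease: str) -> set[str]:
        return self.disease_genes.get(disease, set())

    def n_edges(self) -> dict[str, int]:
        return {
            "disease_gene": sum(len(v) for v in self.disease_genes.values()),
            "mirna_target": sum(len(v) for v in self.mirna_targets.values()),
            "disease_mirna": len(self.dm_provenance),
        }

    def copy(self) -> "TripartiteNetwork":
        return TripartiteNetwork(
            diseases=set(self.diseases),
            genes=set(self.genes),
            mirnas=set(self.mirnas),
            disease_genes={k: set(v) for k, v in self.disease_genes.items()},
            mirna_targets={k: set(v) for k, v in self.mirna_targets.items()},
            disease_mirnas={k: set(v) for k, v in self.disease_mirnas.items()},
            mirna_diseases={k: set(v) for k, v in self.mirna_diseases.items()},
            dm_provenance=dict(self.dm_provenance),
        )


@dataclass
class PairScore:
    mirna1: str
    mirna2: str
    psg: float
    rd: float
    psgc: float
    cf_score: float
    shared_diseases: int
    rank: int = 0


@dataclass
class TargetProbability:
    gene: str
    p: float


def build_network(
    disease_gene: Iterable[Edge],
    mirna_target: Iterable[Edge],
    disease_mirna: Iterable[Edge],
) -> TripartiteNetwork:
    """Assemble a deduplicated tripartite network from three edge lists.

    Accepts any iterables of (left id, right id) rows, e.g. itertuples of the
    association tables loaded by :mod:`cofunmir.data_io`.
    """
    net = TripartiteNetwork()
    for d, g in disease_gene:
        net.add_disease_gene(str(d), str(g))
    for r, g in mirna_target:
        net.add_mirna_target(str(r), str(g))
    for d, r in disease_mirna:
        net.add_disease_mirna(str(d), str(r), provenance="known")
    counts = net.n_edges()
    logger.info(
        "network: %d diseases, %d genes, %d miRNAs; edges %s",
        len(net.diseases), len(net.genes), len(net.mirnas), counts,
    )
    return net


def reconstruct(
    network: TripartiteNetwork,
    predictions: Sequence[PredictionRecord],
    top_n: int = DEFAULT_TOP_N,
) -> TripartiteNetwork:
    """Add the top-ranked predicted disease-miRNA edges to a copy of the network.

    Predictions duplicating a known edge are skipped and the next-ranked
    prediction is taken instead, so exactly ``top_n`` new edges are added
    when enough novel predictions are available.
    """
    if top_n < 0:
        raise InvalidInputError("top_n must be >= 0")
    net = network.copy()
    ranked = sorted(predictions, key=lambda r: r.rank)
    added = 0
    for rec in ranked:
        if added == top_n:
            break
        if net.add_disease_mirna(rec.disease, rec.mirna, "predicted", rec.probability):
            added += 1
    if added < top_n:
        logger.warning("only %d novel predictions available; requested %d", added, top_n)
    return net


def score_pair(network: TripartiteNetwork, r1: str, r2: str) -> PairScore:
    """cfScore and its three factors for one unordered miRNA pair."""
    if r1 == r2:
        raise InvalidPairError(f"self-pair {r1!r}")
    if not network.diseases:
        raise InvalidInputError("network has no diseases")
    g1, g2 = network.targets_of(r1), network.targets_of(r2)
    d1, d2 = network.diseases_of(r1), network.diseases_of(r2)

    shared_genes = g1 & g2
    union_genes = g1 | g2
    psg = len(shared_genes) / len(union_genes) if union_genes else 0.0

    shared_dis = d1 & d2
    union_dis = d1 | d2
    rd = 0.0
    if union_dis:
        rd = (len(shared_dis) / len(union_dis)) * (len(shared_dis) / len(network.diseases))

    if shared_genes:
        covered: set[str] = set()
        for d in shared_dis:
            covered |= shared_genes & network.genes_of_disease(d)
        psgc = len(covered) / len(shared_genes)
    else:
        psgc = 0.0

    return PairScore(
        mirna1=min(r1, r2),
        mirna2=max(r1, r2),
        psg=psg,
        rd=rd,
        psgc=psgc,
        cf_score=psg * rd * psgc,
        shared_diseases=len(shared_dis),
    )


def rank_pairs(
    network: TripartiteNetwork,
    min_diseases: int = DEFAULT_MIN_DISEASES,
) -> list[PairScore]:
    """All miRNA pairs with cfScore > 0 sharing >= min_diseases diseases, ranked.

    Sorted by cfScore descending; ties broken lexicographically by the pair ids.
    """
    if min_diseases < 1:
        raise InvalidInputError("min_diseases must be >= 1")
    scores = []
    for r1, r2 in itertools.combinations(sorted(network.mirnas), 2):
        s = score_pair(network, r1, r2)
        if s.cf_score > 0 and s.shared_diseases >= min_diseases:
            scores.append(s)
    scores.sort(key=lambda s: (-s.cf_score, s.mirna1, s.mirna2))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def target_probabilities(network: TripartiteNetwork, r1: str, r2: str) -> list[TargetProbability]:
    """Co-functional-target probability for each shared target of the pair.

    p(g) is the fraction of the pair's shared diseases whose disease-gene set
    contains g; genes linked to more of the shared diseases rank higher.
    """
    if r1 == r2:
        raise InvalidPairError(f"self-pair {r1!r}")
    shared_genes = network.targets_of(r1) & network.targets_of(r2)
    shared_dis = network.diseases_of(r1) & network.diseases_of(r2)
    if not shared_genes:
        logger.warning("pair (%s, %s) shares no target genes", r1, r2)
        return []
    result = []
    for g in shared_genes:
        if shared_dis:
            linked = sum(1 for d in shared_dis if g in network.genes_of_disease(d))
            p = linked / len(shared_dis)
        else:
            p = 0.0
        result.append(TargetProbability(gene=g, p=p))
    result.sort(key=lambda t: (-t.p, t.gene))
    return result
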