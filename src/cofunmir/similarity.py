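"""Pairwise similarity measures for diseases and miRNAs.

Disease similarity combines ontology-based semantic similarity (Resnik,
information content of the most informative common ancestor, normalized to
[0, 1]) with functional similarity between disease gene sets.  miRNA
similarity combines target-set functional similarity with a sequence
similarity built on a pseudo-nucleotide-composition encoding: each RNA
sequence becomes a (4 + lambda)-dimensional vector of nucleotide frequencies
plus lambda sequence-order correlation terms computed from normalized
nucleotide molecular weights.  Both combined measures use the same convex
weight alpha:

    DisSim = alpha * FunSim + (1 - alpha) * SemSim
    MiRSim = alpha * funSim + (1 - alpha) * SeqSim
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    AlignmentError,
    DegenerateWeightsError,
    InvalidInputError,
    InvalidWeightsError,
    MissingAnnotationError,
    SequenceError,
    UnknownIdError,
)

logger = logging.getLogger(__name__)

#: molecular weights (daltons) of the four ribonucleotides
DEFAULT_NUCLEOTIDE_WEIGHTS: dict[str, float] = {
    "A": 135.1270,
    "G": 151.1261,
    "C": 111.1020,
    "U": 112.0868,
}

DEFAULT_LAMBDA = 5
DEFAULT_W = 0.05
DEFAULT_ALPHA = 0.8

_NUCLEOTIDES = ("A", "G", "C", "U")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Square symmetric entity-by-entity similarity matrix with an id index."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise InvalidInputError("duplicate ids in similarity matrix")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("similarity values must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidInputError("similarity matrix must be symmetric")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise UnknownIdError(f"id {exc.args[0]!r} not in similarity matrix") from None

    def positions(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[e] for e in ids], dtype=int)
        except KeyError as exc:
            raise UnknownIdError(f"id {exc.args[0]!r} not in similarity matrix") from None

    def mean_offdiagonal(self) -> float:
        """Mean over all unordered off-diagonal entity pairs."""
        n = len(self.ids)
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(self.values[iu].mean())

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OntologyDAG:
    """A rooted is_a ontology: term ids plus child -> parents edges.

    Invariants checked at construction: the edge relation is acyclic and
    every non-root term reaches a root.
    """

    terms: set[str]
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = set(self.terms)
        if not self.terms:
            raise InvalidInputError("ontology has no terms")
        for child, pars in self.parents.items():
            if child not in self.terms or not set(pars) <= self.terms:
                raise InvalidInputError(f"edge endpoints of {child!r} not all declared terms")
        self._check_acyclic_and_rooted()

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def _check_acyclic_and_rooted(self) -> None:
        roots = self.roots
        if not roots:
            raise InvalidInputError("ontology has no root (cycle through every term)")
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise InvalidInputError(f"cycle in ontology at term {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):
                visit(p)
            state[t] = 1

        for t in self.terms:
            visit(t)
        # acyclic + every parentless chain ends at a root => rooted

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of *term*, including the term itself."""
        if term not in self.terms:
            raise UnknownIdError(f"term {term!r} not in ontology")
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents.get(t, ()))
        return seen

    def descendant_counts(self) -> dict[str, int]:
        """Number of descendants of each term, the term itself included."""
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, pars in self.parents.items():
            for p in pars:
                children[p].add(child)

        desc: dict[str, set[str]] = {}

        def collect(t: str) -> set[str]:
            if t in desc:
                return desc[t]
            s = {t}
            for c in children[t]:
                s |= collect(c)
            desc[t] = s
            return s

        for t in self.terms:
            collect(t)
        return {t: len(s) for t, s in desc.items()}


@dataclass
class NucleotideWeights:
    """Raw (dalton) and normalized (zero-mean, unit population-SD) weights."""

    raw: dict[str, float]
    normalized: dict[str, float]


@dataclass
class CompositionVector:
    """Pseudo-nucleotide-composition encoding of one sequence.

    The first four entries are nucleotide frequencies, the remaining
    ``lam`` entries are weighted sequence-order correlation terms; all
    entries share one denominator so they sum to 1.
    """

    mirna_id: str
    values: np.ndarray
    lam: int
    w: float


# ---------------------------------------------------------------------------
# ontology semantic similarity
# ---------------------------------------------------------------------------

def semantic_similarity(dag: OntologyDAG, entities: Sequence[str]) -> SimilarityMatrix:
    """Resnik similarity between ontology terms, normalized to [0, 1].

    The information content of a term is ``-log(p)`` with ``p`` the fraction
    of all terms that are its descendants (itself included); the similarity
    of two terms is the IC of their most informative common ancestor, divided
    by the maximum attainable IC (that of a leaf in this ontology,
    ``log(n_terms)``).  The diagonal is ``IC(t) / maxIC``; similarity with a
    term whose only common ancestor is the root is 0.
    """
    entities = list(entities)
    missing = [e for e in entities if e not in dag.terms]
    if missing:
        raise UnknownIdError(f"terms not in ontology: {missing[:5]}")

    n_terms = len(dag.terms)
    counts = dag.descendant_counts()
    max_ic = math.log(n_terms)
    ic = {t: -math.log(counts[t] / n_terms) for t in dag.terms}

    anc = {e: dag.ancestors(e) for e in set(entities)}
    n = len(entities)
    values = np.zeros((n, n))
    for i, a in enumerate(entities):
        for j in range(i, n):
            b = entities[j]
            common = anc[a] & anc[b]
            mica_ic = max(ic[t] for t in common)  # root is always common
            sim = mica_ic / max_ic if max_ic > 0 else 0.0
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(entities, values)


# ---------------------------------------------------------------------------
# gene-set functional similarity
# ---------------------------------------------------------------------------

def geneset_functional_similarity(
    sets: Mapping[str, set[str]],
    entities: Sequence[str] | None = None,
    gene_sim: SimilarityMatrix | None = None,
) -> SimilarityMatrix:
    """Functional similarity between entities from their gene annotations.

    Default is the Jaccard index of the two gene sets.  When a gene-gene
    similarity matrix is supplied, the best-match-average is used instead:
    for each gene of one set take the maximal similarity against the other
    set, average within each direction, then average the two directions.
    """
    if entities is None:
        entities = sorted(sets)
    entities = list(entities)
    genes: dict[str, frozenset[str]] = {}
    for e in entities:
        s = sets.get(e)
        if not s:
            raise MissingAnnotationError(f"entity {e!r} has no gene annotation")
        genes[e] = frozenset(s)

    n = len(entities)
    values = np.zeros((n, n))
    for i, a in enumerate(entities):
        for j in range(i, n):
            b = entities[j]
            if gene_sim is None:
                inter = len(genes[a] & genes[b])
                union = len(genes[a] | genes[b])
                sim = inter / union
            else:
                sim = _best_match_average(genes[a], genes[b], gene_sim)
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(entities, values)


def _best_match_average(g1: frozenset[str], g2: frozenset[str], gene_sim: SimilarityMatrix) -> float:
    i1 = gene_sim.positions(sorted(g1))
    i2 = gene_sim.positions(sorted(g2))
    block = gene_sim.values[np.ix_(i1, i2)]
    return float((block.max(axis=1).mean() + block.max(axis=0).mean()) / 2.0)


def combine_similarity(
    fun_part: SimilarityMatrix,
    other_part: SimilarityMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> SimilarityMatrix:
    """Convex combination ``alpha * fun + (1 - alpha) * other``."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidInputError(f"alpha must be in [0, 1], got {alpha}")
    if fun_part.ids != other_part.ids:
        raise AlignmentError("similarity matrices do not share the same id index")
    return SimilarityMatrix(
        fun_part.ids, alpha * fun_part.values + (1.0 - alpha) * other_part.values
    )


# ---------------------------------------------------------------------------
# sequence similarity (pseudo-nucleotide composition)
# ---------------------------------------------------------------------------

def normalize_weights(raw: Mapping[str, float] | None = None) -> NucleotideWeights:
    """Standardize the four nucleotide molecular weights.

    ``M_i = (M0_i - mean) / population_SD`` so the normalized weights have
    zero mean and unit population standard deviation.
    """
    raw = dict(DEFAULT_NUCLEOTIDE_WEIGHTS if raw is None else raw)
    if set(raw) != set(_NUCLEOTIDES):
        raise InvalidWeightsError(f"need weights for exactly {_NUCLEOTIDES}, got {sorted(raw)}")
    if any(v <= 0 for v in raw.values()):
        raise InvalidWeightsError("nucleotide weights must be positive")
    vals = np.array([raw[n] for n in _NUCLEOTIDES])
    sd = float(vals.std())  # population SD (ddof=0) over the 4 nucleotides
    if sd == 0.0:
        raise DegenerateWeightsError("all nucleotide weights equal; zero variance")
    mean = float(vals.mean())
    normalized = {n: (raw[n] - mean) / sd for n in _NUCLEOTIDES}
    return NucleotideWeights(raw=raw, normalized=normalized)


def _clean_sequence(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_NUCLEOTIDES)
    if bad:
        raise SequenceError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return s


def pseudo_composition(
    seq: str,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_W,
    weights: NucleotideWeights | None = None,
    mirna_id: str = "",
) -> CompositionVector:
    """Encode an RNA sequence as a (4 + lam)-dimensional composition vector.

    The first four entries are the nucleotide frequencies f_u; entry 4 + t is
    ``w * theta_t`` where ``theta_t`` is the mean squared difference of
    normalized molecular weights between positions t apart.  All entries are
    divided by ``sum(f) + w * sum(theta)``, so the vector sums to 1.

    ``T`` is accepted and read as ``U``.  The sequence must have length at
    least ``lam + 2`` so that every order term averages over at least two
    position pairs.
    """
    if weights is None:
        weights = normalize_weights()
    s = _clean_sequence(seq)
    L = len(s)
    if L <= lam + 1:
        raise SequenceError(f"sequence length {L} must be at least lambda+2={lam + 2}")

    m = np.array([weights.normalized[c] for c in s])
    freqs = np.array([s.count(n) / L for n in _NUCLEOTIDES])
    thetas = np.array(
        [np.mean((m[: L - t] - m[t:]) ** 2) for t in range(1, lam + 1)]
    )
    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs, w * thetas]) / denom
    return CompositionVector(mirna_id=mirna_id, values=values, lam=lam, w=w)


def sequence_similarity(
    records: Sequence[tuple[str, str]],
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_W,
    weights: NucleotideWeights | None = None,
) -> SimilarityMatrix:
    """Min-max rescaled sequence similarity over a set of miRNA sequences.

    Pairwise Euclidean distances between composition vectors are rescaled
    over all off-diagonal pairs and inverted, so the closest pair scores 1
    and the farthest 0; the diagonal is set to 1.  When every pairwise
    distance is identical the normalization is degenerate and all pairs
    score 1 (a warning is logged).
    """
    if len(records) < 2:
        raise InvalidInputError("need at least 2 sequences")
    ids = [r[0] for r in records]
    vectors = np.vstack(
        [pseudo_composition(seq, lam, w, weights, mirna_id=rid).values for rid, seq in records]
    )
    dist = squareform(pdist(vectors))
    iu = np.triu_indices(len(ids), k=1)
    dmin, dmax = dist[iu].min(), dist[iu].max()
    if dmax == dmin:
        logger.warning("all pairwise sequence distances equal; similarity set to 1 everywhere")
        values = np.ones_like(dist)
    else:
        values = 1.0 - (dist - dmin) / (dmax - dmin)
        np.fill_diagonal(values, 1.0)
        values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(ids, values)
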