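"""Precomputed kernels over (disease, miRNA) pairs.

The classifier never sees feature vectors: each sample is a disease-miRNA
pair, and the kernel entry between two samples is a similarity-of-pairs
built from the disease-disease and miRNA-miRNA similarity matrices.

Three pair-similarity modes:

- ``average``: (DisSim + MiRSim) / 2
- ``sqrt``:    sqrt(DisSim * MiRSim)   (the recommended default)
- ``centre``:  Euclidean distance of (DisSim, MiRSim) from the grand means
  (AvgDisSim, AvgMiRSim) of the full similarity matrices.

Note on ``centre``: as defined it is a *distance* from the centre, so larger
values mean the pair of pairs is farther from typical similarity, not more
similar; it is provided verbatim for completeness and a warning is logged
when it is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

MODES = ("average", "sqrt", "centre")
DEFAULT_MODE = "sqrt"


@dataclass(frozen=True)
class PairSample:
    """One (disease, miRNA) pair, optionally labeled +1 / -1."""

    disease: str
    mirna: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label not in (None, 1, -1):
            raise InvalidInputError(f"label must be +1, -1 or None, got {self.label!r}")


@dataclass
class KernelMatrix:
    """Pairwise similarity-of-pairs matrix.

    A training kernel is square and symmetric; a prediction kernel is
    rectangular with columns indexed by the training pairs in training order.
    """

    row_pairs: list[PairSample]
    col_pairs: list[PairSample]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_pairs), len(self.col_pairs)):
            raise InvalidInputError("kernel shape does not match pair lists")

    @property
    def is_square(self) -> bool:
        return self.row_pairs == self.col_pairs


def _mode_combine(dis: np.ndarray, mir: np.ndarray, mode: str, avg_dis: float, avg_mir: float) -> np.ndarray:
    if mode == "average":
        return (dis + mir) / 2.0
    if mode == "sqrt":
        return np.sqrt(dis * mir)
    if mode == "centre":
        return np.sqrt((dis - avg_dis) ** 2 + (mir - avg_mir) ** 2)
    raise ConfigError(f"unknown kernel mode {mode!r}; expected one of {MODES}")


def pair_similarity(
    p: PairSample,
    q: PairSample,
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    avg_dis: float = 0.0,
    avg_mir: float = 0.0,
) -> float:
    """Similarity of two (disease, miRNA) pairs under the given mode."""
    d = dis_sim.loc(p.disease, q.disease)
    m = mir_sim.loc(p.mirna, q.mirna)
    return float(_mode_combine(np.asarray(d), np.asarray(m), mode, avg_dis, avg_mir))


def _kernel_block(
    rows: Sequence[PairSample],
    cols: Sequence[PairSample],
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
) -> np.ndarray:
    ri_d = dis_sim.positions([p.disease for p in rows])
    ci_d = dis_sim.positions([p.disease for p in cols])
    ri_m = mir_sim.positions([p.mirna for p in rows])
    ci_m = mir_sim.positions([p.mirna for p in cols])
    dis = dis_sim.values[np.ix_(ri_d, ci_d)]
    mir = mir_sim.values[np.ix_(ri_m, ci_m)]
    # grand means over all off-diagonal entity pairs of the *full* matrices,
    # not just the entities occurring in the samples
    avg_dis = dis_sim.mean_offdiagonal()
    avg_mir = mir_sim.mean_offdiagonal()
    if mode == "centre":
        logger.warning(
            "mode 'centre' is a distance from the average-similarity centre: "
            "larger values mean LESS typical, not more similar"
        )
    return _mode_combine(dis, mir, mode, avg_dis, avg_mir)


def training_kernel(
    samples: Sequence[PairSample],
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
) -> KernelMatrix:
    """Square M x M kernel over the training pairs (symmetric)."""
    if len(samples) < 2:
        raise InvalidInputError("need at least 2 training samples")
    samples = list(samples)
    values = _kernel_block(samples, samples, mode, dis_sim, mir_sim)
    return KernelMatrix(samples, samples, values)


def prediction_kernel(
    test: Sequence[PairSample],
    train: Sequence[PairSample],
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
) -> KernelMatrix:
    """Rectangular n x M kernel: test pairs vs training pairs in training order."""
    if not test or not train:
        raise InvalidInputError("test and train pair lists must be non-empty")
    test, train = list(test), list(train)
    values = _kernel_block(test, train, mode, dis_sim, mir_sim)
    return KernelMatrix(test, train, values)
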