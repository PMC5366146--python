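"""Disease-miRNA association prediction.

Workflow: nominate negative (disease, miRNA) pairs from case/control
expression studies (miRNAs whose |log2 fold change| stays below a small
threshold are treated as unrelated to that disease), train a support vector
classifier on a precomputed pair kernel over balanced positive/negative
samples, score all unconnected candidate pairs, and evaluate with
leave-one-out or k-fold cross-validation plus a label-permutation test.
The 100-model ensemble retrains on independently resampled balanced negative
subsets and calls a candidate strongly associated only when every model
predicts it positive; its reported probability is the across-model average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    DegenerateTrainingError,
    InvalidInputError,
    SamplingError,
)
from .pairkernel import (
    DEFAULT_MODE,
    PairSample,
    prediction_kernel,
    training_kernel,
)
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 0.05
DEFAULT_PSEUDOCOUNT = 1e-8
DEFAULT_C = 1.0
DEFAULT_N_MODELS = 100


# ---------------------------------------------------------------------------
# expression-based negative samples
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """One case/control miRNA expression study for a single disease."""

    disease: str
    expression: pd.DataFrame  # miRNA x sample, non-negative
    groups: Mapping[str, str]  # sample id -> 'case' | 'control'
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise InvalidInputError("duplicate miRNA ids in expression matrix")
        self.groups = dict(self.groups)
        missing = set(self.expression.columns) - set(self.groups)
        if missing:
            raise InvalidInputError(f"samples without group label: {sorted(missing)[:5]}")
        labels = {self.groups[s] for s in self.expression.columns}
        if not {"case", "control"} <= labels:
            raise InvalidInputError("study needs at least one case and one control sample")
        if (self.expression.values < 0).any():
            raise InvalidInputError("expression values must be non-negative")

    def case_columns(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups[s] == "case"]

    def control_columns(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups[s] == "control"]


def fold_changes(study: ExpressionStudy, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """log2 fold change of mean case vs mean control expression per miRNA.

    A pseudocount guards against all-zero rows; such rows are flagged in the
    log because their fold change is determined by the pseudocount alone.
    """
    case_mean = study.expression[study.case_columns()].mean(axis=1)
    ctrl_mean = study.expression[study.control_columns()].mean(axis=1)
    zero = (case_mean == 0) & (ctrl_mean == 0)
    if zero.any():
        logger.warning(
            "study %s/%s: %d all-zero miRNA rows; fold change set by pseudocount",
            study.study_id, study.disease, int(zero.sum()),
        )
    fc = np.log2((case_mean + pseudocount) / (ctrl_mean + pseudocount))
    fc.name = "log2_fold_change"
    return fc


@dataclass
class NegativeSampleSet:
    """Expression-nominated negative pairs with provenance."""

    records: pd.DataFrame  # columns: disease, mirna, study_id, log2_fold_change

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["disease"], self.records["mirna"]))

    def __len__(self) -> int:
        return len(self.records)


def select_negatives(
    studies: Sequence[ExpressionStudy],
    positives: Sequence[PairSample],
    threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NegativeSampleSet:
    """Select negative (disease, miRNA) pairs from expression studies.

    A pair enters when the miRNA's |log2 fold change| in that disease's study
    is below ``threshold``.  Pairs that also occur in the positive set are
    discarded; finally, diseases without any known positive miRNA and miRNAs
    without any known positive disease are dropped, keeping only entities the
    positive data can vouch for.
    """
    if not studies:
        raise InvalidInputError("no expression studies supplied")
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    pos_pairs = {(p.disease, p.mirna) for p in positives}
    pos_diseases = {p.disease for p in positives}
    pos_mirnas = {p.mirna for p in positives}

    rows = []
    for study in studies:
        fc = fold_changes(study, pseudocount)
        flat = fc[fc.abs() < threshold]
        for mirna, value in flat.items():
            pair = (study.disease, mirna)
            if pair in pos_pairs:
                continue
            rows.append((study.disease, mirna, study.study_id, float(value)))
    frame = pd.DataFrame(rows, columns=["disease", "mirna", "study_id", "log2_fold_change"])
    frame = frame.drop_duplicates(subset=["disease", "mirna"], keep="first")
    n_raw = len(frame)
    frame = frame[frame["disease"].isin(pos_diseases) & frame["mirna"].isin(pos_mirnas)]
    frame = frame.reset_index(drop=True)
    logger.info(
        "select_negatives: %d flat pairs -> %d after positive-entity filtering "
        "(%d diseases, %d miRNAs)",
        n_raw, len(frame), frame["disease"].nunique(), frame["mirna"].nunique(),
    )
    result = NegativeSampleSet(frame)
    assert not (result.pairs & pos_pairs), "negative set overlaps positives"
    return result


def sample_balanced_negatives(
    pool: NegativeSampleSet | Sequence[PairSample],
    n: int,
    seed: int,
) -> list[PairSample]:
    """Draw ``n`` negatives (label -1) from the pool without replacement."""
    if isinstance(pool, NegativeSampleSet):
        candidates = sorted(pool.pairs)
    else:
        candidates = sorted({(p.disease, p.mirna) for p in pool})
    if len(candidates) < n:
        raise SamplingError(f"negative pool ({len(candidates)}) smaller than requested {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [PairSample(candidates[i][0], candidates[i][1], -1) for i in sorted(idx)]


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted precomputed-kernel classifier plus its immutable pair order."""

    train_pairs: tuple[PairSample, ...]
    mode: str
    classifier: SVC


@dataclass
class PredictionRecord:
    disease: str
    mirna: str
    label: int
    probability: float
    rank: int = 0
    strong: bool | None = None  # only set by ensemble_predict


def _labels(samples: Sequence[PairSample]) -> np.ndarray:
    y = np.array([s.label for s in samples], dtype=float)
    if np.isnan(y).any():
        raise InvalidInputError("all training samples must carry a label")
    return y.astype(int)


def _fit_svc(kernel: np.ndarray, y: np.ndarray, c: float, seed: int) -> SVC:
    if len(set(y)) < 2:
        raise DegenerateTrainingError("training set contains a single class")
    import warnings

    with warnings.catch_warnings():
        # keep libsvm's internal Platt calibration (probability=True); newer
        # sklearn nudges towards CalibratedClassifierCV, which changes the
        # probability semantics
        warnings.filterwarnings("ignore", category=FutureWarning)
        svc = SVC(kernel="precomputed", C=c, probability=True, random_state=seed)
        svc.fit(kernel, y)
    return svc


def train(
    samples: Sequence[PairSample],
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    seed: int = 0,
    c: float = DEFAULT_C,
) -> TrainedModel:
    """Fit the precomputed-kernel SVM on labeled (disease, miRNA) pairs."""
    samples = list(samples)
    y = _labels(samples)
    tkm = training_kernel(samples, mode, dis_sim, mir_sim)
    svc = _fit_svc(tkm.values, y, c, seed)
    return TrainedModel(tuple(samples), mode, svc)


def _positive_probabilities(svc: SVC, kernel: np.ndarray) -> np.ndarray:
    proba = svc.predict_proba(kernel)
    pos_col = int(np.where(svc.classes_ == 1)[0][0])
    return proba[:, pos_col]


def _ranked(records: list[PredictionRecord]) -> list[PredictionRecord]:
    records.sort(key=lambda r: (-r.probability, r.disease, r.mirna))
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records


def predict(
    model: TrainedModel,
    candidates: Sequence[PairSample],
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
) -> list[PredictionRecord]:
    """Score candidate pairs; ranked by probability desc, ties by ids."""
    candidates = list(candidates)
    pkm = prediction_kernel(candidates, list(model.train_pairs), model.mode, dis_sim, mir_sim)
    probs = _positive_probabilities(model.classifier, pkm.values)
    labels = model.classifier.predict(pkm.values).astype(int)
    records = [
        PredictionRecord(c.disease, c.mirna, int(l), float(p))
        for c, l, p in zip(candidates, labels, probs)
    ]
    return _ranked(records)


def ensemble_predict(
    positives: Sequence[PairSample],
    negative_pool: NegativeSampleSet | Sequence[PairSample],
    candidates: Sequence[PairSample],
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    mode: str = DEFAULT_MODE,
    n_models: int = DEFAULT_N_MODELS,
    seed: int = 0,
    c: float = DEFAULT_C,
) -> list[PredictionRecord]:
    """Average an ensemble of models over resampled balanced negative sets.

    Each model trains on all positives plus an independently drawn balanced
    negative subset.  A candidate is marked strongly associated (``strong``)
    only when every model predicts it positive; probabilities are averaged
    across models and the output is ranked on the average.
    """
    if n_models < 1:
        raise InvalidInputError("n_models must be >= 1")
    positives = [PairSample(p.disease, p.mirna, 1) for p in positives]
    candidates = list(candidates)
    rng = np.random.default_rng(seed)
    prob_sum = np.zeros(len(candidates))
    positive_votes = np.zeros(len(candidates), dtype=int)
    for _ in range(n_models):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        negatives = sample_balanced_negatives(negative_pool, len(positives), sub_seed)
        model = train(positives + negatives, mode, dis_sim, mir_sim, seed=sub_seed, c=c)
        preds = predict(model, candidates, dis_sim, mir_sim)
        by_pair = {(r.disease, r.mirna): r for r in preds}
        for i, cand in enumerate(candidates):
            r = by_pair[(cand.disease, cand.mirna)]
            prob_sum[i] += r.probability
            positive_votes[i] += int(r.label == 1)
    records = [
        PredictionRecord(
            cand.disease,
            cand.mirna,
            label=1 if positive_votes[i] == n_models else -1,
            probability=float(prob_sum[i] / n_models),
            strong=bool(positive_votes[i] == n_models),
        )
        for i, cand in enumerate(candidates)
    ]
    return _ranked(records)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    scheme: str
    specificity: float
    sensitivity: float
    precision: float
    accuracy: float
    auc: float
    fold_details: list[dict] = field(default_factory=list)

    def metrics(self) -> dict[str, float]:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def _binary_metrics(y: np.ndarray, prob: np.ndarray, cutoff: float = 0.5) -> dict[str, float]:
    pred = np.where(prob >= cutoff, 1, -1)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    return {
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "accuracy": (tp + tn) / len(y),
    }


def _fold_indices(y: np.ndarray, scheme: str, k: int | None, seed: int):
    n = len(y)
    if scheme == "loocv":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    if scheme == "kfold":
        if k is None or k < 2:
            raise InvalidInputError("k-fold evaluation needs k >= 2")
        if k > n:
            raise InvalidInputError(f"k={k} exceeds number of samples {n}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(n), y))
    raise InvalidInputError(f"unknown evaluation scheme {scheme!r}")


def evaluate(
    samples: Sequence[PairSample],
    scheme: str,
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    seed: int = 0,
    k: int | None = None,
    c: float = DEFAULT_C,
    _y_override: np.ndarray | None = None,
) -> EvaluationReport:
    """Cross-validated evaluation with pooled held-out probabilities.

    The full sample-by-sample kernel is computed once and sliced per fold
    (kernel entries do not depend on the fitted model).  AUC is computed over
    the pooled held-out probabilities; the threshold metrics use a 0.5
    probability cutoff.
    """
    samples = list(samples)
    y = _labels(samples) if _y_override is None else np.asarray(_y_override, dtype=int)
    full = training_kernel(samples, mode, dis_sim, mir_sim).values
    folds = _fold_indices(y, scheme, k, seed)
    pooled = np.empty(len(samples))
    details = []
    for fi, (tr, te) in enumerate(folds):
        svc = _fit_svc(full[np.ix_(tr, tr)], y[tr], c, seed)
        pooled[te] = _positive_probabilities(svc, full[np.ix_(te, tr)])
        details.append({"fold": fi, "n_train": len(tr), "n_test": len(te)})
    metrics = _binary_metrics(y, pooled)
    auc = float(roc_auc_score(y, pooled))
    name = scheme if scheme == "loocv" else f"kfold({k})"
    return EvaluationReport(scheme=name, auc=auc, fold_details=details, **metrics)


def permutation_test(
    samples: Sequence[PairSample],
    n_perm: int,
    scheme: str,
    mode: str,
    dis_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    seed: int = 0,
    k: int | None = None,
    c: float = DEFAULT_C,
) -> tuple[float, np.ndarray, float]:
    """Label-permutation null for the cross-validated AUC.

    Returns (observed AUC, null AUCs, empirical p) with the plus-one rule
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 10:
        raise InvalidInputError("need at least 10 permutations")
    samples = list(samples)
    observed = evaluate(samples, scheme, mode, dis_sim, mir_sim, seed=seed, k=k, c=c).auc
    y = _labels(samples)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_y = rng.permutation(y)
        null[i] = evaluate(
            samples, scheme, mode, dis_sim, mir_sim,
            seed=seed, k=k, c=c, _y_override=perm_y,
        ).auc
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return observed, null, p
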