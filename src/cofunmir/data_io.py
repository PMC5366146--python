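"""Readers and writers for the standard formats, plus static id mapping.

Formats: OBO 1.2 ontologies (term ids and is_a edges only), FASTA mature
miRNA sequences, and TSV for every table, matrix and result.  The TSV
dialect is tab-separated UTF-8 with a header row; lines starting with '#'
(and GEO series-matrix-style '!' lines in expression matrices) are ignored.

ID mapping is applied from static two-column tables (source id -> canonical
id) shipped alongside the data; there are no network calls.  Unmapped ids
are dropped and counted, mirroring curation pipelines that discard dead
records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import ExpressionStudy, PredictionRecord
from .cofunction import PairScore, TargetProbability, TripartiteNetwork
from .errors import ParseError
from .pairkernel import KernelMatrix
from .similarity import OntologyDAG, SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ontology and sequences
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO ontology, keeping term ids and is_a edges only."""
    graph = obonet.read_obo(str(path))
    terms = set(graph.nodes)
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return OntologyDAG(terms=terms, parents=parents)


def write_obo(dag: OntologyDAG, path: str | Path, name: str = "synthetic-ontology") -> None:
    """Write a minimal OBO 1.2 file (id, name, is_a stanzas)."""
    lines = ["format-version: 1.2", f"ontology: {name}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term}")
        for parent in sorted(dag.parents.get(term, ())):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) records from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# id mapping
# ---------------------------------------------------------------------------

@dataclass
class IdMappingTable:
    """source id -> canonical id; one canonical id per source id."""

    mapping: dict[str, str]
    namespace: str = ""

    def get(self, source: str) -> str | None:
        return self.mapping.get(source)


def load_id_mapping(path: str | Path, namespace: str = "") -> IdMappingTable:
    frame = read_tsv(path, min_columns=2)
    mapping: dict[str, str] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        src, dst = str(row[0]), str(row[1])
        if src in mapping and mapping[src] != dst:
            raise ParseError(f"source id {src!r} maps to multiple canonical ids", line=i)
        mapping[src] = dst
    return IdMappingTable(mapping=mapping, namespace=namespace)


def apply_id_mapping(
    ids: Sequence[str], mapping: IdMappingTable
) -> tuple[list[str], list[str]]:
    """Map ids to canonical form; returns (canonical ids, unmapped ids)."""
    mapped, unmapped = [], []
    for i in ids:
        canonical = mapping.get(i)
        if canonical is None:
            unmapped.append(i)
        else:
            mapped.append(canonical)
    if unmapped:
        logger.info("id mapping: %d/%d ids unmapped", len(unmapped), len(ids))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    total: int = 0
    kept: int = 0
    dropped: int = 0
    deduplicated: int = 0

    def conserved(self) -> bool:
        return self.total == self.kept + self.dropped + self.deduplicated


@dataclass
class AssociationTable:
    """Deduplicated two-column association rows with declared namespaces."""

    frame: pd.DataFrame  # columns: left, right
    left_ns: str = ""
    right_ns: str = ""
    report: LoadReport = field(default_factory=LoadReport)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["left"], self.frame["right"]))

    def __len__(self) -> int:
        return len(self.frame)


def read_tsv(path: str | Path, min_columns: int = 2) -> pd.DataFrame:
    """Read a TSV with a header row; '#' comment lines ignored."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed TSV {path}: {exc}") from exc
    if frame.shape[1] < min_columns:
        raise ParseError(f"{path}: expected >= {min_columns} columns, found {frame.shape[1]}")
    return frame


def load_association_table(
    path: str | Path,
    left_ns: str = "",
    right_ns: str = "",
    mapping_left: IdMappingTable | None = None,
    mapping_right: IdMappingTable | None = None,
) -> AssociationTable:
    """Load a two-column association TSV, applying optional id mappings.

    Rows with ids the mapping cannot resolve are dropped and counted;
    duplicates (after mapping) are collapsed.  The load report conserves
    counts: total = kept + dropped + deduplicated.
    """
    frame = read_tsv(path, min_columns=2)
    report = LoadReport(total=len(frame))
    rows: list[tuple[str, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        left, right = row[0], row[1]
        if pd.isna(left) or pd.isna(right):
            raise ParseError(f"{path}: missing id", line=i)
        left, right = str(left), str(right)
        if mapping_left is not None:
            left = mapping_left.get(left)
        if mapping_right is not None:
            right = mapping_right.get(right)
        if left is None or right is None:
            report.dropped += 1
            continue
        rows.append((left, right))
    out = pd.DataFrame(rows, columns=["left", "right"])
    before = len(out)
    out = out.drop_duplicates().reset_index(drop=True)
    report.deduplicated = before - len(out)
    report.kept = len(out)
    logger.info(
        "loaded %s: %d rows -> %d kept, %d dropped, %d duplicates",
        path, report.total, report.kept, report.dropped, report.deduplicated,
    )
    return AssociationTable(frame=out, left_ns=left_ns, right_ns=right_ns, report=report)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame.columns = [table.left_ns or "left", table.right_ns or "right"]
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="id")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(frame.columns), frame.to_numpy(dtype=float))


def _pair_label(p) -> str:
    return f"{p.disease}|{p.mirna}"


def write_kernel(kernel: KernelMatrix, path: str | Path) -> None:
    """Kernel as TSV with 'diseaseId|miRNAId' row/column labels."""
    frame = pd.DataFrame(
        kernel.values,
        index=[_pair_label(p) for p in kernel.row_pairs],
        columns=[_pair_label(p) for p in kernel.col_pairs],
    )
    frame.to_csv(path, sep="\t", index_label="pair")


def write_kernel_libsvm(kernel: KernelMatrix, path: str | Path) -> None:
    """Kernel in the libsvm precomputed-kernel convention.

    Each row: ``<label> 0:<serial> 1:<k_1> ... M:<k_M>`` where the leading
    0-indexed feature is the 1-based sample serial number.
    """
    lines = []
    for i, (p, row) in enumerate(zip(kernel.row_pairs, kernel.values), start=1):
        label = p.label if p.label is not None else 0
        feats = " ".join(f"{j}:{v:.10g}" for j, v in enumerate(row, start=1))
        lines.append(f"{label} 0:{i} {feats}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def read_expression_study(
    matrix_path: str | Path,
    design_path: str | Path,
    disease: str,
    study_id: str = "",
) -> ExpressionStudy:
    """Read a miRNA-by-sample expression TSV plus a (sample, group) design TSV.

    GEO series-matrix-style metadata lines beginning with '!' are skipped in
    the matrix file.
    """
    matrix_path = Path(matrix_path)
    text = [
        ln for ln in matrix_path.read_text(encoding="utf-8").splitlines()
        if ln and not ln.startswith(("!", "#"))
    ]
    from io import StringIO

    expr = pd.read_csv(StringIO("\n".join(text)), sep="\t", index_col=0)
    expr = expr.astype(float)

    design = read_tsv(design_path, min_columns=2)
    groups = {str(r[0]): str(r[1]) for r in design.itertuples(index=False)}
    return ExpressionStudy(
        disease=disease, expression=expr, groups=groups, study_id=study_id or matrix_path.stem
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.disease, r.mirna, r.label, r.probability, r.rank) for r in records],
        columns=["disease", "mirna", "label", "probability", "rank"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    frame = read_tsv(path, min_columns=5)
    return [
        PredictionRecord(
            disease=str(r.disease), mirna=str(r.mirna),
            label=int(r.label), probability=float(r.probability), rank=int(r.rank),
        )
        for r in frame.itertuples(index=False)
    ]


def write_pair_scores(
    scores: Sequence[PairScore],
    network: TripartiteNetwork,
    path: str | Path,
    top_targets: int = 10,
) -> None:
    """Ranked co-functional pairs with their top-k shared targets.

    Targets are reported as 'gene:probability' joined by semicolons, best
    first.
    """
    from .cofunction import target_probabilities

    rows = []
    for s in scores:
        targets = target_probabilities(network, s.mirna1, s.mirna2)[:top_targets]
        joined = ";".join(f"{t.gene}:{t.p:.4g}" for t in targets)
        rows.append(
            (s.rank, s.mirna1, s.mirna2, s.psg, s.rd, s.psgc, s.cf_score,
             s.shared_diseases, joined)
        )
    frame = pd.DataFrame(
        rows,
        columns=["rank", "mirna1", "mirna2", "psg", "rd", "psgc", "cfScore",
                 "shared_disease_count", "top_targets"],
    )
    frame.to_csv(path, sep="\t", index=False)
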