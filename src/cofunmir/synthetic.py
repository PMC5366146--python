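"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generator plants co-functional modules: each module is a pair of miRNAs
that share a configurable fraction of a module gene set and are both
associated with a common set of module diseases, each of which is linked to
the module genes.  Background miRNAs and diseases carry sparse random
annotations and no disease-miRNA edges.  Case/control expression studies are
generated per module disease: the module's miRNAs are dysregulated with a
configurable log2 effect size, background miRNAs fluctuate around zero
log-fold change.  Sequences of a planted pair differ by a few point
mutations so sequence similarity correlates with planted co-function;
background sequences are uniform random.  A random ontology tree groups each
module's diseases under a shared branch so semantic similarity is
non-trivial.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import ExpressionStudy
from .cofunction import TripartiteNetwork
from .errors import SpecError
from .pairkernel import PairSample
from .similarity import OntologyDAG

_NUC = np.array(list("ACGU"))


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults give three planted modules of 12 diseases each (enough to clear
    the 10-shared-disease ranking threshold), a high but imperfect target
    overlap within pairs, and expression effect sizes typical of a clearly
    dysregulated miRNA (2-fold, i.e. 1.0 on the log2 scale) over modest
    biological noise.
    """

    seed: int = 0
    n_diseases: int = 40
    n_genes: int = 60
    n_mirnas: int = 24
    n_modules: int = 3
    module_overlap: float = 0.8          # fraction of module genes shared by the pair
    module_n_diseases: int = 12
    module_n_genes: int = 8
    background_targets: int = 5          # targets per background miRNA
    background_disease_genes: int = 5    # genes per background disease
    n_samples_per_group: int = 5
    effect_size: float = 1.0             # |log2 FC| of planted disease miRNAs
    noise_sd: float = 0.05               # SD of log2 expression noise
    seq_len_range: tuple[int, int] = (20, 25)
    n_mutations: int = 2                 # point mutations within a planted pair

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_genes, self.n_mirnas, self.n_modules) < 1:
            raise SpecError("all counts must be positive")
        if not 0.0 <= self.module_overlap <= 1.0:
            raise SpecError("module_overlap must be in [0, 1]")
        if self.n_modules * self.module_n_diseases > self.n_diseases:
            raise SpecError("module diseases exceed n_diseases")
        if self.n_modules * self.module_n_genes > self.n_genes:
            raise SpecError("module genes exceed n_genes")
        if 2 * self.n_modules > self.n_mirnas:
            raise SpecError("module miRNAs exceed n_mirnas")


@dataclass
class Fixture:
    """One generated fixture: network, sequences, ontology, studies, truth."""

    spec: FixtureSpec
    network: TripartiteNetwork
    sequences: list[tuple[str, str]]
    ontology: OntologyDAG
    studies: list[ExpressionStudy]
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def positives(self) -> list[PairSample]:
        return [
            PairSample(d, r, 1)
            for d, r in self.truth["planted_positives"].itertuples(index=False)
        ]

    @property
    def planted_negative_pairs(self) -> list[PairSample]:
        return [
            PairSample(d, r, -1)
            for d, r in self.truth["planted_negatives"].itertuples(index=False)
        ]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NUC, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False):
        alternatives = [c for c in "ACGU" if c != chars[pos]]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def _module_ontology(spec: FixtureSpec, diseases: list[str], module_diseases: list[list[str]]) -> OntologyDAG:
    root = "DO:0000000"
    terms = {root}
    parents: dict[str, set[str]] = {}
    assigned: set[str] = set()
    for m, members in enumerate(module_diseases):
        branch = f"DO:branch{m}"
        terms.add(branch)
        parents[branch] = {root}
        for d in members:
            terms.add(d)
            parents[d] = {branch}
            assigned.add(d)
    bg_branch = "DO:branchBG"
    terms.add(bg_branch)
    parents[bg_branch] = {root}
    for d in diseases:
        if d not in assigned:
            terms.add(d)
            parents[d] = {bg_branch}
    return OntologyDAG(terms=terms, parents=parents)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the full fixture described by *spec*, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)

    diseases = [f"DO:{i:07d}" for i in range(1, spec.n_diseases + 1)]
    genes = [f"G{i}" for i in range(1, spec.n_genes + 1)]
    mirnas = [f"miR-{i}" for i in range(1, spec.n_mirnas + 1)]

    net = TripartiteNetwork()
    module_rows = []
    positive_rows = []
    module_diseases: list[list[str]] = []
    planted_mirnas: set[str] = set()

    for m in range(spec.n_modules):
        d_slice = diseases[m * spec.module_n_diseases:(m + 1) * spec.module_n_diseases]
        g_slice = genes[m * spec.module_n_genes:(m + 1) * spec.module_n_genes]
        ra, rb = mirnas[2 * m], mirnas[2 * m + 1]
        planted_mirnas.update((ra, rb))
        module_diseases.append(d_slice)

        n_shared = max(1, int(round(spec.module_overlap * spec.module_n_genes)))
        shared = g_slice[:n_shared]
        ra_only = g_slice[n_shared:]
        # rb's non-shared targets come from the background gene pool
        bg_genes = genes[spec.n_modules * spec.module_n_genes:]
        n_extra = spec.module_n_genes - n_shared
        rb_extra = (
            list(rng.choice(bg_genes, size=n_extra, replace=False)) if n_extra and bg_genes else []
        )
        for g in shared + ra_only:
            net.add_mirna_target(ra, g)
        for g in shared + rb_extra:
            net.add_mirna_target(rb, g)
        for d in d_slice:
            for g in g_slice:
                net.add_disease_gene(d, g)
            for r in (ra, rb):
                net.add_disease_mirna(d, r)
                positive_rows.append((d, r))
        module_rows.append((m, ra, rb, len(shared), len(d_slice)))

    # background annotations
    bg_mirnas = [r for r in mirnas if r not in planted_mirnas]
    module_dis_flat = {d for ds in module_diseases for d in ds}
    bg_diseases = [d for d in diseases if d not in module_dis_flat]
    for r in bg_mirnas:
        for g in rng.choice(genes, size=min(spec.background_targets, len(genes)), replace=False):
            net.add_mirna_target(r, g)
    for d in bg_diseases:
        net.diseases.add(d)
        for g in rng.choice(genes, size=min(spec.background_disease_genes, len(genes)), replace=False):
            net.add_disease_gene(d, g)
    # every background miRNA gets one known association to a background
    # disease: negative-pair selection only keeps miRNAs with at least one
    # known positive disease, so miRNAs entering the negative pool must have
    # a positive record somewhere (as real negative-set miRNAs do)
    if bg_diseases:
        for i, r in enumerate(bg_mirnas):
            net.add_disease_mirna(bg_diseases[i % len(bg_diseases)], r)

    # sequences: planted pairs differ by a few point mutations
    sequences: dict[str, str] = {}
    lo, hi = spec.seq_len_range
    for m in range(spec.n_modules):
        ra, rb = mirnas[2 * m], mirnas[2 * m + 1]
        base = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        sequences[ra] = base
        sequences[rb] = _mutate(rng, base, spec.n_mutations)
    for r in bg_mirnas:
        sequences[r] = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
    seq_records = [(r, sequences[r]) for r in mirnas]

    ontology = _module_ontology(spec, diseases, module_diseases)

    # expression studies: one per module disease; the module's miRNA pair is
    # dysregulated, every other miRNA is flat
    studies: list[ExpressionStudy] = []
    negative_rows = []
    sample_ids = (
        [f"case{i}" for i in range(1, spec.n_samples_per_group + 1)]
        + [f"ctrl{i}" for i in range(1, spec.n_samples_per_group + 1)]
    )
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    for m, d_slice in enumerate(module_diseases):
        ra, rb = mirnas[2 * m], mirnas[2 * m + 1]
        for d in d_slice:
            log2_expr = rng.normal(5.0, spec.noise_sd, size=(spec.n_mirnas, len(sample_ids)))
            for r in (ra, rb):
                i = mirnas.index(r)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                log2_expr[i, : spec.n_samples_per_group] += sign * spec.effect_size
            expr = pd.DataFrame(2.0 ** log2_expr, index=mirnas, columns=sample_ids)
            studies.append(
                ExpressionStudy(disease=d, expression=expr, groups=groups, study_id=f"study-{d}")
            )
            for r in mirnas:
                if r not in (ra, rb):
                    negative_rows.append((d, r))

    truth = {
        "planted_pairs": pd.DataFrame(
            module_rows, columns=["module", "mirna1", "mirna2", "n_shared_targets", "n_diseases"]
        ),
        "planted_positives": pd.DataFrame(positive_rows, columns=["disease", "mirna"]),
        "planted_negatives": pd.DataFrame(negative_rows, columns=["disease", "mirna"]),
    }
    return Fixture(
        spec=spec, network=net, sequences=seq_records, ontology=ontology,
        studies=studies, truth=truth,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write all fixture files (TSV/FASTA/OBO) to a directory."""
    from . import data_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = fixture.network
    pd.DataFrame(
        [(d, g) for d, gs in sorted(net.disease_genes.items()) for g in sorted(gs)],
        columns=["disease", "gene"],
    ).to_csv(outdir / "disease_gene.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r, g) for r, gs in sorted(net.mirna_targets.items()) for g in sorted(gs)],
        columns=["mirna", "gene"],
    ).to_csv(outdir / "mirna_target.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(net.dm_provenance), columns=["disease", "mirna"]
    ).to_csv(outdir / "disease_mirna.tsv", sep="\t", index=False)
    data_io.write_fasta(fixture.sequences, outdir / "sequences.fasta")
    data_io.write_obo(fixture.ontology, outdir / "ontology.obo")
    for name, frame in fixture.truth.items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    for study in fixture.studies:
        study.expression.to_csv(expr_dir / f"{study.study_id}.tsv", sep="\t", index_label="mirna")
        pd.DataFrame(
            sorted(study.groups.items()), columns=["sample", "group"]
        ).to_csv(expr_dir / f"{study.study_id}.design.tsv", sep="\t", index=False)
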