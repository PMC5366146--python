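"""Train the precomputed pair-kernel SVM on a planted benchmark and evaluate it.

A synthetic fixture plants co-functional modules (miRNA pairs sharing targets
and diseases).  Disease-disease and miRNA-miRNA similarity matrices are built
from the fixture's gene annotations, ontology and sequences; the kernel entry
between two (disease, miRNA) pairs is sqrt(DisSim x MiRSim).  Evaluation is
leave-one-out cross-validation on the planted positives plus an equal number
of expression-selected negatives, with a label-permutation test for the AUC.
"""

import numpy as np

from cofunmir import (
    FixtureSpec,
    evaluate,
    generate_fixture,
    permutation_test,
    sample_balanced_negatives,
    select_negatives,
)
from cofunmir.pipeline import disease_similarity, mirna_similarity

fixture = generate_fixture(FixtureSpec(seed=1))
dis_sim = disease_similarity(fixture.network, fixture.ontology, alpha=0.8)
mir_sim = mirna_similarity(fixture.network, fixture.sequences, alpha=0.8)

pool = select_negatives(fixture.studies, fixture.positives, threshold=0.05)
negatives = sample_balanced_negatives(pool, len(fixture.positives), seed=7)
samples = fixture.positives + negatives
print(f"{len(fixture.positives)} positives + {len(negatives)} negatives "
      f"(pool of {len(pool)} expression-flat pairs)")

report = evaluate(samples, "loocv", "sqrt", dis_sim, mir_sim, seed=3)
print("\nleave-one-out cross-validation:")
for name, value in report.metrics().items():
    print(f"  {name:12s} {value:.4f}")

observed, null, p = permutation_test(
    samples, 50, "kfold", "sqrt", dis_sim, mir_sim, seed=3, k=5
)
print(f"\npermutation test (50 label permutations, 5-fold CV):")
print(f"  observed AUC {observed:.4f}, null mean {np.mean(null):.4f}, p = {p:.4f}")
print("\nAn AUC near 1 with a chance-level (~0.5) permutation null shows the "
      "kernel separates planted associations, not an artefact of the pipeline.")
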