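"""Nominate negative disease-miRNA pairs from case/control expression data.

A miRNA whose expression barely moves between diseased and control samples
(|log2 fold change| below a small threshold) is treated as unrelated to that
disease.  Pairs already known to be positive are discarded, and only
diseases/miRNAs with at least one known positive association are kept.
"""

import pandas as pd

from cofunmir import ExpressionStudy, PairSample, fold_changes, select_negatives

samples = ["case1", "case2", "case3", "ctrl1", "ctrl2", "ctrl3"]
groups = {s: ("case" if s.startswith("case") else "control") for s in samples}

# miR-up is 2-fold up in disease, miR-down 2-fold down, the others are flat
expression = pd.DataFrame(
    {
        "miR-up":    [8.0, 8.2, 7.9, 4.0, 4.1, 3.9],
        "miR-down":  [2.0, 2.1, 1.9, 4.0, 4.0, 4.1],
        "miR-flat1": [4.0, 4.0, 4.1, 4.0, 4.1, 4.0],
        "miR-flat2": [6.0, 6.1, 6.0, 6.0, 6.0, 6.1],
    },
    index=samples,
).T

study = ExpressionStudy(disease="DO:melanoma", expression=expression,
                        groups=groups, study_id="GSE-toy")
print("log2 fold changes (case vs control):")
print(fold_changes(study).round(3))

# miR-flat1 is a known positive for this disease; miR-flat2 is positive
# elsewhere, so it survives the positive-entity refinement
positives = [
    PairSample("DO:melanoma", "miR-flat1", 1),
    PairSample("DO:other", "miR-flat2", 1),
]
negatives = select_negatives([study], positives, threshold=0.05)
print("\nselected negative pairs (flat, not positive, entities vouched for):")
print(negatives.records.to_string(index=False))
print("\nOnly (DO:melanoma, miR-flat2) qualifies: the dysregulated miRNAs and "
      "the known positive are excluded.")
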