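"""Published reference data used in worked examples and checks.

Six-class growth-stage confusion matrices reported for SVM models
classifying the growth stage (6, 8, 10, 24, 30 and 52 h of culture) of
two soil bacteria, Pseudomonas putida KT2440 and Paenibacillus polymyxa
ATCC 39564, from single-cell innate fluorescence signatures.  Rows are
the predicted stage, columns the true stage.
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix

GROWTH_STAGES = ["6 h", "8 h", "10 h", "24 h", "30 h", "52 h"]

# rows = predicted stage, columns = true stage
P_PUTIDA_GROWTH_STAGE_COUNTS = np.array(
    [
        [17, 5, 2, 1, 0, 0],
        [5, 15, 6, 0, 0, 0],
        [5, 1, 14, 1, 0, 0],
        [3, 0, 0, 6, 2, 2],
        [0, 0, 0, 5, 8, 1],
        [1, 2, 0, 1, 3, 20],
    ]
)

P_POLYMYXA_GROWTH_STAGE_COUNTS = np.array(
    [
        [23, 2, 3, 0, 3, 3],
        [2, 14, 3, 0, 2, 0],
        [2, 2, 62, 2, 4, 3],
        [1, 0, 2, 9, 1, 0],
        [2, 0, 8, 1, 10, 2],
        [1, 1, 2, 1, 1, 8],
    ]
)

# per-class accuracies as printed alongside the matrices (2-decimal display)
P_PUTIDA_REPORTED_ACCURACY = [0.55, 0.65, 0.64, 0.43, 0.62, 0.87]
P_POLYMYXA_REPORTED_ACCURACY = [0.74, 0.74, 0.78, 0.69, 0.48, 0.50]


def growth_stage_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The two published growth-stage confusion matrices as objects."""
    return {
        "P. putida": ConfusionMatrix(P_PUTIDA_GROWTH_STAGE_COUNTS, list(GROWTH_STAGES)),
        "P. polymyxa": ConfusionMatrix(P_POLYMYXA_GROWTH_STAGE_COUNTS, list(GROWTH_STAGES)),
    }
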