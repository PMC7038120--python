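"""Published worked examples of seven-class confusion matrices.

Four single-participant confusion matrices from a study of the same seven
activity classes (rows = predicted, columns = true), with the recall,
precision and F1 percentages printed alongside them.  They serve as exact
regression oracles for `compute_metrics`: row-wise precision, column-wise
recall, F1 with beta = 1 and half-up integer rounding reproduce every
printed cell.

Matrix keys: 'acc' / 'acc_gps' crossed with training scenario 's1'
(semi-structured training data) and 's2' (combined training data).
"""
from __future__ import annotations

import numpy as np

CLASS_ORDER = ("cycling", "lying", "non_level_walking", "running", "sitting", "standing", "walking")

#: counts[predicted, true] in CLASS_ORDER.
CONFUSION_COUNTS = {
    "s1_acc": np.array(
        [
            [168, 0, 9, 0, 0, 0, 0],
            [0, 124, 0, 0, 0, 1, 0],
            [0, 0, 209, 0, 0, 0, 163],
            [1, 0, 0, 113, 0, 0, 0],
            [0, 1, 0, 0, 108, 0, 0],
            [0, 0, 0, 0, 1, 62, 0],
            [47, 0, 279, 0, 0, 0, 394],
        ]
    ),
    "s1_acc_gps": np.array(
        [
            [165, 0, 10, 0, 0, 0, 0],
            [0, 124, 0, 0, 0, 1, 0],
            [0, 0, 278, 0, 0, 0, 89],
            [1, 0, 0, 112, 0, 0, 0],
            [0, 1, 0, 0, 107, 0, 0],
            [0, 0, 0, 0, 0, 66, 0],
            [2, 0, 192, 0, 0, 0, 523],
        ]
    ),
    "s2_acc": np.array(
        [
            [743, 0, 2, 0, 0, 0, 0],
            [0, 185, 1, 0, 1, 0, 0],
            [2, 0, 800, 1, 0, 0, 91],
            [0, 0, 0, 320, 0, 0, 0],
            [0, 1, 0, 0, 170, 1, 0],
            [0, 1, 0, 0, 0, 157, 0],
            [0, 0, 233, 2, 0, 1, 885],
        ]
    ),
    "s2_acc_gps": np.array(
        [
            [738, 0, 0, 0, 0, 0, 0],
            [0, 186, 1, 0, 0, 0, 0],
            [1, 0, 810, 1, 0, 0, 63],
            [0, 0, 0, 318, 0, 0, 1],
            [0, 1, 0, 0, 166, 1, 0],
            [0, 1, 0, 0, 3, 158, 0],
            [1, 0, 97, 2, 0, 1, 1018],
        ]
    ),
}

#: Printed per-class (recall, precision, F1) percentages, in CLASS_ORDER.
PRINTED_METRICS = {
    "s1_acc": [
        (78, 95, 85),
        (99, 99, 99),
        (42, 56, 48),
        (100, 99, 100),
        (99, 99, 99),
        (98, 98, 98),
        (71, 55, 62),
    ],
    "s1_acc_gps": [
        (98, 94, 96),
        (99, 99, 99),
        (58, 76, 66),
        (100, 99, 100),
        (100, 99, 100),
        (99, 100, 99),
        (85, 73, 79),
    ],
    "s2_acc": [
        (100, 100, 100),
        (99, 99, 99),
        (77, 89, 83),
        (99, 100, 100),
        (99, 99, 99),
        (99, 99, 99),
        (91, 79, 84),
    ],
    "s2_acc_gps": [
        (100, 100, 100),
        (99, 99, 99),
        (89, 93, 91),
        (99, 100, 99),
        (98, 99, 99),
        (99, 98, 98),
        (94, 91, 93),
    ],
}
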