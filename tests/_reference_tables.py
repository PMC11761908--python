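"""Published fold-wise evaluation tables used as test inputs.

Per-fold per-class precision/recall/F1 (percent) and fold accuracy for the
two cross-validation experiments (real data only, and real + GAN-augmented
training data), plus the printed summary rows they aggregate to.
"""

# fold: (benign (pre, rec, f1), malignant (pre, rec, f1), accuracy)
REAL_FOLDS = {
    1: ((88.924, 76.0, 81.955), (79.045, 90.533, 84.400), 83.267),
    2: ((86.898, 86.667, 86.782), (86.702, 86.933, 86.818), 86.8),
    3: ((91.265, 80.8, 85.714), (82.775, 92.267, 87.264), 86.533),
    4: ((90.054, 89.333, 89.692), (89.418, 90.133, 89.774), 89.733),
    5: ((85.185, 92.0, 88.462), (91.304, 84.0, 87.500), 88.0),
}

REAL_AVERAGE = {
    "benign": (88.4652, 84.96, 86.521),
    "malignant": (85.8488, 88.7732, 87.1512),
    "overall": (87.157, 86.8666, 86.8361),
    "accuracy": 86.867,
}

AUGMENTED_FOLDS = {
    1: ((92.945, 95.733, 94.319), (95.601, 92.733, 94.146), 94.233),
    2: ((95.652, 96.8, 96.223), (96.761, 95.6, 96.177), 96.2),
    3: ((95.976, 97.0, 96.485), (96.968, 95.933, 96.448), 96.467),
    4: ((97.642, 96.6, 97.118), (96.636, 97.667, 97.149), 97.133),
    5: ((97.732, 97.667, 97.699), (97.668, 97.733, 97.701), 97.7),
}

AUGMENTED_AVERAGE = {
    "benign": (95.9894, 96.76, 96.3688),
    "malignant": (96.7268, 95.9332, 96.3242),
    "overall": (96.3581, 96.3466, 96.3465),
    "accuracy": 96.347,
}

# rows whose printed F1 is exactly the harmonic mean of the printed
# precision and recall (to 3 decimals)
F1_CONSISTENT_ROWS = [
    ("real", 2, "benign"), ("real", 2, "malignant"),
    ("real", 3, "benign"), ("real", 3, "malignant"),
    ("real", 4, "benign"), ("real", 4, "malignant"),
    ("augmented", 2, "benign"), ("augmented", 2, "malignant"),
]

# reported improvement deltas (percentage points) between the two
# experiments' summary rows
IMPROVEMENT_DELTAS = {
    ("overall", "precision"): 9.20,
    ("benign", "recall"): 11.80,
    ("malignant", "precision"): 10.88,
}

# per-class test supports behind the tables (balanced 2600-image test set)
TEST_SUPPORT = 1300
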