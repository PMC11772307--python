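"""Shared test utilities: independent oracles and scoring helpers."""

import numpy as np

import turtlehr as t


def match_events(detected, truth, tol_s=0.1):
    """Greedy one-to-one matching of detected to true event times within a
    tolerance; returns (tp, fp, fn)."""
    detected = np.sort(np.asarray(detected))
    truth = np.sort(np.asarray(truth))
    i = j = tp = 0
    while i < detected.size and j < truth.size:
        d = detected[i] - truth[j]
        if abs(d) <= tol_s:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return tp, detected.size - tp, truth.size - tp


def f1_score(detected, truth, tol_s=0.1):
    tp, fp, fn = match_events(detected, truth, tol_s)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def brute_force_phases(statuses, min_minutes):
    """Independent oracle for phase segmentation: enumerate maximal
    same-status runs one minute at a time, then filter by length."""
    runs = []
    i = 0
    n = len(statuses)
    while i < n:
        j = i
        while j < n and statuses[j] == statuses[i]:
            j += 1
        runs.append((str(statuses[i]), i, j))
        i = j
    return [(s, a, b) for s, a, b in runs if b - a >= min_minutes]


def make_evals(placement, counts):
    """Build placement evaluations with the given (undetectable, unclear,
    clear) counts at one placement."""
    evals = []
    i = 0
    for grade, n in zip(("undetectable", "unclear", "clear"), counts):
        for _ in range(n):
            evals.append(t.PlacementEvaluation(f"T{placement}{i:03d}", placement, grade))
            i += 1
    return evals
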