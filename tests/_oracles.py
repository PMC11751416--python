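"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the definitions, not the package's vectorised
code: exhaustive O(n^2) pair enumeration with explicit conditionals.
"""

import numpy as np


def brute_force_cindex(F, labels):
    """Exhaustive time-dependent concordance over all ordered pairs.

    A pair (i, j) is comparable when i has an event in bin k_i and j's
    observed bin is strictly later, or equal with j censored. Concordant
    when F_i(k_i) > F_j(k_i); exact ties get half credit.
    """
    F = np.asarray(F, dtype=float)
    num = den = 0.0
    n = len(labels)
    for i in range(n):
        if labels[i].event != 1:
            continue
        ki = labels[i].bin
        for j in range(n):
            if j == i:
                continue
            comparable = labels[j].bin > ki or (
                labels[j].bin == ki and labels[j].event == 0)
            if not comparable:
                continue
            den += 1
            if F[i, ki] > F[j, ki]:
                num += 1
            elif F[i, ki] == F[j, ki]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_force_auroc(scores, labels):
    """Exhaustive pairwise AUROC with half credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    num = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / (len(pos) * len(neg))
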