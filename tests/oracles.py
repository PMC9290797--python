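"""Independent oracles used by the test suite."""

import numpy as np


def pairwise_pi_oracle(alleles, length):
    """Mean pairwise Hamming difference over all haplotype pairs / bp length.

    Independent oracle for window pi; assumes no missing data.
    """
    A = np.asarray(alleles)
    n = A.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((A[i] != A[j]).sum())
            pairs += 1
    return total / pairs / length


def four_point_oracle(D, o, w, e, i):
    """Quartet topology from the four-point condition on a distance matrix.

    Returns 1 for {O,E}|{W,I}, 2 for {O,W}|{E,I}, 3 for {O,I}|{W,E},
    0 when unresolved (tied minimum).
    """
    s1 = D[o, e] + D[w, i]
    s2 = D[o, w] + D[e, i]
    s3 = D[o, i] + D[w, e]
    sums = [s1, s2, s3]
    order = sorted(sums)
    if order[1] - order[0] <= 1e-12:
        return 0
    return int(np.argmin(sums)) + 1
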