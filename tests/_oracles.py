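"""Independent brute-force reference implementations used to check the
package's vectorized code paths.  These stay deliberately naive."""

import numpy as np


def conv1d_loops(x, weight, bias):
    """Triple-loop 1-D convolution: y[m, j] = sum_n sum_i W[m,n,i] x[n, j+i] + b[m].

    x: (C_in, L); weight: (C_out, C_in, k); bias: (C_out,).
    """
    c_out, c_in, k = weight.shape
    l_out = x.shape[1] - k + 1
    y = np.zeros((c_out, l_out))
    for m in range(c_out):
        for j in range(l_out):
            acc = bias[m]
            for n in range(c_in):
                for i in range(k):
                    acc += weight[m, n, i] * x[n, j + i]
            y[m, j] = acc
    return y


def auc_pairwise(labels, scores):
    """AUC as the fraction of positive-negative pairs ranked correctly,
    ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def percentile_ci_sorted(values, lo=2.5, hi=97.5):
    """Empirical percentiles computed directly from order statistics with
    linear interpolation (matches numpy's default definition)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def pct(q):
        h = (q / 100.0) * (n - 1)
        low = int(np.floor(h))
        high = int(np.ceil(h))
        return v[low] + (h - low) * (v[high] - v[low])

    return pct(lo), pct(hi)
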