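"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force grid
search for the logistic likelihood, O(n^2) pairwise concordance for the AUC,
and direct ANOVA arithmetic for the ICC.
"""

import numpy as np


def grid_search_deviance(X, y, n_refine=24, span=8.0, points=9):
    """Coordinate-refined grid minimizer of the logistic deviance."""
    Xc = np.column_stack([np.ones(len(y)), X])
    p = Xc.shape[1]
    center = np.zeros(p)
    width = span
    best = None
    for _ in range(n_refine):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        betas = np.column_stack([m.ravel() for m in mesh])
        eta = betas @ Xc.T
        dev = 2 * np.sum(np.logaddexp(0.0, eta) - y[None, :] * eta, axis=1)
        i = int(np.argmin(dev))
        center = betas[i]
        best = dev[i]
        width *= 0.55
    return best, center


def concordance_auc(scores, labels):
    """Mann-Whitney concordance probability, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def icc_anova_oracle(x):
    """ICC(A,1) from the raw two-way ANOVA decomposition of an n x k table."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2
           ).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
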