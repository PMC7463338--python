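"""Independent brute-force oracles used only by the test suite.

Deliberately written as plain loops over the textbook formulas, sharing no
code with the package implementation they check.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def wc_theta_brute(pops_per_locus: list[list[list[tuple]]]) -> float:
    """Weir & Cockerham (1984) multi-allelic theta, ratio of summed
    components across loci.

    ``pops_per_locus[locus][pop]`` is a list of genotype tuples (a1, a2) for
    the non-missing individuals of that population at that locus.
    """
    num = 0.0
    den = 0.0
    for pops in pops_per_locus:
        pops = [p for p in pops if len(p) > 0]
        r = len(pops)
        if r < 2:
            continue
        alleles = sorted({a for pop in pops for g in pop for a in g})
        n_i = [len(pop) for pop in pops]
        nbar = sum(n_i) / r
        if nbar <= 1:
            continue
        sum_n = sum(n_i)
        nc = (sum_n - sum(n**2 for n in n_i) / sum_n) / (r - 1)
        for allele in alleles:
            p_i = [
                sum(g.count(allele) for g in pop) / (2 * n)
                for pop, n in zip(pops, n_i)
            ]
            h_i = [
                sum(1 for g in pop if g[0] != g[1] and allele in g) / n
                for pop, n in zip(pops, n_i)
            ]
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum_n
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / (
                (r - 1) * nbar
            )
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum_n
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2.0
            num += a
            den += a + b + c
    return num / den if den != 0 else float("nan")


def gaussian_posterior_brute(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, n_pcs: int
) -> np.ndarray:
    """Group posteriors from full-PC-space Gaussian densities with pooled
    within-group covariance (denominator n - g) and uniform priors.

    Mathematically identical to a discriminant-subspace posterior with the
    same covariance convention, but computed directly in PC space via
    scipy.stats.multivariate_normal - no discriminant axes involved.
    """
    mean = X_train.mean(axis=0)
    _, _, Vt = np.linalg.svd(X_train - mean, full_matrices=False)
    proj = Vt[:n_pcs].T
    S_train = (X_train - mean) @ proj
    S_test = (X_test - mean) @ proj
    classes = sorted(set(y_train))
    g = len(classes)
    n = len(y_train)
    means = {}
    pooled = np.zeros((n_pcs, n_pcs))
    for c in classes:
        block = S_train[np.asarray(y_train) == c]
        means[c] = block.mean(axis=0)
        centered = block - means[c]
        pooled += centered.T @ centered
    pooled /= n - g
    dens = np.column_stack(
        [
            multivariate_normal.pdf(S_test, mean=means[c], cov=pooled,
                                    allow_singular=True)
            for c in classes
        ]
    )
    return dens / dens.sum(axis=1, keepdims=True)
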