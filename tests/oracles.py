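"""Independent brute-force oracles for the scatter and eigen computations.

Every function here evaluates the defining double sums with explicit
Python loops (or solves eigenproblems via the QZ algorithm on the
explicitly inverted form), deliberately avoiding the vectorized
Laplacian identities and symmetric-definite solvers used by the package.
"""

import numpy as np
from scipy import linalg


def heat_kernel_loop(items, t):
    n = len(items)
    W = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d2 = float(np.sum((np.asarray(items[i]) - np.asarray(items[j])) ** 2))
            W[i, j] = np.exp(-d2 / t)
    return W


def laplacian_loop(W):
    return np.diag(W.sum(axis=1)) - W


def psi_loop(class_blocks, weights, n_f):
    """Eq.-style double sum: 1/(2 N_f) sum_s sum_ij W_ij (Xi-Xj)^T (Xi-Xj)."""
    n_g = class_blocks[0][0].shape[1]
    out = np.zeros((n_g, n_g))
    for mats, W in zip(class_blocks, weights):
        for i in range(len(mats)):
            for j in range(len(mats)):
                D = mats[i] - mats[j]
                out += W[i, j] * (D.T @ D)
    return out / (2 * n_f)


def phi_loop(class_blocks, weights, n_g):
    n_f = class_blocks[0][0].shape[0]
    out = np.zeros((n_f, n_f))
    for mats, W in zip(class_blocks, weights):
        for i in range(len(mats)):
            for j in range(len(mats)):
                D = mats[i] - mats[j]
                out += W[i, j] * (D @ D.T)
    return out / (2 * n_g)


def between_loop(means, B):
    """S_BL and S_BR (with the 1/trace(S_BL) factor) by explicit loops."""
    Z = len(means)
    n_f, n_g = means[0].shape
    S_BL = np.zeros((n_f, n_f))
    S_BR_raw = np.zeros((n_g, n_g))
    for a in range(Z):
        for b in range(Z):
            D = means[a] - means[b]
            S_BL += 0.5 * B[a, b] * (D @ D.T)
            S_BR_raw += 0.5 * B[a, b] * (D.T @ D)
    return S_BL, S_BR_raw / np.trace(S_BL)


def weighted_total_distance(class_blocks, weights):
    """sum_s sum_ij W_ij ||Xi - Xj||_F^2."""
    total = 0.0
    for mats, W in zip(class_blocks, weights):
        for i in range(len(mats)):
            for j in range(len(mats)):
                total += W[i, j] * float(np.sum((mats[i] - mats[j]) ** 2))
    return total


def dlpp_quadratic_loop(vectors, W, a):
    """1/2 sum_ij W_ij (a.(x_i) - a.(x_j))^2 for one direction a."""
    y = [float(a @ v) for v in vectors]
    total = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            total += 0.5 * W[i, j] * (y[i] - y[j]) ** 2
    return total


def gevp_qz(S, T):
    """Generalized eigenvalues of (S, T) via the QZ algorithm, sorted
    ascending.  Independent of the symmetric-definite eigh path."""
    vals = linalg.eig(S, T, right=False)
    vals = np.real(vals)
    return np.sort(vals)


def class_blocks_of(mset):
    """Per-class matrix lists in class order (helper for the loop oracles)."""
    return [list(mset.class_members(c)) for c in range(1, mset.n_classes + 1)]
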