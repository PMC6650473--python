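"""Inference of the latent correlation matrix Sigma.

The dependence between two discrete attributes is summarised by their
plug-in mutual information, corrected for chance with a permutation model
(adjusted mutual information, AMI).  Each latent pairwise correlation
sigma_ij in [0, 1] is then found by bounded Nelder-Mead: simulate a
bivariate sample Y from the pair copula q(. | sigma, (Psi_i, Psi_j)) and
minimise the distance between the data AMI and the AMI of Y.  The full
matrix is assembled cell by cell and projected onto the positive
semidefinite cone.

The latent normal draws behind Y (and the permutation indices behind the
chance correction) are generated once per pair and reused for every sigma
the optimizer visits, so the objective is deterministic during the search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from ._seeding import seed_seq
from .marginals import MarginalModel


class AssociationError(RuntimeError):
    pass


@dataclass
class PairwiseAssociation:
    """Diagnostics of one inferred pair (i, j)."""
    i: int
    j: int
    mi: float  # plug-in mutual information, nats
    ami: float  # adjusted mutual information
    sigma_hat: float
    objective_value: float


def _contingency(col_i, col_j, ki, kj):
    joint = (col_i - 1) * kj + (col_j - 1)
    return np.bincount(joint, minlength=ki * kj).reshape(ki, kj).astype(float)


def _mi_from_table(table):
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    mask = pij > 0
    outer = np.outer(pi, pj)
    return float(np.sum(pij[mask] * (np.log(pij[mask]) - np.log(outer[mask]))))


def _entropy(col, k):
    p = np.bincount(col, minlength=k + 1)[1:] / col.size
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(col_i, col_j) -> float:
    """Plug-in mutual information (nats) from the joint contingency table."""
    col_i = np.asarray(col_i, dtype=np.int64)
    col_j = np.asarray(col_j, dtype=np.int64)
    if col_i.size != col_j.size:
        raise ValueError("columns must have equal length")
    if col_i.size == 0:
        raise ValueError("columns must be non-empty")
    ki, kj = int(col_i.max()), int(col_j.max())
    return max(_mi_from_table(_contingency(col_i, col_j, ki, kj)), 0.0)


def adjusted_mutual_information(col_i, col_j, n_perm: int = 25,
                                seed=None) -> float:
    """MI corrected for chance with a permutation null.

    AI = (I - E[I]) / (max{H_i, H_j} - E[I]) with E[I] the mean MI over
    ``n_perm`` independent permutations of ``col_j``.  May be slightly
    negative through sampling noise.  Returns 0 by convention when the
    denominator vanishes (both columns constant).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    col_i = np.asarray(col_i, dtype=np.int64)
    col_j = np.asarray(col_j, dtype=np.int64)
    if col_i.size != col_j.size:
        raise ValueError("columns must have equal length")
    ki, kj = int(col_i.max()), int(col_j.max())
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, col_j.size)), axis=1)
    return _ami(col_i, col_j, ki, kj, perms)


def _ami(col_i, col_j, ki, kj, perms):
    mi = _mi_from_table(_contingency(col_i, col_j, ki, kj))
    e_mi = np.mean([_mi_from_table(_contingency(col_i, col_j[p], ki, kj))
                    for p in perms])
    h = max(_entropy(col_i, ki), _entropy(col_j, kj))
    denom = h - e_mi
    if denom <= 1e-12:
        return 0.0
    return float((mi - e_mi) / denom)


def infer_pairwise_sigma(col_i, col_j, psi_i: MarginalModel,
                         psi_j: MarginalModel, mc_sample_size: int = 10_000,
                         n_perm: int = 25, tol: float = 1e-3, seed=None,
                         use_adjusted: bool = True,
                         sigma_bounds=(0.0, 1.0)) -> PairwiseAssociation:
    """Latent correlation of one attribute pair by objective minimization.

    The objective is f(sigma) = | A_target - A(Y_1; Y_2) | for sigma inside
    ``sigma_bounds`` and +inf outside, where Y is a synthetic bivariate
    sample of size ``mc_sample_size`` drawn from the pair copula under
    common random numbers, and A is the adjusted (default) or raw mutual
    information.
    """
    col_i = np.asarray(col_i, dtype=np.int64)
    col_j = np.asarray(col_j, dtype=np.int64)
    rng = np.random.default_rng(seed_seq(seed))
    ki = max(int(col_i.max()), psi_i.K)
    kj = max(int(col_j.max()), psi_j.K)

    m = int(mc_sample_size)
    perms_data = np.argsort(rng.random((n_perm, col_j.size)), axis=1)
    if use_adjusted:
        target = _ami(col_i, col_j, ki, kj, perms_data)
    else:
        target = _mi_from_table(_contingency(col_i, col_j, ki, kj))
    mi_raw = mutual_information(col_i, col_j)

    if psi_i.K == 1 or psi_j.K == 1:
        # dependence is unidentifiable against a constant attribute
        return PairwiseAssociation(i=-1, j=-1, mi=mi_raw, ami=target if
                                   use_adjusted else float("nan"),
                                   sigma_hat=0.0, objective_value=0.0)

    # common random numbers: fixed across every sigma evaluation
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    perms_y = np.argsort(rng.random((n_perm, m)), axis=1)
    y1 = psi_i.quantile(ndtr(z1))

    def objective(vec):
        s = float(vec[0])
        if not (sigma_bounds[0] <= s <= sigma_bounds[1]):
            return np.inf
        lat2 = s * z1 + np.sqrt(max(1.0 - s * s, 0.0)) * z2
        y2 = psi_j.quantile(ndtr(lat2))
        if use_adjusted:
            a = _ami(y1, y2, psi_i.K, psi_j.K, perms_y)
        else:
            a = _mi_from_table(_contingency(y1, y2, psi_i.K, psi_j.K))
        return abs(target - a)

    # the CRN objective is deterministic but jagged; a coarse scan picks the
    # basin and a wide initial simplex keeps Nelder-Mead from stalling in it
    lo, hi = sigma_bounds
    grid = np.linspace(lo, hi, 11)
    x0 = float(grid[int(np.argmin([objective([s]) for s in grid]))])
    half_step = (hi - lo) / 20.0
    simplex = np.clip([[x0 - half_step], [x0 + half_step]], lo, hi)
    if simplex[0, 0] == simplex[1, 0]:
        simplex[1, 0] = min(simplex[0, 0] + 2 * half_step, hi)
    res = optimize.minimize(objective, [x0], method="Nelder-Mead",
                            options={"xatol": tol, "fatol": 1e-6,
                                     "maxiter": 200,
                                     "initial_simplex": simplex})
    if not np.isfinite(res.fun):
        raise AssociationError(
            f"sigma inference failed for pair (K={psi_i.K}, K={psi_j.K}): "
            f"objective is non-finite everywhere")
    sigma_hat = float(np.clip(res.x[0], sigma_bounds[0], sigma_bounds[1]))
    return PairwiseAssociation(i=-1, j=-1, mi=mi_raw,
                               ami=target if use_adjusted else float("nan"),
                               sigma_hat=sigma_hat,
                               objective_value=float(res.fun))


def assemble_covariance(pairs: dict[tuple[int, int], PairwiseAssociation],
                        d: int) -> np.ndarray:
    """Assemble the d x d matrix from all d(d-1)/2 pairwise fits."""
    sigma = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            pair = pairs.get((i, j), pairs.get((j, i)))
            if pair is None:
                raise AssociationError(f"missing pairwise fit for ({i}, {j})")
            sigma[i, j] = sigma[j, i] = pair.sigma_hat
    return sigma


def project_psd(matrix, eigen_floor: float = 1e-6,
                renormalize: bool = True) -> np.ndarray:
    """Nearest (Frobenius) PSD matrix by eigenvalue clipping.

    Eigenvalues are clipped at ``eigen_floor`` (> 0 keeps the copula
    density invertible); with ``renormalize`` the clipped matrix is
    rescaled to unit diagonal, D^{-1/2} A D^{-1/2}.  A PSD input with unit
    diagonal is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= eigen_floor:
        return matrix.copy()
    clipped = (vecs * np.maximum(vals, eigen_floor)) @ vecs.T
    clipped = (clipped + clipped.T) / 2
    if renormalize:
        dinv = 1.0 / np.sqrt(np.diag(clipped))
        clipped = clipped * np.outer(dinv, dinv)
        np.fill_diagonal(clipped, 1.0)
    return clipped
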