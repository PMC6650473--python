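"""Marginal distributions of discrete attributes.

Each attribute's marginal law Psi_j is fitted by maximum likelihood over
three candidate families — categorical (plug-in), negative binomial and
logarithmic (log-series) — and selected by BIC = -2 log L + k log n_D.
The two count families have infinite support and are truncated to the
declared sample space 1..K and renormalized, so that F(K) = 1 holds for
the latent rectangle bounds.

Nominal attributes carry no meaningful category order; a seeded uniform
permutation is drawn once at fit time and baked into the model, so that a
record's score is reproducible within a fitted model.  Internally a model
stores its mass over *positions* (the permuted order); code-level pmf/cdf
queries go through the permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import logser, nbinom

FAMILIES = ("categorical", "negative_binomial", "logarithmic")

#: number of free parameters per family (categorical resolved at fit time)
_N_PARAMS = {"negative_binomial": 2, "logarithmic": 1, "exact_counts": 0}


class MarginalFitError(RuntimeError):
    pass


@dataclass
class MarginalModel:
    family: str
    params: dict
    K: int
    order: np.ndarray  # order[code-1] = 0-based position in the CDF ordering
    position_pmf: np.ndarray  # mass per position, sums to 1
    n_params: int
    loglik: float = float("nan")
    bic: float = float("nan")

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=np.int64)
        self.position_pmf = np.asarray(self.position_pmf, dtype=float)
        self._cum = np.cumsum(self.position_pmf)
        self._cum[-1] = 1.0
        self._inv_order = np.empty(self.K, dtype=np.int64)
        self._inv_order[self.order] = np.arange(self.K)

    # -- queries ----------------------------------------------------------
    def pmf(self, code):
        """Probability mass of integer code(s) in 1..K."""
        code = np.asarray(code)
        self._check_codes(code, low=1)
        return self.position_pmf[self.order[code - 1]]

    def cdf(self, code):
        """F(code): cumulative mass through the code's position.

        Accepts the sentinel 0 (F(0) = 0).  For ordinal attributes the
        position order is the code order; for nominal attributes it is the
        baked-in permutation.
        """
        code = np.asarray(code)
        self._check_codes(code, low=0)
        out = np.where(code == 0, 0.0,
                       self._cum[self.order[np.maximum(code, 1) - 1]])
        return out if out.ndim else float(out)

    def cdf_bounds(self, code):
        """(F at the cell's lower edge, F at its upper edge) per code."""
        code = np.asarray(code)
        self._check_codes(code, low=1)
        pos = self.order[code - 1]
        hi = self._cum[pos]
        lo = hi - self.position_pmf[pos]
        return lo, hi

    def quantile(self, u):
        """Generalized inverse: the code whose CDF interval contains u."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("u must lie in [0, 1]")
        pos = np.searchsorted(self._cum, u, side="left")
        pos = np.minimum(pos, self.K - 1)
        out = self._inv_order[pos] + 1
        return out if out.ndim else int(out)

    def _check_codes(self, code, low):
        if np.any(code < low) or np.any(code > self.K):
            raise ValueError(f"codes must lie in {low}..{self.K}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family,
                "params": {k: float(v) for k, v in self.params.items()},
                "K": int(self.K),
                "order": self.order.tolist(),
                "position_pmf": self.position_pmf.tolist(),
                "n_params": int(self.n_params),
                "loglik": float(self.loglik),
                "bic": float(self.bic)}

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalModel":
        return cls(family=d["family"], params=dict(d["params"]), K=int(d["K"]),
                   order=np.asarray(d["order"]),
                   position_pmf=np.asarray(d["position_pmf"]),
                   n_params=int(d["n_params"]), loglik=d.get("loglik", float("nan")),
                   bic=d.get("bic", float("nan")))


# -- family-specific truncated pmfs (support 1..K) -------------------------

def _categorical_pmf(probs):
    return np.asarray(probs, dtype=float)


def _negbin_trunc_pmf(r, theta, K):
    """Negative binomial (size r, success prob theta), shifted to start at
    1 and renormalized over 1..K."""
    raw = nbinom.pmf(np.arange(K), r, theta)
    z = raw.sum()
    if not np.isfinite(z) or z <= 0:
        raise MarginalFitError("degenerate negative-binomial mass")
    return raw / z


def _logser_trunc_pmf(p, K):
    """Log-series on {1, 2, ...} renormalized over 1..K."""
    raw = logser.pmf(np.arange(1, K + 1), p)
    z = raw.sum()
    if not np.isfinite(z) or z <= 0:
        raise MarginalFitError("degenerate log-series mass")
    return raw / z


def _fit_categorical(pos_counts, pseudocount=0.0):
    n = pos_counts.sum()
    probs = (pos_counts + pseudocount) / (n + pseudocount * len(pos_counts))
    with np.errstate(divide="ignore"):
        ll = float(np.sum(pos_counts[pos_counts > 0]
                          * np.log(probs[pos_counts > 0])))
    return probs, {}, ll


def _fit_negbin(pos_counts):
    K = len(pos_counts)
    support = np.arange(K)  # shifted: code m has count value m-1
    n = pos_counts.sum()
    mean = float(support @ pos_counts) / n
    var = float(((support - mean) ** 2) @ pos_counts) / n
    # moment-matching start; near-Poisson columns get a large-r start
    if var > mean > 0:
        r0 = mean ** 2 / (var - mean)
        t0 = mean / var
    else:
        r0, t0 = 50.0, 50.0 / (50.0 + max(mean, 1e-6))
    r0 = float(np.clip(r0, 1e-3, 1e4))
    t0 = float(np.clip(t0, 1e-6, 1 - 1e-6))

    def nll(z):
        r = np.exp(z[0])
        theta = 1 / (1 + np.exp(-z[1]))
        with np.errstate(all="ignore"):
            pmf = nbinom.pmf(support, r, theta)
            z_norm = pmf.sum()
            if not np.isfinite(z_norm) or z_norm <= 0:
                return 1e12
            logp = np.log(np.maximum(pmf / z_norm, 1e-300))
        return -float(pos_counts @ logp)

    x0 = np.array([np.log(r0), np.log(t0 / (1 - t0))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 2000})
    r = float(np.exp(res.x[0]))
    theta = float(1 / (1 + np.exp(-res.x[1])))
    probs = _negbin_trunc_pmf(r, theta, K)
    ll = -float(res.fun)
    if not np.isfinite(ll):
        raise MarginalFitError("negative-binomial likelihood did not converge")
    return probs, {"r": r, "theta": theta}, ll


def _fit_logser(pos_counts):
    K = len(pos_counts)
    support = np.arange(1, K + 1)

    def nll(p):
        with np.errstate(all="ignore"):
            pmf = logser.pmf(support, p)
            z = pmf.sum()
            if not np.isfinite(z) or z <= 0:
                return 1e12
            logp = np.log(np.maximum(pmf / z, 1e-300))
        return -float(pos_counts @ logp)

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 1 - 1e-12),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    p = float(res.x)
    probs = _logser_trunc_pmf(p, K)
    ll = -float(res.fun)
    if not np.isfinite(ll):
        raise MarginalFitError("log-series likelihood did not converge")
    return probs, {"p": p}, ll


_FITTERS = {"categorical": lambda c: _fit_categorical(c),
            "negative_binomial": _fit_negbin,
            "logarithmic": _fit_logser}

#: BIC tie-break preference: fewer parameters first
_TIE_RANK = {"logarithmic": 0, "negative_binomial": 1, "categorical": 2}


def fit_marginal(column, kind: str = "ordinal", families=FAMILIES,
                 seed: int | None = None, cardinality: int | None = None,
                 pseudocount: float = 0.0) -> MarginalModel:
    """Fit one attribute's marginal and select the family by BIC.

    ``column`` holds integer codes in 1..K.  For nominal attributes a
    seeded uniform permutation of the category order is drawn and the
    count families are fitted on the permuted codes; for ordinal
    attributes the order is the identity.  A count family whose
    optimization degenerates is skipped rather than fatal.
    """
    column = np.asarray(column, dtype=np.int64)
    if column.size == 0:
        raise ValueError("cannot fit a marginal on an empty column")
    if not families:
        raise ValueError("at least one candidate family is required")
    K = int(cardinality if cardinality is not None else column.max())
    if column.min() < 1 or column.max() > K:
        raise ValueError(f"codes must lie in 1..{K}")
    counts = np.bincount(column, minlength=K + 1)[1:].astype(float)
    n = counts.sum()

    if kind == "nominal":
        rng = np.random.default_rng(seed)
        order = rng.permutation(K)
    else:
        order = np.arange(K)
    pos_counts = np.zeros(K)
    pos_counts[order] = counts

    candidates = []
    for family in families:
        if family not in _FITTERS:
            raise ValueError(f"unknown family {family!r}")
        if family != "categorical" and K == 1:
            continue  # count families are vacuous on a single category
        try:
            if family == "categorical":
                probs, params, ll = _fit_categorical(pos_counts, pseudocount)
            else:
                probs, params, ll = _FITTERS[family](pos_counts)
        except MarginalFitError:
            continue
        k = K - 1 if family == "categorical" else _N_PARAMS[family]
        bic = -2.0 * ll + k * np.log(n)
        candidates.append((bic, _TIE_RANK[family], family, probs, params, ll, k))
    if not candidates:
        raise MarginalFitError("no marginal family could be fitted")
    bic, _, family, probs, params, ll, k = min(candidates, key=lambda c: c[:2])
    return MarginalModel(family=family, params=params, K=K, order=order,
                         position_pmf=probs, n_params=k, loglik=ll, bic=bic)


def exact_marginal(counts, order=None) -> MarginalModel:
    """Marginal known exogenously with its exact distribution.

    ``counts`` are per-code population counts; the CDF is directly
    available and no parameter is estimated (k = 0).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative and non-empty")
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts must have positive total")
    K = counts.size
    order = np.arange(K) if order is None else np.asarray(order)
    probs = np.zeros(K)
    probs[order] = counts / total
    return MarginalModel(family="exact_counts", params={}, K=K, order=order,
                         position_pmf=probs, n_params=0, loglik=float("nan"),
                         bic=float("nan"))


def marginal_cdf(model: MarginalModel, code):
    """F(code) for codes in 0..K (module-level wrapper)."""
    return model.cdf(code)


def marginal_quantile(model: MarginalModel, u):
    """Generalized-inverse quantile for u in [0, 1] (module-level wrapper)."""
    return model.quantile(u)


# -- constructors for known (ground-truth) marginals -----------------------

def categorical_marginal(probs, order=None) -> MarginalModel:
    """A categorical marginal with known cell probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
        raise ValueError("probs must be a probability vector")
    K = probs.size
    order = np.arange(K) if order is None else np.asarray(order)
    pos = np.zeros(K)
    pos[order] = probs
    return MarginalModel(family="categorical", params={}, K=K, order=order,
                         position_pmf=pos, n_params=K - 1)


def negative_binomial_marginal(r: float, theta: float, K: int) -> MarginalModel:
    """Shifted, truncated negative binomial with known parameters."""
    return MarginalModel(family="negative_binomial",
                         params={"r": r, "theta": theta}, K=K,
                         order=np.arange(K),
                         position_pmf=_negbin_trunc_pmf(r, theta, K),
                         n_params=2)


def logarithmic_marginal(p: float, K: int) -> MarginalModel:
    """Truncated log-series with known parameter."""
    return MarginalModel(family="logarithmic", params={"p": p}, K=K,
                         order=np.arange(K),
                         position_pmf=_logser_trunc_pmf(p, K), n_params=1)
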