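"""The generative engine: Gaussian-copula density, discrete cell
probabilities, and the latent-copula population sampler.

A model couples d discrete marginals Psi_1..Psi_d through a latent
zero-mean multivariate normal with correlation matrix Sigma.  The
probability of a full record x = (x_1, ..., x_d) is the normal mass of
the latent rectangle

    prod_j ( Phi^{-1}(F_j(x_j - 1)), Phi^{-1}(F_j(x_j)) ]

where F_j is the j-th marginal CDF (F_j(0) = 0 maps to -inf and
F_j(K_j) = 1 to +inf).  Sampling goes the other way: draw z ~ N(0, Sigma),
set u_j = Phi(z_j) and x_j = F_j^{-1}(u_j) by the generalized inverse.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr, ndtri

from .marginals import MarginalModel
from .mvnrect import mvn_rectangle_prob, _chol_lower


def copula_density(u, sigma) -> float:
    """Gaussian-copula density c_Sigma(u) at a point of the open unit cube.

    c(u) = det(Sigma)^{-1/2} exp(-1/2 z' (Sigma^{-1} - I) z), z = Phi^{-1}(u).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly inside (0, 1)^d")
    sigma = np.asarray(sigma, dtype=float)
    z = ndtri(u)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("sigma must be positive definite")
    quad = z @ (np.linalg.solve(sigma, z) - z)
    return float(np.exp(-0.5 * logdet - 0.5 * quad))


@dataclass
class CopulaModel:
    """Fitted (or ground-truth) generative model of a discrete population.

    Attributes
    ----------
    sigma : (d, d) latent correlation matrix
    marginals : one fitted marginal per attribute
    population_size : the size n of the complete population
    n_train : number of records the model was trained on (None when the
        model is constructed rather than fitted); drives the small-sample
        scoring guard
    abs_tol, max_points, integration_seed : rectangle-integration options;
        a fixed integration seed makes repeated scoring bit-stable
    """

    sigma: np.ndarray
    marginals: list[MarginalModel]
    population_size: int
    n_train: int | None = None
    abs_tol: float = 1e-6
    max_points: int = 2 ** 17
    integration_seed: int = 0
    _chol: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = len(self.marginals)
        if self.sigma.shape != (d, d):
            raise ValueError("sigma dimension does not match marginals")
        if self.population_size < 1:
            raise ValueError("population size must be >= 1")
        # degenerate (e.g. sigma_ij -> 1) matrices get an epsilon jitter so
        # the latent normal stays non-singular
        self._chol = _chol_lower(self.sigma)

    @property
    def n_attributes(self) -> int:
        return len(self.marginals)

    def latent_bounds(self, records: np.ndarray):
        """Per-record latent rectangle (lower, upper) bounds."""
        records = np.atleast_2d(np.asarray(records, dtype=np.int64))
        d = self.n_attributes
        lo = np.empty(records.shape, dtype=float)
        hi = np.empty(records.shape, dtype=float)
        for j in range(d):
            flo, fhi = self.marginals[j].cdf_bounds(records[:, j])
            with np.errstate(divide="ignore"):
                lo[:, j] = ndtri(flo)
                hi[:, j] = ndtri(np.minimum(fhi, 1.0))
        return lo, hi

    def cell_probabilities(self, records, return_err: bool = False):
        """q(x | Sigma, Psi) for a batch of records.

        Zero-mass cells under any marginal return exactly 0 without
        integration.  Duplicated records are integrated once.
        """
        records = np.atleast_2d(np.asarray(records, dtype=np.int64))
        uniq, inv = np.unique(records, axis=0, return_inverse=True)
        mass = np.ones(uniq.shape[0])
        for j in range(self.n_attributes):
            mass *= self.marginals[j].pmf(uniq[:, j])
        q = np.zeros(uniq.shape[0])
        err = np.zeros(uniq.shape[0])
        live = mass > 0
        if live.any():
            lo, hi = self.latent_bounds(uniq[live])
            q[live], err[live] = mvn_rectangle_prob(
                lo, hi, self.sigma, abs_tol=self.abs_tol,
                max_points=self.max_points, seed=self.integration_seed)
        if return_err:
            return q[inv], err[inv]
        return q[inv]

    def cell_probability(self, record, return_err: bool = False):
        """q(x) for a single record (convenience wrapper)."""
        out = self.cell_probabilities(np.atleast_2d(record),
                                      return_err=return_err)
        if return_err:
            return float(out[0][0]), float(out[1][0])
        return float(out[0])

    def sample(self, n_out: int, seed=None) -> np.ndarray:
        """Draw ``n_out`` i.i.d. records from q via the latent copula.

        z ~ N(0, Sigma); u_j = Phi(z_j); x_j = F_j^{-1}(u_j).
        """
        if n_out < 0:
            raise ValueError("n_out must be >= 0")
        d = self.n_attributes
        if n_out == 0:
            return np.empty((0, d), dtype=np.int64)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_out, d)) @ self._chol.T
        u = ndtr(z)
        out = np.empty((n_out, d), dtype=np.int64)
        for j in range(d):
            out[:, j] = self.marginals[j].quantile(u[:, j])
        return out

    # -- serialization (sigma.csv + marginals.json + meta.json) -----------
    def save(self, path) -> None:
        """Write the model bundle to a directory (or ``.zip``)."""
        path = Path(path)
        names = [f"a{j}" for j in range(self.n_attributes)]
        header = ",".join(names)
        sigma_csv = header + "\n" + "\n".join(
            ",".join(repr(float(v)) for v in row) for row in self.sigma)
        marg_json = json.dumps([m.to_dict() for m in self.marginals])
        meta = json.dumps({"population_size": int(self.population_size),
                           "n_train": self.n_train,
                           "abs_tol": self.abs_tol,
                           "max_points": self.max_points,
                           "integration_seed": self.integration_seed,
                           "format_version": 1})
        if path.suffix == ".zip":
            with zipfile.ZipFile(path, "w") as zf:
                zf.writestr("sigma.csv", sigma_csv)
                zf.writestr("marginals.json", marg_json)
                zf.writestr("meta.json", meta)
        else:
            path.mkdir(parents=True, exist_ok=True)
            (path / "sigma.csv").write_text(sigma_csv)
            (path / "marginals.json").write_text(marg_json)
            (path / "meta.json").write_text(meta)

    @classmethod
    def load(cls, path) -> "CopulaModel":
        path = Path(path)
        if path.suffix == ".zip":
            with zipfile.ZipFile(path) as zf:
                sigma_csv = zf.read("sigma.csv").decode()
                marg = json.loads(zf.read("marginals.json").decode())
                meta = json.loads(zf.read("meta.json").decode())
        else:
            sigma_csv = (path / "sigma.csv").read_text()
            marg = json.loads((path / "marginals.json").read_text())
            meta = json.loads((path / "meta.json").read_text())
        rows = sigma_csv.strip().splitlines()[1:]
        sigma = np.array([[float(v) for v in r.split(",")] for r in rows])
        return cls(sigma=sigma,
                   marginals=[MarginalModel.from_dict(m) for m in marg],
                   population_size=meta["population_size"],
                   n_train=meta.get("n_train"),
                   abs_tol=meta.get("abs_tol", 1e-6),
                   max_points=meta.get("max_points", 2 ** 17),
                   integration_seed=meta.get("integration_seed", 0))

    def fingerprint(self) -> str:
        """Short stable hash of the model contents, for score provenance."""
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.sigma).tobytes())
        for m in self.marginals:
            h.update(json.dumps(m.to_dict(), sort_keys=True).encode())
        h.update(str(self.population_size).encode())
        return h.hexdigest()[:16]


def cell_probability(record, model: CopulaModel, return_err: bool = False):
    """Module-level convenience: q(x | Sigma, Psi) for one record."""
    return model.cell_probability(record, return_err=return_err)


def sample_population(model: CopulaModel, n_out: int, seed=None) -> np.ndarray:
    """Module-level convenience: latent-copula population sampler."""
    return model.sample(n_out, seed=seed)
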