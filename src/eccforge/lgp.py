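"""Local Gaussian-process (LGP) surrogate for simulation-derived properties.

One independent GP per target property, each restricted at query time to
the k nearest training points (scaled-Euclidean distance in the unit
hypercube defined by the parameter bounds).  Kernel: constant ×
squared-exponential with per-dimension lengthscales plus a white-noise
term.  Hyperparameters are re-optimized by marginal-likelihood
maximization at every retrain event (on a capped subsample, for speed)
and then held fixed for the cheap per-query local fits.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

DEFAULT_LOCALITY = 50
RETRAIN_EVERY = 50
_HYPEROPT_CAP = 150  # points used for marginal-likelihood maximization


class SurrogateError(RuntimeError):
    pass


class LocalGaussianProcess:
    """k-nearest-neighbour local GP regression over named properties.

    Parameters
    ----------
    bounds
        Per-dimension (lo, hi) used to scale inputs to the unit hypercube
        before distances and kernels (σ in nm and ϵ in kJ/mol differ by
        orders of magnitude otherwise).
    locality
        Number of nearest training points used per query; ``None`` or a
        value >= the training-set size reproduces a global GP.
    """

    def __init__(
        self,
        bounds: list[tuple[float, float]],
        locality: int | None = DEFAULT_LOCALITY,
        noise_level: float = 1e-6,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.bounds = np.asarray(bounds, dtype=float)
        self.locality = locality
        self.noise_level = noise_level
        self.rng = rng or np.random.default_rng(0)
        self.X: np.ndarray | None = None  # scaled inputs (n, d)
        self.Y: dict[str, np.ndarray] = {}
        self._kernels: dict[str, object] = {}
        self.retrain_count = 0

    # -- data ------------------------------------------------------------

    def _scale(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.atleast_2d(theta) - lo) / span

    @property
    def n_training(self) -> int:
        return 0 if self.X is None else self.X.shape[0]

    def fit(self, thetas: np.ndarray, properties: dict[str, np.ndarray]) -> None:
        """(Re)train on the full data set; re-optimizes hyperparameters."""
        X = self._scale(np.asarray(thetas, dtype=float))
        if X.shape[0] < 2:
            raise SurrogateError("need at least 2 training points")
        self.X = X
        self.Y = {k: np.asarray(v, dtype=float) for k, v in properties.items()}
        n, d = X.shape
        sub = (
            self.rng.choice(n, size=_HYPEROPT_CAP, replace=False)
            if n > _HYPEROPT_CAP
            else np.arange(n)
        )
        for prop, y in self.Y.items():
            kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
                length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2)
            ) + WhiteKernel(self.noise_level, (1e-12, 1e-1))
            gpr = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, n_restarts_optimizer=0,
                random_state=0,
            )
            try:
                with warnings.catch_warnings():
                    # hyperparameter search may stop early on flat likelihoods;
                    # the incumbent kernel is still usable
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gpr.fit(X[sub], y[sub])
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SurrogateError(f"degenerate kernel matrix for {prop}") from exc
            self._kernels[prop] = gpr.kernel_
        self.retrain_count += 1

    # -- prediction ------------------------------------------------------

    def _neighbours(self, x: np.ndarray) -> np.ndarray:
        d2 = ((self.X - x) ** 2).sum(axis=1)
        k = self.locality
        if k is None or k >= d2.size:
            return np.arange(d2.size)
        return np.argpartition(d2, k)[:k]

    def predict(self, theta: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        """Mean and variance per property at one parameter vector.

        Direct Cholesky solve on the k-nearest local kernel matrix with
        the hyperparameters frozen at the last retrain; escalating jitter
        is added if the local matrix is numerically degenerate.
        """
        if self.X is None:
            raise SurrogateError("surrogate is untrained")
        from scipy.linalg import cho_factor, cho_solve

        x = self._scale(np.asarray(theta, dtype=float))[0]
        idx = self._neighbours(x)
        Xl = self.X[idx]
        means: dict[str, float] = {}
        variances: dict[str, float] = {}
        for prop, y in self.Y.items():
            yl = y[idx]
            y_mean, y_std = yl.mean(), yl.std()
            if y_std == 0.0:
                y_std = 1.0
            yn = (yl - y_mean) / y_std
            kernel = self._kernels[prop]
            K = kernel(Xl)
            k_star = kernel(Xl, x[None, :])[:, 0]
            k_ss = float(kernel(x[None, :])[0, 0])
            for jitter in (0.0, 1e-10, 1e-8, 1e-6):
                try:
                    cf = cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
                    break
                except np.linalg.LinAlgError:
                    continue
            else:
                raise SurrogateError(
                    f"kernel matrix degenerate for {prop} after jitter escalation"
                )
            alpha = cho_solve(cf, yn)
            v = cho_solve(cf, k_star)
            mu = float(k_star @ alpha) * y_std + y_mean
            var = max(k_ss - float(k_star @ v), 0.0) * y_std**2
            means[prop] = mu
            variances[prop] = var
        return means, variances
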