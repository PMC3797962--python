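"""Covariance matrix adaptation evolution strategy.

A self-contained (mu/mu_w, lambda)-CMA-ES: candidate parameter vectors are
sampled from an adapted multivariate Gaussian, ranked by cost, and the
distribution mean, step size (cumulative step-size adaptation) and
covariance (rank-1 plus rank-mu updates) are updated from the better half.
Parameter settings follow the standard defaults, including the population
size lambda = 4 + floor(3 ln n).
"""

from __future__ import annotations

import numpy as np


class CMAES:
    """Ask/tell interface; minimizes.  Deterministic given the seed."""

    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float,
        seed: int | None = 0,
        popsize: int | None = None,
    ):
        self.x0 = np.asarray(x0, dtype=float).copy()
        self.n = len(self.x0)
        if not sigma0 > 0:
            raise ValueError("sigma0 must be positive")
        self.sigma0 = float(sigma0)
        self.rng = np.random.default_rng(seed)
        n = self.n
        self.lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        self.c_sigma = (self.mueff + 2) / (n + self.mueff + 5)
        self.d_sigma = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.c_sigma
        self.c_c = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.c_1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.c_mu = min(
            1 - self.c_1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))
        self._reset_distribution(self.x0, self.sigma0)
        self.generation = 0

    def _reset_distribution(self, mean, sigma):
        n = self.n
        self.mean = np.asarray(mean, dtype=float).copy()
        self.sigma = float(sigma)
        self.C = np.eye(n)
        self.p_sigma = np.zeros(n)
        self.p_c = np.zeros(n)
        self._decompose()

    def _decompose(self):
        self.C = (self.C + self.C.T) / 2.0
        eigvals, self.B = np.linalg.eigh(self.C)
        eigvals = np.maximum(eigvals, 1e-30)
        self.D = np.sqrt(eigvals)
        self._degenerate = eigvals.max() / eigvals.min() > 1e14

    def ask(self) -> np.ndarray:
        """Sample a (lambda, n) array of candidates."""
        z = self.rng.standard_normal((self.lam, self.n))
        self._last_z = z
        return self.mean + self.sigma * (z * self.D) @ self.B.T

    def tell(self, solutions: np.ndarray, costs) -> None:
        costs = np.asarray(costs, dtype=float)
        order = np.argsort(costs, kind="stable")
        sel = solutions[order[: self.mu]]
        y = (sel - self.mean) / self.sigma          # (mu, n)
        y_w = self.weights @ y

        n = self.n
        # C^{-1/2} y_w in the eigenbasis
        c_inv_half_yw = self.B @ ((self.B.T @ y_w) / self.D)
        self.p_sigma = (1 - self.c_sigma) * self.p_sigma + np.sqrt(
            self.c_sigma * (2 - self.c_sigma) * self.mueff
        ) * c_inv_half_yw
        self.generation += 1
        denom = np.sqrt(1 - (1 - self.c_sigma) ** (2 * self.generation))
        h_sigma = float(
            np.linalg.norm(self.p_sigma) / denom < (1.4 + 2 / (n + 1)) * self.chi_n
        )
        self.p_c = (1 - self.c_c) * self.p_c + h_sigma * np.sqrt(
            self.c_c * (2 - self.c_c) * self.mueff
        ) * y_w

        rank_mu = (y * self.weights[:, None]).T @ y
        self.C = (
            (1 - self.c_1 - self.c_mu) * self.C
            + self.c_1
            * (
                np.outer(self.p_c, self.p_c)
                + (1 - h_sigma) * self.c_c * (2 - self.c_c) * self.C
            )
            + self.c_mu * rank_mu
        )
        self.mean = self.mean + self.sigma * y_w
        self.sigma = self.sigma * np.exp(
            (self.c_sigma / self.d_sigma)
            * (np.linalg.norm(self.p_sigma) / self.chi_n - 1)
        )
        self._decompose()
        # restart with a fresh step size on numerical degeneracy
        if (
            self._degenerate
            or not np.all(np.isfinite(self.C))
            or not np.isfinite(self.sigma)
            or self.sigma <= 0
        ):
            self._reset_distribution(self.mean if np.all(np.isfinite(self.mean)) else self.x0,
                                     self.sigma0)
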