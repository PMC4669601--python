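"""Beta model for the per-chromosome allele-frequency spectrum.

Observed allele-1 frequencies ``x_k`` on a chromosome are treated as draws
from ``Beta(alpha, beta)``. The shape parameters are estimated by minimising
the negative log-likelihood with a bound-constrained limited-memory BFGS
scheme started at the method-of-moments point. A fitted model can then sample
new frequencies subject to a minor-allele-frequency (MAF) floor by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .panel import HaplotypePanel

__all__ = [
    "BetaFit",
    "BetaFrequencyModel",
    "allele_frequencies",
    "beta_nll",
    "fit_beta",
    "sample_frequency",
    "FitError",
    "SamplingError",
]


class FitError(RuntimeError):
    """Raised when a beta fit cannot be performed on the given frequencies."""


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the MAF limit."""


@dataclass(frozen=True)
class BetaFit:
    """Fitted beta shape parameters for one chromosome's frequency spectrum."""

    alpha_hat: float
    beta_hat: float
    nll: float
    converged: bool
    n_obs: int


def allele_frequencies(panel: HaplotypePanel, chromosome: str) -> np.ndarray:
    """Allele-1 frequency of every marker on ``chromosome``: column mean."""
    return panel.chromosome_alleles(chromosome).mean(axis=0)


def beta_nll(alpha: float, beta: float, freqs: np.ndarray) -> float:
    """Negative log-likelihood of ``freqs`` under ``Beta(alpha, beta)``.

    All frequencies must lie strictly inside (0, 1); boundary clamping is the
    caller's responsibility (see :func:`fit_beta`).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"shape parameters must be positive, got ({alpha}, {beta})")
    x = np.asarray(freqs, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    return -float(np.sum(stats.beta.logpdf(x, alpha, beta)))


def _moment_start(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    v = float(np.var(x))
    if v <= 0:
        return 1.0, 1.0
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return 1.0, 1.0
    return max(m * common, 1e-3), max((1.0 - m) * common, 1e-3)


class BetaFrequencyModel(BaseEstimator):
    """Maximum-likelihood beta fit of an allele-frequency sample.

    Parameters
    ----------
    boundary_eps : float
        Frequencies are clamped to ``[boundary_eps, 1 - boundary_eps]`` before
        likelihood evaluation (the beta log-density diverges at 0 and 1).
        When fitting from a panel use ``1 / (2 N)`` with N the haplotype
        count, the resolution below which a realized frequency cannot fall.
    shape_floor : float
        Lower optimisation bound on both shapes.
    gtol, max_iter : float, int
        L-BFGS-B projected-gradient tolerance and iteration cap.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted shape parameters.
    nll_ : float
        Negative log-likelihood at the optimum.
    converged_ : bool
    n_obs_ : int
    """

    def __init__(
        self,
        boundary_eps: float = 1e-6,
        shape_floor: float = 1e-6,
        gtol: float = 1e-8,
        max_iter: int = 500,
    ) -> None:
        self.boundary_eps = boundary_eps
        self.shape_floor = shape_floor
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "BetaFrequencyModel":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10:
            raise FitError(f"need at least 10 frequencies to fit a beta, got {x.size}")
        if np.ptp(x) == 0:
            raise FitError(
                "all frequencies identical: the beta likelihood is degenerate; "
                "provide more (polymorphic) markers"
            )
        x = np.clip(x, self.boundary_eps, 1.0 - self.boundary_eps)
        s_log_x = float(np.sum(np.log(x)))
        s_log_1mx = float(np.sum(np.log1p(-x)))
        n = x.size

        def nll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            a, b = theta
            lnB = special.betaln(a, b)
            nll = -((a - 1) * s_log_x + (b - 1) * s_log_1mx - n * lnB)
            dig_ab = special.digamma(a + b)
            ga = -(s_log_x - n * (special.digamma(a) - dig_ab))
            gb = -(s_log_1mx - n * (special.digamma(b) - dig_ab))
            return nll, np.array([ga, gb])

        x0 = np.array(_moment_start(x))
        res = optimize.minimize(
            nll_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(self.shape_floor, None)] * 2,
            options={"gtol": self.gtol, "maxiter": self.max_iter},
        )
        nll_start, _ = nll_and_grad(x0)
        # L-BFGS-B never reports a point worse than its start, but guard anyway
        if res.fun > nll_start:
            res.x, res.fun = x0, nll_start
        self.alpha_, self.beta_ = float(res.x[0]), float(res.x[1])
        self.nll_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.n_obs_ = n
        return self

    @property
    def fit_(self) -> BetaFit:
        return BetaFit(self.alpha_, self.beta_, self.nll_, self.converged_, self.n_obs_)

    def sample(
        self,
        rng: np.random.Generator,
        maf_limit: float = 0.0,
        n_haplotypes: int | None = None,
        size: int | None = None,
        max_draws: int = 1_000_000,
    ) -> float | np.ndarray:
        """Draw frequencies from the fitted beta, honouring a MAF floor.

        Rejection sampling: a draw ``x`` is accepted iff ``min(x, 1-x) >=
        maf_limit`` and, when ``n_haplotypes`` is given, the discretized count
        ``round(N x)`` also satisfies the floor (the MAF of an output marker
        is a property of realized counts).
        """
        if not 0.0 <= maf_limit < 0.5:
            raise ValueError(f"maf_limit must be in [0, 0.5), got {maf_limit}")
        want = 1 if size is None else int(size)
        out: list[float] = []
        drawn = 0
        chunk = max(4 * want, 256)
        while len(out) < want:
            if drawn >= max_draws:
                frac = len(out) / max(drawn, 1)
                raise SamplingError(
                    f"acceptance probability ~{frac:.2e} too low for "
                    f"maf_limit={maf_limit} under Beta({self.alpha_:.3g}, "
                    f"{self.beta_:.3g})"
                )
            x = rng.beta(self.alpha_, self.beta_, size=chunk)
            drawn += chunk
            ok = (np.minimum(x, 1 - x) >= maf_limit) & (x > 0) & (x < 1)
            if n_haplotypes is not None:
                n1 = np.round(n_haplotypes * x)
                maf_real = np.minimum(n1, n_haplotypes - n1) / n_haplotypes
                ok &= maf_real >= maf_limit
            out.extend(x[ok][: want - len(out)])
        return out[0] if size is None else np.array(out)


def fit_beta(freqs, boundary_eps: float = 1e-6) -> BetaFit:
    """Fit ``Beta(alpha, beta)`` to a frequency sample; see BetaFrequencyModel."""
    return BetaFrequencyModel(boundary_eps=boundary_eps).fit(freqs).fit_


def sample_frequency(
    fit: BetaFit,
    maf_limit: float,
    rng: np.random.Generator,
    n_haplotypes: int | None = None,
) -> float:
    """One beta draw with MAF floor, from a frozen :class:`BetaFit`."""
    model = BetaFrequencyModel()
    model.alpha_, model.beta_ = fit.alpha_hat, fit.beta_hat
    model.nll_, model.converged_, model.n_obs_ = fit.nll, fit.converged, fit.n_obs
    return float(model.sample(rng, maf_limit=maf_limit, n_haplotypes=n_haplotypes))
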