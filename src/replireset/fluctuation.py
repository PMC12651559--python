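"""Luria-Delbruck fluctuation analysis.

Estimates the expected number of mutation events per culture, ``m``, from a
vector of per-culture mutant counts by maximum likelihood under the
Luria-Delbruck distribution, and converts it to a mutation rate per
generation, ``mu = m / N_t``, where ``N_t`` is the final number of cells per
culture.

The mutant-count distribution is evaluated with the Ma-Sandri-Sarkar
recursion (mutant relative fitness fixed at 1)::

    p_0 = exp(-m)
    p_k = (m / k) * sum_{j=0}^{k-1} p_j / (k - j + 1),   k >= 1

which is the exact pmf of a compound Poisson process in which each mutation
event founds a clone whose final size K has P(K = k) = 1 / (k (k + 1)) --
the classical "jackpot" clone-size law for a mutation arising at a uniformly
random point of the population's exponential expansion.

The model surface follows the statsmodels convention: build a
:class:`FluctuationModel` from data, call :meth:`~FluctuationModel.fit`, and
read estimates and diagnostics off the returned
:class:`MutationRateResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LDDistribution",
    "luria_delbruck_pmf",
    "FluctuationModel",
    "MutationRateResults",
    "compare_mutation_rates",
]

# Optimisation bracket and tolerance for the 1-D likelihood maximisation.
_M_LOWER = 1e-6
_M_TOL = 1e-6
# Jackpot cultures can carry arbitrarily large mutant counts; the recursion
# is evaluated up to this index and larger counts enter the likelihood
# through the (exact) right-tail mass, i.e. they are treated as censored.
_K_CAP = 512


@dataclass(frozen=True)
class LDDistribution:
    """Truncated Luria-Delbruck pmf: probabilities for 0..K mutants."""

    m: float
    p: np.ndarray

    @property
    def K(self) -> int:
        return len(self.p) - 1

    def tail_mass(self) -> float:
        """Probability of observing more than K mutants."""
        return max(0.0, 1.0 - float(self.p.sum()))


def luria_delbruck_pmf(m: float, K: int) -> LDDistribution:
    """Ma-Sandri-Sarkar recursion for the Luria-Delbruck pmf.

    Parameters
    ----------
    m : float
        Expected number of mutation events per culture (>= 0).
    K : int
        Truncation index; probabilities are returned for 0..K mutants.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if K < 0:
        raise ValueError("K must be non-negative")
    p = np.zeros(K + 1)
    p[0] = np.exp(-m)
    if m == 0.0:
        return LDDistribution(m=m, p=p)
    # p_k = (m/k) sum_{j<k} p_j / (k-j+1); O(K^2), exact.
    for k in range(1, K + 1):
        j = np.arange(k)
        p[k] = m / k * np.sum(p[j] / (k - j + 1))
    return LDDistribution(m=float(m), p=p)


def _loglik(m: float, counts: np.ndarray, K: int) -> float:
    """MSS log-likelihood; counts above K contribute the censored tail mass."""
    dist = luria_delbruck_pmf(m, K)
    capped = counts <= K
    # floor keeps the objective finite for the optimizer at extreme m
    ll = float(np.log(np.maximum(dist.p[counts[capped]], 1e-300)).sum())
    n_tail = int((~capped).sum())
    if n_tail:
        ll += n_tail * np.log(max(dist.tail_mass(), 1e-300))
    return ll


class FluctuationModel:
    """Luria-Delbruck mutation-number model for one fluctuation experiment.

    Parameters
    ----------
    mutant_counts : array-like of int
        Number of resistant colonies per culture.
    titer : float
        Final cells per culture, N_t (mean across titered cultures).
    plating_fraction : float
        Fraction of each culture plated on selection, z in (0, 1].  The
        likelihood itself assumes complete plating (z = 1); when z < 1 a
        warning is emitted and the value is recorded for reporting only.
    """

    def __init__(self, mutant_counts, titer: float, plating_fraction: float = 1.0):
        counts = np.asarray(mutant_counts)
        if counts.size < 2:
            raise ValueError("need at least two cultures")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("mutant counts must be non-negative integers")
            counts = counts.astype(int)
        if titer <= 0:
            raise ValueError("titer must be positive")
        if not (0 < plating_fraction <= 1):
            raise ValueError("plating fraction must be in (0, 1]")
        if plating_fraction < 1:
            warnings.warn(
                "plating_fraction < 1 declared; the estimator assumes complete "
                "plating and does not correct for partial plating",
                UserWarning,
                stacklevel=2,
            )
        self.mutant_counts = counts
        self.titer = float(titer)
        self.plating_fraction = float(plating_fraction)

    @classmethod
    def from_csv(cls, path, titer: float | None = None, plating_fraction: float = 1.0):
        """Read a one-row-per-culture CSV with a ``mutant_count`` column.

        The titer may be given either as an argument or as a ``titer``
        column (its mean is used).
        """
        df = pd.read_csv(path)
        if "mutant_count" not in df.columns:
            raise ValueError("CSV must contain a 'mutant_count' column")
        if titer is None:
            if "titer" not in df.columns:
                raise ValueError("titer not supplied and no 'titer' column present")
            titer = float(df["titer"].mean())
        return cls(df["mutant_count"].to_numpy(), titer, plating_fraction)

    def loglike(self, m: float) -> float:
        K = int(np.clip(self.mutant_counts.max(), 1, _K_CAP))
        return _loglik(m, self.mutant_counts, K)

    def fit(self) -> "MutationRateResults":
        """Maximise the MSS likelihood over m by bounded 1-D optimisation."""
        counts = self.mutant_counts
        K = int(np.clip(counts.max(), 1, _K_CAP))
        if np.all(counts == 0):
            # Likelihood exp(-n m): maximised on the boundary m = 0.
            return MutationRateResults(self, m_hat=0.0, se_m=0.0, converged=True)
        upper = 10.0 * (counts.mean() + 1.0)
        res = optimize.minimize_scalar(
            lambda m: -_loglik(m, counts, K),
            bounds=(_M_LOWER, upper),
            method="bounded",
            options={"xatol": _M_TOL},
        )
        if not res.success:
            raise RuntimeError(f"MSS likelihood optimisation failed: {res.message}")
        m_hat = float(res.x)
        se = self._observed_information_se(m_hat, counts, K)
        return MutationRateResults(self, m_hat=m_hat, se_m=se, converged=True)

    @staticmethod
    def _observed_information_se(m_hat: float, counts: np.ndarray, K: int) -> float:
        h = max(1e-4, 1e-3 * m_hat)
        ll = _loglik(m_hat, counts, K)
        ll_p = _loglik(m_hat + h, counts, K)
        ll_m = _loglik(max(m_hat - h, _M_LOWER / 10), counts, K)
        info = -(ll_p - 2 * ll + ll_m) / h**2
        if info <= 0 or not np.isfinite(info):
            return float("nan")
        return float(1.0 / np.sqrt(info))


class MutationRateResults:
    """Results of a fluctuation-assay fit.

    Attributes
    ----------
    m_hat : float
        MLE of the expected mutations per culture.
    se_m : float
        Standard error from the numerical observed information.
    mu_hat : float
        Mutation rate per generation, ``m_hat / titer`` (default) or
        ``m_hat / (titer * ln 2)`` with ``per_division=True`` at
        construction of the conversion.
    ci95 : (float, float)
        Wald interval ``m_hat +/- 1.96 se``, truncated at zero, on the m
        scale; :attr:`mu_ci95` is the same interval divided by the titer.
    """

    def __init__(self, model: FluctuationModel, m_hat: float, se_m: float,
                 converged: bool, per_division: bool = False):
        self.model = model
        self.m_hat = float(m_hat)
        self.se_m = float(se_m)
        self.converged = converged
        self.per_division = per_division

    @property
    def n_cultures(self) -> int:
        return len(self.model.mutant_counts)

    @property
    def _denominator(self) -> float:
        denom = self.model.titer
        if self.per_division:
            denom *= np.log(2.0)
        return denom

    @property
    def mu_hat(self) -> float:
        return self.m_hat / self._denominator

    @property
    def se_mu(self) -> float:
        return self.se_m / self._denominator

    @property
    def ci95(self) -> tuple[float, float]:
        lo = max(0.0, self.m_hat - 1.96 * self.se_m)
        hi = self.m_hat + 1.96 * self.se_m
        return (lo, hi)

    @property
    def mu_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (lo / self._denominator, hi / self._denominator)

    def compare(self, other: "MutationRateResults", alternative: str = "greater") -> float:
        return compare_mutation_rates(self, other, alternative)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.mu_ci95
        return pd.DataFrame(
            {
                "m_hat": [self.m_hat],
                "se_m": [self.se_m],
                "mu_hat": [self.mu_hat],
                "mu_ci_lo": [lo],
                "mu_ci_hi": [hi],
                "n_cultures": [self.n_cultures],
                "titer": [self.model.titer],
                "plating_fraction": [self.model.plating_fraction],
            }
        )

    def summary(self) -> str:
        lo, hi = self.ci95
        mlo, mhi = self.mu_ci95
        lines = [
            "Fluctuation assay -- MSS maximum likelihood",
            f"  cultures:            {self.n_cultures}",
            f"  m_hat (per culture): {self.m_hat:.6g} +/- {self.se_m:.3g}",
            f"  m 95% CI:            [{lo:.6g}, {hi:.6g}]",
            f"  titer N_t:           {self.model.titer:.6g}",
            f"  mu_hat (per gen):    {self.mu_hat:.6g}",
            f"  mu 95% CI:           [{mlo:.6g}, {mhi:.6g}]",
        ]
        return "\n".join(lines)


def compare_mutation_rates(
    est_a: MutationRateResults, est_b: MutationRateResults, alternative: str = "greater"
) -> float:
    """One-sided (or two-sided) z-test comparing two mutation-rate estimates.

    ``alternative="greater"`` tests mu_a > mu_b.
    """
    se = np.hypot(est_a.se_mu, est_b.se_mu)
    if not np.isfinite(se) or se == 0:
        raise ValueError("zero or non-finite pooled standard error")
    z = (est_a.mu_hat - est_b.mu_hat) / se
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    if alternative == "two-sided":
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown alternative {alternative!r}")
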