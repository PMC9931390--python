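"""Luria–Delbrück fluctuation analysis with partial plating.

Mutation-rate estimation from parallel-culture mutant colony counts under
the Lea–Coulson formulation: mutations arise as a Poisson process during
exponential growth (expected ``m`` mutational events per culture), each
founding a clone whose final size ``j`` follows the heavy-tailed law
``P(j) = 1/(j(j+1))``.  Plating a fraction ``epsilon`` of each culture thins
every clone binomially, which changes the observed count distribution; the
pmf is obtained by a compound-Poisson (Panjer-type) recursion over the
thinned clone-size law.

The per-division mutation rate is ``mu = m / (Nt - N0)`` where ``N0`` and
``Nt`` are the initial and final cells per culture; ``Nt - N0`` is the
number of cell divisions.  Rates are optionally normalized per 1000 bp of
the mutational target gene so loci of different lengths can be compared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationDesign",
    "FluctuationModel",
    "FluctuationResults",
    "clone_pmf",
    "count_pmf",
    "mle_m",
    "profile_ci",
    "mutation_rate",
    "rate_ratio",
]

_TAIL_TOL = 1e-12
_CLONE_CACHE: dict[tuple[float, int], np.ndarray] = {}


@dataclass(frozen=True)
class FluctuationDesign:
    """Design parameters of one fluctuation experiment.

    Parameters
    ----------
    N0, Nt : float
        Initial and final viable cells per culture; ``Nt > N0 > 0``.
    epsilon : float
        Plating efficiency, the fraction of each culture plated on
        selective medium; in ``(0, 1]``.
    gene_length : int
        Length in bp of the mutational target (for per-kb normalization).
    n_cultures : int
        Number of parallel cultures.
    """

    N0: float
    Nt: float
    epsilon: float = 1.0
    gene_length: int = 1000
    n_cultures: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if not (self.Nt > self.N0 > 0):
            raise ValueError("need Nt > N0 > 0")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")


def clone_pmf(epsilon: float, kmax: int) -> np.ndarray:
    """Distribution of observed colonies from a single mutational event.

    A clone of final size ``j ~ P(j)=1/(j(j+1))`` contributes
    ``Binomial(j, epsilon)`` colonies when a fraction ``epsilon`` of the
    culture is plated.  Returns ``q[0..kmax]`` with

        q_k = sum_{j >= max(k,1)} [1/(j(j+1))] C(j,k) eps^k (1-eps)^(j-k)

    evaluated by truncated summation with neglected tail mass < 1e-12.
    ``q_0 = sum_j (1-eps)^j / (j(j+1))`` has the closed form
    ``1 + (eps/(1-eps)) * log(eps)``.
    With ``epsilon = 1`` this reduces to ``q_0 = 0``, ``q_k = 1/(k(k+1))``.
    """
    if not (0.0 < epsilon <= 1.0):
        raise ValueError(f"epsilon must be in (0, 1], got {epsilon}")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    cached = _CLONE_CACHE.get((epsilon, kmax))
    if cached is not None:
        return cached.copy()
    k = np.arange(kmax + 1)
    if epsilon == 1.0:
        q = np.zeros(kmax + 1)
        q[1:] = 1.0 / (k[1:] * (k[1:] + 1.0))
        return q

    q = np.zeros(kmax + 1)
    q[0] = 1.0 + epsilon / (1.0 - epsilon) * math.log(epsilon)

    # Truncated sum over clone sizes j.  Terms decay geometrically in j at
    # rate (1 - epsilon); extend jmax until the geometric tail bound of the
    # largest k drops below tolerance.
    jmax = max(kmax, 64)
    while True:
        j = np.arange(1, jmax + 1, dtype=float)
        w = 1.0 / (j * (j + 1.0))  # clone-size law
        # binom.pmf broadcast: rows k>=1, cols j
        pmf = stats.binom.pmf(k[1:, None], j[None, :], epsilon)
        q[1:] = (w[None, :] * pmf).sum(axis=1)
        # Tail bound: for j > jmax the term for each k is bounded by
        # w_j * P(Bin(j,eps)=k) <= (1/jmax^2) * (1-eps)^(j-k) * C(j,k) eps^k.
        # Conservatively bound with the ratio of successive terms r < 1.
        r = (1.0 - epsilon) * (jmax + 1.0) / max(jmax + 1.0 - kmax, 1.0)
        if r < 1.0:
            last = (w[-1] * pmf[:, -1]).max()
            if last * r / (1.0 - r) < _TAIL_TOL:
                break
        jmax *= 2
        if jmax > 10_000_000:  # pragma: no cover - defensive
            warnings.warn("clone_pmf truncation bound not reached", stacklevel=2)
            break
    _CLONE_CACHE[(epsilon, kmax)] = q.copy()
    return q


def _log_count_pmf(m: float, epsilon: float, nmax: int) -> np.ndarray:
    """log p_0..p_nmax by the compound-Poisson recursion, rescaled to stay
    in floating range for large ``m`` or jackpot counts."""
    q = clone_pmf(epsilon, max(nmax, 1))
    kq = np.arange(nmax + 1) * q  # k * q_k
    # run the recursion on r_n = p_n / p_0 (r_0 = 1) with periodic rescaling
    r = np.zeros(nmax + 1)
    r[0] = 1.0
    offset = 0.0
    for n in range(1, nmax + 1):
        r[n] = (m / n) * float(np.dot(kq[1 : n + 1], r[n - 1 :: -1]))
        if r[n] > 1e280:
            r[: n + 1] /= 1e280
            offset += 280.0 * math.log(10.0)
    with np.errstate(divide="ignore"):
        return np.log(r) + offset - m * (1.0 - q[0])


def count_pmf(m: float, epsilon: float = 1.0, nmax: int = 100) -> np.ndarray:
    """Probability of observing ``n`` mutant colonies in one culture.

    Compound-Poisson recursion over the thinned clone-size law ``q``:

        p_0 = exp(-m (1 - q_0))
        p_n = (m/n) * sum_{k=1..n} k q_k p_{n-k}

    For ``epsilon = 1`` this is the classic Ma–Sandri–Sarkar recursion
    ``p_n = (m/n) sum_{i<n} p_i / (n - i + 1)``.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    return np.exp(_log_count_pmf(m, epsilon, nmax))


def _loglik(m: float, counts: np.ndarray, epsilon: float) -> float:
    if m < 0:
        return -np.inf
    if m == 0.0:
        return -np.inf if counts.max() > 0 else 0.0
    logp = _log_count_pmf(m, epsilon, int(counts.max()))
    return float(logp[counts].sum())


class FluctuationModel:
    """Mutation-rate model for one fluctuation dataset.

    Parameters
    ----------
    counts : array-like of int
        Observed mutant colonies per culture.
    epsilon : float
        Plating efficiency in ``(0, 1]``.
    design : FluctuationDesign, optional
        Needed to convert ``m`` to a per-division rate.
    """

    def __init__(self, counts, epsilon: float = 1.0, design: FluctuationDesign | None = None):
        counts = np.asarray(counts)
        if counts.size < 2:
            raise ValueError("need counts from at least 2 cultures")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(int)
        if not (0.0 < epsilon <= 1.0):
            raise ValueError(f"epsilon must be in (0, 1], got {epsilon}")
        self.counts = counts
        self.epsilon = epsilon
        self.design = design

    def loglike(self, m: float) -> float:
        """Log-likelihood of ``m`` given the observed counts."""
        return _loglik(m, self.counts, self.epsilon)

    def fit(self, level: float = 0.95) -> "FluctuationResults":
        """Maximum-likelihood ``m`` with a profile-likelihood interval."""
        counts = self.counts
        eps = self.epsilon
        q0 = clone_pmf(eps, 1)[0] if eps < 1.0 else 0.0

        if counts.max() == 0:
            # Likelihood exp(-C m (1-q0)): maximized at the m = 0 boundary.
            ll0 = self.loglike(0.0)
            crit = stats.chi2.ppf(level, 1)
            upper = crit / (2.0 * len(counts) * (1.0 - q0))
            return FluctuationResults(self, m=0.0, ci=(0.0, upper), loglik=ll0, level=level)

        # p0-method start when zero-count cultures exist, else the sample
        # mean (an overestimate for the heavy-tailed clone law, used only
        # to set the scan range).
        frac0 = float(np.mean(counts == 0))
        if frac0 > 0:
            m0 = -math.log(frac0) / (1.0 - q0)
        else:
            m0 = max(1.0, float(counts.mean()))

        # Coarse geometric scan brackets the optimum robustly (the
        # likelihood is astronomically small far above the MLE, where
        # log-space evaluation saturates), then bounded Brent refines.
        grid = np.geomspace(max(m0 / 1e4, 1e-6), m0 * 8.0, 60)
        lls = np.array([self.loglike(m) for m in grid])
        i = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda m: -self.loglike(m), bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-12},
        )
        if not res.success:  # pragma: no cover - bounded Brent does not fail
            raise RuntimeError(f"MLE did not converge: {res.message}")
        m_hat = float(res.x)
        ll_hat = -float(res.fun)
        ci = self._profile_interval(m_hat, ll_hat, level)
        return FluctuationResults(self, m=m_hat, ci=ci, loglik=ll_hat, level=level)

    def _profile_interval(self, m_hat: float, ll_hat: float, level: float) -> tuple[float, float]:
        crit = stats.chi2.ppf(level, 1)

        def g(m: float) -> float:
            return 2.0 * (ll_hat - self.loglike(m)) - crit

        # Lower endpoint: with any positive count the log-likelihood
        # diverges to -inf at m -> 0, so a sign change always exists.
        lo = m_hat / 2.0
        while g(lo) < 0 and lo > 1e-280:
            lo /= 4.0
        lower = optimize.brentq(g, lo, m_hat, xtol=1e-12, rtol=1e-10)

        hi = m_hat * 2.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover
                raise RuntimeError("flat likelihood: upper profile bound not found")
        upper = optimize.brentq(g, m_hat, hi, xtol=1e-12, rtol=1e-10)
        return (float(lower), float(upper))


@dataclass
class FluctuationResults:
    """MLE of the expected mutations per culture and derived rates."""

    model: FluctuationModel = field(repr=False)
    m: float
    ci: tuple[float, float]
    loglik: float
    level: float = 0.95

    def conf_int(self) -> tuple[float, float]:
        return self.ci

    def mutation_rate(self, design: FluctuationDesign | None = None,
                      divisor: str = "divisions") -> tuple[float, float]:
        """Per-division mutation rate and its per-1000-bp normalization.

        ``divisor="divisions"`` uses ``Nt - N0``; ``divisor="nt"`` divides by
        the final population size ``Nt`` (negligible difference when
        ``N0 << Nt``).
        """
        design = design or self.model.design
        if design is None:
            raise ValueError("a FluctuationDesign is required")
        denom = design.Nt - design.N0 if divisor == "divisions" else design.Nt
        mu = self.m / denom
        return mu, mu * 1000.0 / design.gene_length

    def summary(self) -> str:
        lines = [
            "Luria-Delbruck fluctuation fit",
            "-" * 38,
            f"cultures:            {len(self.model.counts)}",
            f"plating efficiency:  {self.model.epsilon:g}",
            f"m (mutations/culture): {self.m:.6g}",
            f"{int(self.level*100)}% profile CI:      [{self.ci[0]:.6g}, {self.ci[1]:.6g}]",
            f"log-likelihood:      {self.loglik:.6g}",
        ]
        if self.model.design is not None:
            mu, mu_kb = self.mutation_rate()
            lines.append(f"mu (per division):   {mu:.6g}")
            lines.append(f"mu per 1000 bp:      {mu_kb:.6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface


def mle_m(counts, epsilon: float = 1.0) -> FluctuationResults:
    """Maximum-likelihood fit of ``m`` (see :class:`FluctuationModel`)."""
    return FluctuationModel(counts, epsilon).fit()


def profile_ci(counts, epsilon: float = 1.0, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for ``m``."""
    return FluctuationModel(counts, epsilon).fit(level=level).ci


def mutation_rate(fit: FluctuationResults, design: FluctuationDesign,
                  divisor: str = "divisions") -> tuple[float, float]:
    """``(mu, mu_per_kb)`` from a fitted ``m`` and the culture design."""
    return fit.mutation_rate(design, divisor=divisor)


def rate_ratio(fit_a: FluctuationResults, fit_b: FluctuationResults,
               design_a: FluctuationDesign, design_b: FluctuationDesign) -> dict:
    """Fold ratio of per-kb mutation rates with an interval-arithmetic CI.

    Returns ``ratio = mu_per_kb(a) / mu_per_kb(b)``; if the denominator MLE
    is zero the ratio is the ``inf`` sentinel rather than an exception.
    """
    _, kb_a = fit_a.mutation_rate(design_a)
    _, kb_b = fit_b.mutation_rate(design_b)
    scale_a = 1000.0 / ((design_a.Nt - design_a.N0) * design_a.gene_length)
    scale_b = 1000.0 / ((design_b.Nt - design_b.N0) * design_b.gene_length)
    lo_a, hi_a = fit_a.ci[0] * scale_a, fit_a.ci[1] * scale_a
    lo_b, hi_b = fit_b.ci[0] * scale_b, fit_b.ci[1] * scale_b
    if kb_b == 0.0:
        return {"ratio": math.inf, "ci": (math.inf, math.inf) if kb_a > 0 else (0.0, math.inf)}
    ci = (lo_a / hi_b, hi_a / lo_b if lo_b > 0 else math.inf)
    return {"ratio": kb_a / kb_b, "ci": ci}
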