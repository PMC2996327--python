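"""Luria–Delbrück fluctuation analysis of chromosome loss rates.

A fluctuation assay grows many parallel cultures from single cells and counts,
in each culture, the cells that have lost the marked chromosome.  Because a
loss event early in the growth of a culture founds a large clone of loss-derived
cells, the per-culture counts follow the heavy-tailed ("jackpot") Luria–Delbrück
distribution rather than a Poisson law, and the per-division loss rate must be
estimated from the shape of that distribution.

Three classical estimators of ``m`` (the expected number of loss *events* per
culture) are provided:

``p0``
    the zero-class estimator, ``m = -ln(P0)`` where ``P0`` is the fraction of
    cultures with no loss-derived cells;
``lc_median``
    the Lea–Coulson median estimator, solving ``r_median/m - ln(m) = 1.24``;
``mss_mle``
    a maximum-likelihood fit over the full Luria–Delbrück pmf computed by the
    Ma–Sandri–Sarkar recursion.

The per-division loss rate is ``m / N`` with ``N`` the final cells per culture
(the number of divisions in a colony grown from one cell is taken as ``N``;
for ``N >= 1e3`` the ``N-1`` distinction is negligible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FluctuationAssay",
    "LossRateEstimate",
    "EstimatorUndefinedError",
    "ld_pmf",
    "ld_log_likelihood",
    "estimate_p0",
    "estimate_lc_median",
    "estimate_mss_mle",
    "estimate_auto",
    "rate_from_m",
    "bootstrap_ci",
    "simulate_assay",
]

#: Lea–Coulson median-equation constant.
LEA_COULSON_CONSTANT = 1.24


class EstimatorUndefinedError(ValueError):
    """Raised when an estimator's preconditions fail on the given counts."""


@dataclass(frozen=True)
class FluctuationAssay:
    """Per-culture loss counts from one strain/construct fluctuation test.

    Parameters
    ----------
    label
        Identifier, typically ``"<strain>|<construct>"``.
    culture_counts
        Loss-derived cells observed in each culture (``r_i >= 0``).
    culture_size
        Final cells per culture ``N`` (assumed equal across cultures).
    cells_sampled
        Cells actually scored per culture when only a sample of the final
        population is plated; estimates of ``m`` from thinned counts refer to
        the sampled population, and the per-division rate uses this value.
    """

    label: str
    culture_counts: tuple[int, ...]
    culture_size: int
    cells_sampled: Optional[int] = None

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.culture_counts)
        object.__setattr__(self, "culture_counts", counts)
        if len(counts) < 1:
            raise ValueError("assay needs at least one culture")
        if self.culture_size < 2:
            raise ValueError("culture_size must be >= 2")
        cap = self.cells_sampled if self.cells_sampled is not None else self.culture_size
        if self.cells_sampled is not None and not (0 < self.cells_sampled <= self.culture_size):
            raise ValueError("cells_sampled must be in (0, culture_size]")
        if any(c < 0 for c in counts):
            raise ValueError("culture counts must be non-negative")
        if any(c > cap for c in counts):
            raise ValueError("culture counts cannot exceed cells scored per culture")

    @property
    def n_cultures(self) -> int:
        return len(self.culture_counts)

    @property
    def counts(self) -> np.ndarray:
        return np.asarray(self.culture_counts, dtype=np.int64)

    def lower_median(self) -> int:
        """Median count, using the lower of the two middle values for even n."""
        c = np.sort(self.counts)
        return int(c[(len(c) - 1) // 2])


@dataclass(frozen=True)
class LossRateEstimate:
    """Estimated loss events per culture and the implied per-division rate."""

    m_hat: float
    rate_per_division: float
    method: str
    n_cultures: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: Optional[float] = None
    seed: Optional[int] = None

    @property
    def rate_e5(self) -> float:
        """Rate in the display units of the loss-rate tables (×10⁻⁵)."""
        return self.rate_per_division * 1e5


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria–Delbrück pmf ``p_0 .. p_r_max`` by the Ma–Sandri–Sarkar recursion.

    ``p_0 = exp(-m)`` and ``p_r = (m/r) * sum_{i<r} p_i / (r - i + 1)``.
    The returned probabilities sum to less than 1; the deficit is the mass
    beyond ``r_max``.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if r_max < 0:
        raise ValueError("r_max must be non-negative")
    p = np.zeros(r_max + 1)
    p[0] = np.exp(-m)
    if r_max == 0 or m == 0:
        if m == 0:
            p[0] = 1.0
        return p
    # weights w[k] = 1/(k+1) so that sum_{i<r} p_i/(r-i+1) = dot(p[:r], w[r-1::-1])
    w = 1.0 / np.arange(2, r_max + 2)
    for r in range(1, r_max + 1):
        p[r] = (m / r) * np.dot(p[:r], w[:r][::-1])
    return p


def ld_log_likelihood(m: float, counts: np.ndarray, r_cap: int = 1500) -> float:
    """Log-likelihood of per-culture counts under the Luria–Delbrück pmf.

    Counts above ``r_cap`` are treated as right-censored (they contribute
    ``log P(R >= r_cap)``), which bounds the cost of the O(r²) recursion
    without discarding jackpot cultures.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if m <= 0:
        return 0.0 if np.all(counts == 0) else -np.inf
    top = int(min(counts.max(), r_cap))
    p = ld_pmf(m, top)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    ll = 0.0
    censored = counts >= r_cap
    if censored.any():
        tail = max(1.0 - p[:r_cap].sum(), 1e-300)
        ll += censored.sum() * np.log(tail)
    obs = counts[~censored]
    ll += logp[obs].sum()
    return float(ll)


def _estimate(assay: FluctuationAssay, m_hat: float, method: str) -> LossRateEstimate:
    return LossRateEstimate(
        m_hat=float(m_hat),
        rate_per_division=rate_from_m(
            m_hat, assay.cells_sampled if assay.cells_sampled is not None else assay.culture_size
        ),
        method=method,
        n_cultures=assay.n_cultures,
    )


def estimate_p0(assay: FluctuationAssay) -> LossRateEstimate:
    """Zero-class estimator: ``m = -ln(fraction of cultures with no losses)``."""
    n_zero = int(np.sum(assay.counts == 0))
    if n_zero == 0:
        raise EstimatorUndefinedError(
            "no zero-count culture: the P0 estimator is undefined; "
            "use lc_median or mss_mle"
        )
    return _estimate(assay, -np.log(n_zero / assay.n_cultures), "p0")


def lc_median_root(median_count: float) -> float:
    """Solve ``r/m - ln(m) = 1.24`` for ``m > 0`` given a median count ``r > 0``.

    The left side is strictly decreasing in ``m``, so the root is unique;
    it is bracketed in log-space on [1e-6, 1e6].
    """
    if median_count <= 0:
        raise EstimatorUndefinedError("median count must be positive for the Lea–Coulson estimator")

    def g(log_m: float) -> float:
        m = np.exp(log_m)
        return median_count / m - log_m - LEA_COULSON_CONSTANT

    lo, hi = np.log(1e-6), np.log(1e6)
    return float(np.exp(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)))


def estimate_lc_median(assay: FluctuationAssay) -> LossRateEstimate:
    """Lea–Coulson median estimator of ``m``."""
    return _estimate(assay, lc_median_root(assay.lower_median()), "lc_median")


def estimate_mss_mle(assay: FluctuationAssay, r_cap: int = 1500) -> LossRateEstimate:
    """Maximum-likelihood estimate of ``m`` over the Luria–Delbrück pmf.

    The optimum is bracketed a decade either side of a cheap pilot estimate
    (Lea–Coulson median, or P0 when the median is zero).
    """
    counts = assay.counts
    if np.all(counts == 0):
        warnings.warn("all cultures have zero counts: MLE is at the m=0 boundary")
        return _estimate(assay, 0.0, "mss_mle")
    try:
        pilot = lc_median_root(assay.lower_median())
    except EstimatorUndefinedError:
        pilot = max(estimate_p0(assay).m_hat, 1e-6)
    lo, hi = np.log(pilot / 10.0), np.log(pilot * 10.0)
    res = minimize_scalar(
        lambda log_m: -ld_log_likelihood(np.exp(log_m), counts, r_cap=r_cap),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return _estimate(assay, float(np.exp(res.x)), "mss_mle")


_ESTIMATORS = {
    "p0": estimate_p0,
    "lc_median": estimate_lc_median,
    "mss_mle": estimate_mss_mle,
}


def estimate_auto(assay: FluctuationAssay) -> LossRateEstimate:
    """Lea–Coulson when the median count is positive, else P0 (0 if all zero)."""
    if assay.lower_median() > 0:
        return estimate_lc_median(assay)
    return estimate_p0(assay)


def rate_from_m(m_hat: float, culture_size: int) -> float:
    """Per-division loss rate ``m / N`` (divisions per culture taken as ``N``)."""
    if culture_size < 2:
        raise ValueError("culture_size must be >= 2")
    if m_hat < 0:
        raise ValueError("m_hat must be non-negative")
    return m_hat / culture_size


def bootstrap_ci(
    assay: FluctuationAssay,
    estimator: str = "lc_median",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``m``, resampling cultures with replacement.

    Resamples on which the estimator is undefined are dropped; if more than
    half are, an error is raised. Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    func = _ESTIMATORS[estimator]
    rng = np.random.default_rng(seed)
    counts = assay.counts
    n = len(counts)
    values = []
    for _ in range(n_boot):
        resample = counts[rng.integers(0, n, size=n)]
        boot = FluctuationAssay(
            assay.label, tuple(resample), assay.culture_size, assay.cells_sampled
        )
        try:
            values.append(func(boot).m_hat)
        except EstimatorUndefinedError:
            continue
    if len(values) < n_boot / 2:
        raise EstimatorUndefinedError(
            f"estimator {estimator!r} undefined on {n_boot - len(values)}/{n_boot} resamples"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def simulate_assay(
    rate: float,
    culture_size: int,
    n_cultures: int,
    seed: int,
    cells_sampled: Optional[int] = None,
    relative_fitness: float = 1.0,
    label: str = "simulated",
) -> FluctuationAssay:
    """Simulate a colony-isolation fluctuation assay at a known loss rate.

    Loss events per culture are Poisson with mean ``m = rate * culture_size``;
    each event founds a clone whose final size is ``floor(u**(-w))`` for
    ``u ~ U(0,1)`` (``P(size >= k) = k**(-1/w)``), the classical Luria–Delbrück
    clone-size law under deterministic exponential growth. ``w`` is the fitness
    of loss-derived cells relative to fragment-bearing cells (default 1: red
    cells grow at the same rate). Counts are capped at the culture size and,
    when ``cells_sampled`` is given, binomially thinned to the plated sample.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a probability in [0, 1]")
    if culture_size < 2:
        raise ValueError("culture_size must be >= 2")
    rng = np.random.default_rng(seed)
    m = rate * culture_size
    events = rng.poisson(m, size=n_cultures)
    total = int(events.sum())
    u = rng.random(total)
    with np.errstate(over="ignore"):
        sizes = np.floor(u ** (-relative_fitness))
    sizes = np.minimum(sizes, float(culture_size)).astype(np.int64)
    owner = np.repeat(np.arange(n_cultures), events)
    counts = np.bincount(owner, weights=sizes, minlength=n_cultures).astype(np.int64)
    counts = np.minimum(counts, culture_size)
    if cells_sampled is not None:
        counts = rng.binomial(counts, cells_sampled / culture_size)
    return FluctuationAssay(label, tuple(int(c) for c in counts), culture_size, cells_sampled)
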