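"""Closed-form detection-probability model for rare variant junctions.

Detecting a junction requires (i) at least two reads whose split-read
alignments seed the candidate — a read overlapping the breakpoint is
"twice-mapped" when both of its ends reach the minimum match length
6 + 0.2 L, which happens with probability 0.6 − 11/L — and (ii) at least
three total qualifying reads, where the additional reads only need to span
the breakpoint with E perfectly matching bases on each side (probability
1 − (2E − 1)/L per overlapping read, neglecting breakpoint ambiguity).
Twice-mapped reads are a subset of spanning reads on error-free data.

The number of reads overlapping the breakpoint follows the sample's
read-depth distribution: Poisson(C) for unbiased coverage or negative
binomial with mean C and size parameter r capturing library-preparation
bias (smaller r = more overdispersion; r → ∞ recovers Poisson). The overall
detection probability is the coverage-weighted sum

    P(detect) = Σ_k P_cov(k; C, r) · P(X ≥ 2 and X + Y ≥ 3 | k)

with X ~ Binomial(k, p_twice) and Y the count of spanning-only reads among
the remaining k − X.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import optimize, stats

__all__ = [
    "SensitivityParams",
    "CoverageModel",
    "detection_probability",
    "coverage_for_sensitivity",
    "frequency_threshold",
    "sensitivity_band",
    "fit_coverage_model",
    "sensitivity_grid",
]


@dataclass(frozen=True)
class SensitivityParams:
    """Inputs of the detection model.

    L: read length (bases); E: perfect-extension requirement (default 6);
    C: mean read-depth coverage of the variant genome; r: negative-binomial
    size parameter of the coverage distribution (inf = Poisson).
    """

    L: float
    C: float
    r: float = math.inf
    E: int = 6
    seed_min: int = 2
    n_min: int = 3

    def __post_init__(self):
        if self.C < 0:
            raise ValueError("coverage must be >= 0")
        if not (self.r > 0):
            raise ValueError("r must be positive or inf")
        if self.p_twice <= 0:
            raise ValueError(
                f"read length {self.L} too short: twice-mapped probability "
                f"0.6 - 11/L must be positive (needs L > 18.4)")
        if self.p_span <= 0 or self.p_span > 1:
            raise ValueError("read length too short for spanning reads")

    @property
    def p_twice(self) -> float:
        """Chance an overlapping read maps to both sides of the junction."""
        return 0.6 - 11.0 / self.L

    @property
    def p_span(self) -> float:
        """Chance an overlapping read qualifies as spanning (A neglected)."""
        return 1.0 - (2 * self.E - 1.0) / self.L


@dataclass(frozen=True)
class CoverageModel:
    """Fitted read-depth distribution: NB(mean, size r) or Poisson."""

    mean: float
    r: float  # inf = Poisson

    @property
    def is_poisson(self) -> bool:
        return math.isinf(self.r)

    def distribution(self):
        if self.is_poisson:
            return stats.poisson(self.mean)
        return stats.nbinom(self.r, self.r / (self.r + self.mean))


def _coverage_pmf(C: float, r: float,
                  tail: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    dist = stats.poisson(C) if math.isinf(r) \
        else stats.nbinom(r, r / (r + C))
    kmax = int(dist.ppf(1 - tail)) + 1
    k = np.arange(kmax + 1)
    return k, dist.pmf(k)


def detection_probability(params: SensitivityParams) -> float:
    """Probability that a junction present at variant coverage C is called."""
    if params.C == 0:
        return 0.0
    p_tw, p_sp = params.p_twice, params.p_span
    q = (p_sp - p_tw) / (1.0 - p_tw)  # spanning-only chance per non-twice read
    k, w = _coverage_pmf(params.C, params.r)
    # need X >= 2 twice-mapped and X + Y >= 3 total qualifying reads
    p_x_ge3 = stats.binom.sf(2, k, p_tw)
    p_x_eq2 = stats.binom.pmf(2, k, p_tw)
    p_y_ge1 = np.where(k >= 2, 1.0 - (1.0 - q) ** np.maximum(k - 2, 0), 0.0)
    return float(np.sum(w * (p_x_ge3 + p_x_eq2 * p_y_ge1)))


def coverage_for_sensitivity(target: float, L: float, r: float = math.inf,
                             E: int = 6, tol: float = 0.01) -> float:
    """Mean variant coverage at which the detection chance equals ``target``
    (bisection to within ``tol`` fold)."""
    if not 0 < target < 1:
        raise ValueError("target probability must be in (0, 1)")

    def f(C):
        return detection_probability(SensitivityParams(L=L, C=C, r=r, E=E)) \
            - target

    hi = 4.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("target sensitivity unreachable")
    return float(optimize.brentq(f, 1e-9, hi, xtol=tol / 2))


def frequency_threshold(sensitivity: float, total_coverage: float, L: float,
                        r: float = math.inf, E: int = 6) -> float:
    """Variant frequency above which a junction is detected with the given
    chance, for a sample sequenced to ``total_coverage``."""
    if total_coverage <= 0:
        raise ValueError("total coverage must be positive")
    return coverage_for_sensitivity(sensitivity, L, r, E) / total_coverage


def sensitivity_band(params: SensitivityParams,
                     n_junctions: int) -> tuple[float, float]:
    """95% exact binomial (Clopper–Pearson) band on the detected fraction of
    ``n_junctions`` independent junctions given the model probability."""
    if n_junctions < 1:
        raise ValueError("need at least one junction")
    p = detection_probability(params)
    x = int(round(p * n_junctions))
    n = n_junctions
    lower = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))
    return (lower, upper)


def fit_coverage_model(histogram: np.ndarray,
                       censor: tuple[float, float] = (0.025, 0.975),
                       poisson_r: float = 1e6) -> CoverageModel:
    """Censored maximum-likelihood negative-binomial fit to a read-depth
    histogram (``histogram[c]`` = number of positions with coverage c).

    Bins below/above the censor quantiles of the raw distribution are
    dropped to blunt outliers (deleted regions, collapsed repeats), and the
    NB likelihood is renormalized over the retained support. A fit with
    r above ``poisson_r`` is reported as Poisson.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.sum() <= 0 or (hist > 0).sum() < 2:
        raise ValueError("degenerate coverage histogram")
    values = np.arange(len(hist))
    cdf = np.cumsum(hist) / hist.sum()
    lo_q, hi_q = censor
    keep = (cdf >= lo_q) & (np.concatenate([[0.0], cdf[:-1]]) <= hi_q)
    v = values[keep & (hist >= 0)]
    w = hist[keep & (hist >= 0)]
    mean0 = float(np.sum(values * hist) / hist.sum())
    var0 = float(np.sum((values - mean0) ** 2 * hist) / hist.sum())
    r0 = mean0 ** 2 / max(var0 - mean0, 1e-3)

    def nll(theta):
        mu, r = np.exp(theta)
        dist = stats.nbinom(r, r / (r + mu))
        norm = dist.pmf(v).sum()
        if norm <= 0:
            return 1e12
        return -np.sum(w * (dist.logpmf(v) - np.log(norm)))

    res = optimize.minimize(nll, x0=np.log([max(mean0, 0.1),
                                            min(max(r0, 0.1), 1e5)]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-4,
                                     "maxiter": 2000})
    mu, r = np.exp(res.x)
    if r > poisson_r:
        return CoverageModel(mean=float(mu), r=math.inf)
    return CoverageModel(mean=float(mu), r=float(r))


def sensitivity_grid(Ls, Cs, rs, E: int = 6):
    """Detection probabilities over a (L, C, r) grid as tidy rows."""
    rows = []
    for L in Ls:
        for r in rs:
            for C in Cs:
                p = detection_probability(SensitivityParams(L=L, C=C, r=r,
                                                            E=E))
                rows.append({"L": L, "C": C, "r": r, "probability": p})
    return rows
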