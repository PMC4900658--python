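"""Sample-size planning for off-type detection and Bayesian purity limits.

With a contamination proportion ``p`` and ``n`` individuals sampled, the
probability of catching at least one off-type is ``P = 1 - (1 - p)^n``
(markers assumed fully informative).  Conversely, having observed ``k``
off-types among ``n``, the population off-type proportion is bounded by the
upper quantile of the Beta posterior ``Beta(k + a, n - k + b)``; the Jeffreys
prior ``a = b = 0.5`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import beta as _beta

__all__ = [
    "detection_probability",
    "required_sample_size",
    "bayes_upper_limit",
    "detection_table",
    "SamplingPlan",
    "PosteriorEstimate",
]


@dataclass(frozen=True)
class SamplingPlan:
    n: int
    p: float
    detection_probability: float


@dataclass(frozen=True)
class PosteriorEstimate:
    k: int
    n: int
    prior: Tuple[float, float]
    credibility: float
    upper_limit: float
    method: str = "quantile"


def detection_probability(n: int, p: float) -> float:
    """Probability of observing at least one off-type in ``n`` draws.

    ``1 - (1 - p)^n``, evaluated via ``expm1``/``log1p`` so tiny
    contamination rates do not lose precision.
    """
    if not isinstance(n, (int, np.integer)) or n < 0:
        raise ValueError(f"n must be a non-negative integer, got {n!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    if n == 0:
        return 0.0
    if p == 1.0:
        return 1.0
    return -math.expm1(n * math.log1p(-p))


def required_sample_size(p: float, target_probability: float) -> int:
    """Smallest ``n`` with ``1 - (1 - p)^n >= target_probability``."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1 (p = 0 undetectable)")
    if not 0.0 < target_probability < 1.0:
        raise ValueError("target probability must be strictly between 0 and 1")
    n = max(1, math.ceil(math.log1p(-target_probability) / math.log1p(-p)))
    # guard against float edge effects around the ceiling
    while detection_probability(n, p) < target_probability:
        n += 1
    while n > 1 and detection_probability(n - 1, p) >= target_probability:
        n -= 1
    return n


def bayes_upper_limit(
    k: int,
    n: int,
    credibility: float = 0.95,
    prior: Tuple[float, float] = (0.5, 0.5),
    method: str = "quantile",
) -> float:
    """Upper credible limit on the population off-type proportion.

    Parameters
    ----------
    k, n : int
        Off-types observed among ``n`` sampled individuals.
    credibility : float
        One-sided credibility level (default 0.95).
    prior : (a, b)
        Beta prior parameters; Jeffreys ``(0.5, 0.5)`` by default, pass
        ``(1, 1)`` for the uniform prior.
    method : {"quantile", "central"}
        ``"quantile"`` returns the ``credibility`` quantile of the posterior
        (a one-sided bound); ``"central"`` the upper end of the equal-tailed
        central interval, i.e. the ``(1 + credibility) / 2`` quantile.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior parameters must be positive")
    if not 0.0 < credibility < 1.0:
        raise ValueError("credibility must be in (0, 1)")
    if method == "quantile":
        q = credibility
    elif method == "central":
        q = (1.0 + credibility) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(_beta.ppf(q, k + a, n - k + b))


def detection_table(n_grid: Sequence[int], p_grid: Sequence[float]) -> np.ndarray:
    """Detection probabilities over a grid: rows = sample sizes, cols = p."""
    if len(n_grid) == 0 or len(p_grid) == 0:
        raise ValueError("grids must be non-empty")
    return np.array(
        [[detection_probability(int(n), float(p)) for p in p_grid] for n in n_grid]
    )
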