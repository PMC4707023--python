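"""Program-size dynamics and the statistical comparison of final sizes.

The average size of the individuals after ``g`` generations admits a
closed-form upper-bound recurrence (every random tree pessimistically taken
at its depth budget ``D``):

    S(t) = p_xo * (2 S(t-1) + 2 B + 5)
         + p_m  * (  S(t-1) + 2 B + 4)
         + p_r  *    S(t-1)

where ``B`` is the per-tree node budget.  Two conventions for ``B`` are
provided: ``"pow2"`` takes ``B = 2**D`` (the convention under which the
recurrence is usually printed for binary primitives) and ``"strict"`` takes
``B = 2**(D+1) - 1``, the true node count of a full binary tree of depth
``D``.  An explicit ``tree_node_budget`` overrides both (useful when random
trees carry a unit-interval wrapper node, making their hard cap ``2**(D+1)``).

For large ``t`` the sequence grows geometrically with ratio ``1 + p_xo``:
crossover is the operator responsible for exponential size growth.

Final best-model sizes of two systems are compared the way such run
distributions are normally treated: a Shapiro-Wilk normality check on each
sample (recorded as justification; size distributions across runs are
heavily skewed) followed by a two-sided Mann-Whitney U test at alpha = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GrowthModel",
    "SizeComparison",
    "average_size_bound",
    "first_unmanageable_generation",
    "compare_final_sizes",
]


@dataclass(frozen=True)
class GrowthModel:
    """Symbols of the size recurrence: operator rates, tree depth budget D,
    and the initial average size S0."""

    p_xo: float
    p_m: float
    p_r: float
    D: int
    S0: float = 1.0

    def __post_init__(self) -> None:
        total = self.p_xo + self.p_m + self.p_r
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if min(self.p_xo, self.p_m, self.p_r) < 0:
            raise ValueError("probabilities must be nonnegative")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.S0 < 1:
            raise ValueError("S0 must be >= 1")


def average_size_bound(
    model: GrowthModel,
    g: int,
    convention: str = "pow2",
    tree_node_budget: int | None = None,
) -> np.ndarray:
    """The bound sequence S(0..g) on average individual size.

    ``convention="pow2"`` budgets a depth-D random tree at 2**D nodes,
    reproducing the printed recurrence verbatim; ``"strict"`` uses the true
    full-binary-tree count 2**(D+1) - 1.  ``tree_node_budget`` overrides
    either convention with an explicit per-tree cap.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if tree_node_budget is not None:
        B = int(tree_node_budget)
    elif convention == "pow2":
        B = 2**model.D
    elif convention == "strict":
        B = 2 ** (model.D + 1) - 1
    else:
        raise ValueError("convention must be 'pow2' or 'strict'")
    out = np.empty(g + 1)
    out[0] = model.S0
    for t in range(1, g + 1):
        s = out[t - 1]
        out[t] = (
            model.p_xo * (2.0 * s + 2.0 * B + 5.0)
            + model.p_m * (s + 2.0 * B + 4.0)
            + model.p_r * s
        )
    return out


def first_unmanageable_generation(sizes, budget: int = 2**17) -> int | None:
    """Smallest generation index whose size summary exceeds ``budget``.

    Returns ``None`` when the whole sequence stays within budget.  The
    default budget is the depth-17 node count 2**17 that separates
    manageable from unmanageable models.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    for t, s in enumerate(sizes):
        if s > budget:
            return t
    return None


@dataclass(frozen=True)
class SizeComparison:
    """Outcome of the two-sample comparison of final best-model sizes."""

    n_a: int
    n_b: int
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    u_statistic: float
    p_value: float
    alpha: float
    verdict: str
    method: str

    def to_json(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "shapiro_p_a": self.shapiro_p_a,
            "shapiro_p_b": self.shapiro_p_b,
            "U": self.u_statistic,
            "p": self.p_value,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "method": self.method,
        }


def compare_final_sizes(sample_a, sample_b, alpha: float = 0.1) -> SizeComparison:
    """Shapiro-Wilk-gated Mann-Whitney comparison of two size samples.

    The normality check on each sample is recorded (it motivates the use of
    a rank test) but the verdict always comes from the two-sided
    Mann-Whitney U test: "different" iff p < alpha.  The exact U
    distribution is used for small samples (min(n, m) <= 8) without ties;
    the normal approximation with tie correction otherwise.
    """
    a = np.asarray([float(v) for v in sample_a])
    b = np.asarray([float(v) for v in sample_b])
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all observations are identical")

    shapiro_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else None
    shapiro_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else None

    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return SizeComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        shapiro_p_a=shapiro_a,
        shapiro_p_b=shapiro_b,
        u_statistic=float(res.statistic),
        p_value=p,
        alpha=float(alpha),
        verdict="different" if p < alpha else "not different",
        method=method,
    )
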