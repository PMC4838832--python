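"""Detection-proportion statistics, enrichment, and the a-priori power analysis.

The equal-proportion test is the R ``prop.test`` 2x2 chi-square with Yates'
continuity correction; enrichment is an exact hypergeometric upper tail; the
sample-size search uses exact noncentral-t power for the two-sided
two-sample t-test (the normal approximation misses the integer boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import DetectionMatrix, ValidationError


@dataclass
class ProportionComparison:
    k1: int
    n1: int
    k2: int
    n2: int
    chi2: float
    p_value: float
    degenerate: bool = False  # a table margin was zero; p defined as 1

    @property
    def p1_hat(self) -> float:
        return self.k1 / self.n1

    @property
    def p2_hat(self) -> float:
        return self.k2 / self.n2


@dataclass
class PowerSpec:
    """Two-sample t-test design: standardized effect d, alpha, target power,
    allocation ratio n2/n1."""

    effect_size: float = 1.0
    alpha: float = 0.05
    power: float = 0.95
    ratio: float = 1.14

    def validate(self) -> None:
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must be in (0, 1)")
        if self.ratio <= 0:
            raise ValidationError("ratio must be > 0")


def detection_proportions(
    det: DetectionMatrix, groups: dict[str, str], gene: str
) -> dict[str, tuple[int, int, float]]:
    """Per-group (detected k, total n, proportion) for one gene."""
    if gene not in det.data.index:
        raise KeyError(gene)
    unlabelled = [s for s in det.sample_ids if s not in groups]
    if unlabelled:
        raise ValidationError(f"samples without group label: {unlabelled[:5]}")
    row = det.data.loc[gene]
    out: dict[str, tuple[int, int, float]] = {}
    for label in sorted(set(groups.values())):
        members = [s for s in det.sample_ids if groups[s] == label]
        k = int(row[members].sum())
        out[label] = (k, len(members), k / len(members))
    return out


def prop_test_yates(k1: int, n1: int, k2: int, n2: int) -> ProportionComparison:
    """Two-sided test of equal proportions with Yates' continuity correction.

    chi2 = sum over the 2x2 table of max(0, |O - E| - 0.5)^2 / E, referred
    to chi-square with 1 df. A zero margin makes every expected count on one
    side zero; the comparison is then degenerate and p is defined as 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    if (cols == 0).any():
        return ProportionComparison(k1, n1, k2, n2, 0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / observed.sum()
    corrected = np.maximum(0.0, np.abs(observed - expected) - 0.5)
    chi2 = float((corrected**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return ProportionComparison(k1, n1, k2, n2, chi2, p)


def hypergeom_enrichment(k: int, set_size: int, draw_size: int, universe: int) -> float:
    """Upper-tail P(X >= k) for overlap k between a gene set of ``set_size``
    and a draw of ``draw_size`` from a universe of ``universe`` genes."""
    if not (0 <= k <= min(set_size, draw_size)):
        raise ValidationError("overlap k must satisfy 0 <= k <= min(K, n)")
    if set_size > universe or draw_size > universe:
        raise ValidationError("set and draw sizes cannot exceed the universe")
    return float(sps.hypergeom.sf(k - 1, universe, set_size, draw_size))


def power_two_sample_t(
    n1: int, n2: int, effect_size: float, alpha: float
) -> float:
    """Exact power of the two-sided two-sample t-test via the noncentral t."""
    df = n1 + n2 - 2
    ncp = effect_size / math.sqrt(1.0 / n1 + 1.0 / n2)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def min_sample_size(spec: PowerSpec, max_n1: int = 1_000_000) -> tuple[int, int]:
    """Smallest (n1, n2) with n2 = ceil(ratio * n1) reaching the target power.

    Returns (n1, n2) where n1 is the smaller group when ratio > 1. Uses the
    exact noncentral-t power at integer group sizes.
    """
    spec.validate()
    for n1 in range(2, max_n1 + 1):
        n2 = max(2, math.ceil(spec.ratio * n1))
        if power_two_sample_t(n1, n2, spec.effect_size, spec.alpha) >= spec.power:
            return n1, n2
    raise RuntimeError(f"target power not reachable with n1 <= {max_n1}")
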