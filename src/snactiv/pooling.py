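"""Synthetic pooling of nuclei against a bulk profile.

Nuclei are repeatedly sampled without replacement into pools of increasing
size; a gene is pool-detected if any member expresses it at TPM > 0, and the
overlap with the genes detected in bulk (TPM > 1) is tracked as the pool
grows. Up to 25 distinct subsets are used per size, reduced to C(n, s) when
fewer distinct subsets exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ExpressionMatrix, ValidationError, log2p1

DEFAULT_REPS = 25


@dataclass
class PoolingCurve:
    curve: pd.DataFrame          # pool_size, mean_overlap, sd_overlap, n_subsets
    final_overlap: float         # overlap at the full pool
    fisher_p: float              # two-sided Fisher p of the full-pool 2x2 table
    pearson_r: float             # pooled-mean vs bulk correlation, log2(TPM+1)
    pearson_p: float
    denominator: str             # 'bulk' or 'union'


def _subsets(n: int, size: int, reps: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Up to ``reps`` distinct index subsets of the given size.

    Full enumeration when the subset space is small; otherwise rejection
    sampling on canonical sorted tuples.
    """
    total = comb(n, size)
    if total <= reps or total <= 10 * reps:
        all_subsets = list(combinations(range(n), size))
        if total <= reps:
            return all_subsets
        pick = rng.choice(total, size=reps, replace=False)
        return [all_subsets[i] for i in pick]
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < reps:
        cand = tuple(sorted(rng.choice(n, size=size, replace=False)))
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table by the minimum-likelihood rule
    (sum of hypergeometric probabilities no larger than the observed table's)."""
    if min(a, b, c, d) < 0:
        raise ValidationError("table counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def pool_bulk_correlation(
    subset_tpm: pd.DataFrame, bulk: pd.Series
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between the subset-mean and bulk profiles
    on the log2(TPM+1) scale."""
    if len(subset_tpm) < 3:
        raise ValidationError("need >= 3 genes")
    pooled = np.log2(subset_tpm.mean(axis=1).to_numpy() + 1.0)
    b = np.log2(bulk.loc[subset_tpm.index].to_numpy() + 1.0)
    if np.std(pooled) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance in pooled or bulk profile")
    r, p = sps.pearsonr(pooled, b)
    return float(r), float(p)


def synthetic_pool_overlap(
    single: ExpressionMatrix,
    bulk: pd.Series,
    sizes: list[int] | None = None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    bulk_threshold: float = 1.0,
    denominator: str = "bulk",
) -> PoolingCurve:
    """Detection overlap between synthetic pools of nuclei and a bulk profile.

    For each pool size, up to ``reps`` distinct subsets of nuclei are drawn;
    a gene is pool-detected iff TPM > 0 in at least one member and
    bulk-detected iff bulk TPM > ``bulk_threshold``. Overlap is the
    intersection divided by the bulk-detected set (``denominator='bulk'``) or
    by the union of the two sets (``'union'``).
    """
    if denominator not in ("bulk", "union"):
        raise ValidationError("denominator must be 'bulk' or 'union'")
    bulk = bulk.loc[single.data.index]
    n = len(single.sample_ids)
    if sizes is None:
        sizes = list(range(1, n + 1))
    if max(sizes) > n:
        raise ValidationError("pool size exceeds number of nuclei")
    bulk_det = bulk.to_numpy() > bulk_threshold
    n_bulk = int(bulk_det.sum())
    if n_bulk == 0:
        raise ValidationError("no bulk-detected genes")
    detected = single.values > 0.0  # pool detection convention: TPM > 0

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        overlaps = []
        subsets = _subsets(n, size, reps, rng)
        for subset in subsets:
            pool_det = detected[:, list(subset)].any(axis=1)
            inter = int((pool_det & bulk_det).sum())
            denom = n_bulk if denominator == "bulk" else int((pool_det | bulk_det).sum())
            overlaps.append(inter / denom if denom else 0.0)
        overlaps = np.asarray(overlaps)
        rows.append(
            {
                "pool_size": size,
                "mean_overlap": float(overlaps.mean()),
                "sd_overlap": float(overlaps.std(ddof=1)) if len(overlaps) > 1 else 0.0,
                "n_subsets": len(subsets),
            }
        )
    curve = pd.DataFrame(rows)

    full_det = detected.any(axis=1)
    inter = int((full_det & bulk_det).sum())
    denom = n_bulk if denominator == "bulk" else int((full_det | bulk_det).sum())
    final_overlap = inter / denom
    # 2x2 detection table at the full pool: pool-detected vs bulk-detected
    a = inter
    b = int((full_det & ~bulk_det).sum())
    c = int((~full_det & bulk_det).sum())
    d = int((~full_det & ~bulk_det).sum())
    fisher_p = fisher_exact_2x2(a, b, c, d)
    r, p = pool_bulk_correlation(single.data, bulk)
    return PoolingCurve(curve, final_overlap, fisher_p, r, p, denominator)
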