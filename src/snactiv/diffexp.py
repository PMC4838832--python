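"""Two-group differential expression on expected counts.

The test is a negative-binomial conditional exact test: after median-of-ratios
normalization and library-size equalization, the group sums S_A and S_B are
modelled as NB with common dispersion; conditional on the total S = S_A + S_B
the law of S_A is free of the unknown mean, and the two-sided p-value sums
the conditional probabilities of all outcomes no more likely than the one
observed. At dispersion zero the NB degenerates to Poisson and the
conditional law is Binomial(S, n_A / (n_A + n_B)). Multiplicity is handled
by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, SampleMetadata, ValidationError

DISPERSION_PRIOR_WEIGHT = 10.0  # pseudo-samples pulling phi_g toward the common value
_TIE_REL_TOL = 1e-7             # outcomes with pmf <= pmf_obs*(1+tol) count as "as extreme"


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, renormalized to geometric mean 1.

    The reference is the per-gene geometric mean over genes nonzero in every
    sample; when no such gene exists the factors fall back to total-count
    scaling with a warning.
    """
    x = counts.values
    if (x.sum(axis=0) == 0).any():
        raise ValidationError("every sample needs at least one nonzero gene")
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        sub = x[all_nonzero]
        log_ref = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    else:
        warnings.warn(
            "no gene nonzero in all samples; falling back to total-count scaling",
            RuntimeWarning,
        )
        factors = x.sum(axis=0).astype(float)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids)


def estimate_dispersion(
    counts: CountMatrix,
    groups: dict[str, str],
    prior_weight: float = DISPERSION_PRIOR_WEIGHT,
) -> tuple[float, pd.Series]:
    """Method-of-moments NB dispersion, moderated toward the common value.

    Per gene, the within-group pooled variance s^2 and the grand mean m give
    phi_hat = max(0, (s^2 - m) / m^2) on normalized counts; the common
    dispersion is the median over genes with m > 1, and each gene is shrunk
    as (n * phi_hat + W * phi_common) / (n + W).
    """
    labels = np.array([groups[s] for s in counts.sample_ids])
    uniq = np.unique(labels)
    if any((labels == g).sum() < 2 for g in uniq):
        raise ValidationError("each group needs >= 2 samples")
    sf = size_factors(counts)
    y = counts.values / sf.to_numpy()[None, :]
    n = y.shape[1]

    ss, df_tot = np.zeros(y.shape[0]), 0
    for g in uniq:
        yg = y[:, labels == g]
        ss += (yg.shape[1] - 1) * yg.var(axis=1, ddof=1)
        df_tot += yg.shape[1] - 1
    pooled_var = ss / df_tot
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(mean > 0, (pooled_var - mean) / mean**2, 0.0)
    phi_hat = np.maximum(0.0, phi_hat)
    expressed = mean > 1.0
    phi_common = float(np.median(phi_hat[expressed])) if expressed.any() else 0.0
    phi_g = (n * phi_hat + prior_weight * phi_common) / (n + prior_weight)
    phi_g = np.where(mean > 0, phi_g, phi_common)
    return phi_common, pd.Series(phi_g, index=counts.gene_ids)


def _conditional_log_pmf(S: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(S_A = s | S) for s = 0..S under independent NB group sums with
    shapes r_a, r_b and a shared success probability (which cancels)."""
    s = np.arange(S + 1, dtype=float)
    logw = (
        gammaln(s + r_a)
        - gammaln(s + 1.0)
        + gammaln(S - s + r_b)
        - gammaln(S - s + 1.0)
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    y_a: np.ndarray | list, y_b: np.ndarray | list, phi: float
) -> float:
    """Two-sided conditional exact test on the group sums.

    ``y_a`` and ``y_b`` are counts already equalized to a common effective
    library size (integers after rounding). The p-value is the sum of
    conditional probabilities of all totals s with P(s|S) <= P(observed|S),
    the minimum-likelihood two-sided rule.
    """
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    n_a, n_b = len(y_a), len(y_b)
    s_a = int(round(y_a.sum()))
    S = s_a + int(round(y_b.sum()))
    if S == 0:
        return 1.0
    if phi == 0.0:
        # Poisson limit: S_A | S ~ Binomial(S, n_a/(n_a+n_b))
        p_binom = n_a / (n_a + n_b)
        s = np.arange(S + 1, dtype=float)
        logpmf = (
            gammaln(S + 1.0)
            - gammaln(s + 1.0)
            - gammaln(S - s + 1.0)
            + s * np.log(p_binom)
            + (S - s) * np.log1p(-p_binom)
        )
    else:
        logpmf = _conditional_log_pmf(S, n_a / phi, n_b / phi)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p = float(pmf[pmf <= pmf[s_a] * (1.0 + _TIE_REL_TOL)].sum())
    return min(1.0, p)


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    meta: list[SampleMetadata],
    group_field: str = "stain",
    fdr_threshold: float = 0.05,
    exclude: list[str] | None = None,
    prior_weight: float = DISPERSION_PRIOR_WEIGHT,
) -> pd.DataFrame:
    """Full pipeline: size factors -> dispersion -> per-gene exact test -> BH.

    ``exclude`` drops samples (e.g. pseudo-FOS+ nuclei) before testing.
    Returns a per-gene table sorted by adjusted p, with normalized group
    means, log2 fold change (group 1 over group 2, pseudocount 0.5),
    moderated dispersion, raw and BH-adjusted p, and a significance flag at
    ``fdr_threshold``.
    """
    exclude = set(exclude or ())
    keep = [s for s in counts.sample_ids if s not in exclude]
    sub = counts.subset_samples(keep)
    by_id = {m.sample_id: m for m in meta}
    groups = {s: getattr(by_id[s], group_field).value for s in keep}
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    g1, g2 = labels
    mask_a = np.array([groups[s] == g1 for s in keep])
    if mask_a.all() or not mask_a.any():
        raise ValidationError("one group is empty")

    sf = size_factors(sub)
    phi_common, phi_g = estimate_dispersion(sub, groups, prior_weight)
    # equalize to a common effective library size, round half-up
    norm = sub.values / sf.to_numpy()[None, :]
    eq = np.floor(norm + 0.5)

    y_a, y_b = eq[:, mask_a], eq[:, ~mask_a]
    pvals = np.array(
        [nb_exact_test(y_a[i], y_b[i], float(phi_g.iloc[i])) for i in range(eq.shape[0])]
    )
    qvals = bh_adjust(pvals)
    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, ~mask_a].mean(axis=1)
    log2_fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    out = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            f"mean_{g1}": mean_a,
            f"mean_{g2}": mean_b,
            "log2_fc": log2_fc,
            "dispersion": phi_g.to_numpy(),
            "p_value": pvals,
            "q_value": qvals,
            "direction": np.where(mean_a >= mean_b, g1, g2),
            "significant": qvals < fdr_threshold,
        }
    ).set_index("gene_id", drop=False)
    out.attrs["phi_common"] = phi_common
    out.attrs["groups"] = (g1, g2)
    return out.sort_values(["q_value", "p_value"])
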