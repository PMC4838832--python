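"""Sample-exclusion quality control for single-nucleus libraries.

Three criteria, all of which a sample must meet: (i) more than a minimum
number of uniquely mapped reads, (ii) spike-in TPM significantly positively
correlated with the known ERCC input concentrations, and (iii) detected-gene
count no more than two standard deviations below the batch mean. Thresholds
are computed once on the full input batch and frozen in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleMetadata, ValidationError, detection_matrix

DEFAULT_MIN_READS = 50_000
DEFAULT_ERCC_ALPHA = 0.05
DEFAULT_DETECTION_TPM = 1.0


class EmptyCohortError(RuntimeError):
    """No sample survived quality control."""


def qc_reads(meta: SampleMetadata, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """Pass iff uniquely mapped reads strictly exceed ``min_reads``."""
    if meta.mapped_reads < 0:
        raise ValidationError("mapped_reads must be >= 0")
    return meta.mapped_reads > min_reads


def qc_ercc_correlation(
    observed_tpm: np.ndarray | pd.Series,
    expected: np.ndarray | pd.Series,
    alpha: float = DEFAULT_ERCC_ALPHA,
) -> tuple[float, float, bool]:
    """Pearson correlation of log2(TPM+1) vs log2 expected concentration.

    One-sided test for positive association via the t transform with n-2
    degrees of freedom; anticorrelated spike-ins are a failure, not a pass.
    Fewer than 3 nonzero spikes, or zero variance in either log vector, is
    an automatic fail with (nan, nan).
    """
    obs = np.asarray(observed_tpm, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValidationError("observed and expected spike vectors must align")
    if (obs > 0).sum() < 3:
        return float("nan"), float("nan"), False
    x = np.log2(obs + 1.0)
    y = np.log2(exp)
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant vector: correlation undefined
        return float("nan"), float("nan"), False
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if abs(r) >= 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(stats.t.sf(t_stat, df=n - 2))  # one-sided, positive tail
    return r, p, bool(p < alpha and r > 0)


def qc_gene_count(gene_counts: np.ndarray | pd.Series) -> tuple[np.ndarray, float]:
    """Batch filter on detected-gene counts: pass iff count >= mean - 2*SD.

    SD is the sample (n-1) standard deviation of the batch; the non-strict
    boundary keeps a zero-variance batch intact. Returns (per-sample pass
    flags, threshold).
    """
    counts = np.asarray(gene_counts, dtype=float)
    if counts.size < 2:
        raise ValidationError("gene-count QC needs a batch of >= 2 samples")
    threshold = float(counts.mean() - 2.0 * counts.std(ddof=1))
    return counts >= threshold, threshold


def apply_qc(
    matrix: ExpressionMatrix,
    meta: list[SampleMetadata],
    ercc_observed: pd.DataFrame,
    ercc_expected: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    ercc_alpha: float = DEFAULT_ERCC_ALPHA,
    detection_tpm: float = DEFAULT_DETECTION_TPM,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Run all three criteria and return (filtered matrix, QC report).

    ``ercc_observed`` is a spike x sample TPM block aligned to
    ``ercc_expected`` (index = spike ids, column ``concentration``). The
    report has one row per input sample; the matrix keeps only samples
    passing all criteria, column order preserved. Sets ``qc_pass`` on the
    metadata in place.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing = [s for s in matrix.sample_ids if s not in meta_by_id]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing[:5]}")

    det = detection_matrix(matrix, detection_tpm)
    gene_counts = det.data.sum(axis=0)
    gene_pass, gene_threshold = qc_gene_count(gene_counts.to_numpy())

    expected = ercc_expected.loc[ercc_observed.index, "concentration"]
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        m = meta_by_id[sid]
        reads_ok = qc_reads(m, min_reads)
        r, p, ercc_ok = qc_ercc_correlation(
            ercc_observed[sid].to_numpy(), expected.to_numpy(), ercc_alpha
        )
        overall = bool(reads_ok and ercc_ok and gene_pass[i])
        m.qc_pass = overall
        rows.append(
            {
                "sample_id": sid,
                "mapped_reads": m.mapped_reads,
                "reads_pass": reads_ok,
                "ercc_r": r,
                "ercc_p": p,
                "ercc_pass": ercc_ok,
                "gene_count": int(gene_counts.iloc[i]),
                "gene_count_threshold": gene_threshold,
                "gene_pass": bool(gene_pass[i]),
                "overall_pass": overall,
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id", drop=False)
    keep = [s for s in matrix.sample_ids if report.loc[s, "overall_pass"]]
    if not keep:
        raise EmptyCohortError("no sample passed quality control")
    return matrix.subset_samples(keep), report
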