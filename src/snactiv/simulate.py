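"""Synthetic cohorts with the statistical structure of an activation snRNA-seq study.

The generator emulates a two-group immunostain design (FOS+ vs FOS- nuclei)
in which a latent activation pseudotime t in [0, 1] drives a program of
immediate-early-like genes log-linearly (fold change effect_size**t).
Counts are negative-binomial with logistic dropout on the log mean; TPM is
obtained by per-sample scaling to one million. A configurable fraction of
mid-activation nuclei are labelled FOS+ before their transcriptome responds,
reproducing the "pseudo-FOS+" phenomenon. ERCC spike-ins and TSO-prefixed
retrotransposon reads are generated by companion functions so that QC and
the TE scanner are testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Condition,
    CountMatrix,
    ExpressionMatrix,
    SampleMetadata,
    Stain,
    ValidationError,
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the scale of the emulated experiment: 36 FOS+ and 43
    FOS- nuclei, 8,000 genes of which 500 form the activation program with a
    4-fold change across the activation continuum, NB dispersion 0.3, and
    dropout calibrated so an average nucleus detects roughly 6,000 genes at
    TPM > 1.
    """

    n_fos_pos: int = 36
    n_fos_neg: int = 43
    n_genes: int = 8000
    n_program_genes: int = 500
    mean_log_expression: float = 2.5   # ln-scale mean of NB baseline means
    sd_log_expression: float = 1.8     # ln-scale SD
    dispersion: float = 0.3            # NB dispersion phi (var = m + phi m^2)
    dropout_midpoint: float = 0.5      # logistic dropout: p = sigmoid(mid - slope*ln m)
    dropout_slope: float = 1.0
    effect_size: float = 4.0           # program fold change at t = 1
    label_noise: float = 0.1           # fraction of FOS+ labels given to mid-t nuclei
    ercc_n: int = 92
    ercc_noise_sd: float = 0.3         # lognormal sd of spike-in measurement noise
    library_size_mean: float = 500_000.0  # mapped reads per nucleus
    library_size_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_fos_pos, self.n_fos_neg, self.n_genes, self.n_program_genes) < 1:
            raise ValidationError("all counts must be >= 1")
        if self.n_program_genes > self.n_genes:
            raise ValidationError("n_program_genes exceeds n_genes")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if not 0 <= self.label_noise <= 1:
            raise ValidationError("label_noise must be in [0, 1]")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if self.ercc_n < 1:
            raise ValidationError("ercc_n must be >= 1")


@dataclass
class GroundTruth:
    """Latent quantities the analysis is expected to recover."""

    pseudotime: pd.Series                 # per sample, in [0, 1]
    program_genes: list[str]
    fold_change: pd.Series                # per gene, multiplicative FC at t = 1
    true_label: pd.Series                 # stain the transcriptome supports
    assigned_label: pd.Series             # stain recorded in the metadata
    pseudo_positive: pd.Series            # assigned FOS_POS with FOS_NEG transcriptome


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, ExpressionMatrix, list[SampleMetadata], GroundTruth]:
    """Simulate a two-stain-group cohort driven by a latent activation continuum.

    Counts ~ NB(baseline * FC(t), dispersion) thinned by logistic dropout;
    TPM is counts rescaled per sample to 1e6. FOS_POS is assigned to the
    samples with the highest latent t; a label_noise fraction of mid-t
    FOS_NEG samples are then swapped in as pseudo-FOS+ (group sizes are
    preserved by swapping out the lowest-t true positives).
    Deterministic given cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fos_pos + cfg.n_fos_neg
    sample_ids = [f"nucleus_{i:03d}" for i in range(n)]
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]

    # latent activation pseudotime
    t = rng.uniform(0.0, 1.0, size=n)
    order = np.argsort(t)
    true_pos = np.zeros(n, dtype=bool)
    true_pos[order[-cfg.n_fos_pos:]] = True

    # labels: swap mid-t negatives in as FOS_POS (pseudo-positives) and the
    # lowest-t true positives out, keeping group sizes exact
    assigned_pos = true_pos.copy()
    n_noise = int(round(cfg.label_noise * cfg.n_fos_pos))
    if n_noise > 0:
        neg_idx = order[~true_pos[order]]
        mid_neg = neg_idx[len(neg_idx) // 2 :]           # upper half of negatives by t
        swap_in = mid_neg[-n_noise:] if len(mid_neg) >= n_noise else mid_neg
        pos_idx = order[true_pos[order]]
        swap_out = pos_idx[: len(swap_in)]
        assigned_pos[swap_in] = True
        assigned_pos[swap_out] = False

    # gene baselines and the activation program
    base = np.exp(rng.normal(cfg.mean_log_expression, cfg.sd_log_expression, cfg.n_genes))
    program_idx = rng.choice(cfg.n_genes, size=cfg.n_program_genes, replace=False)
    fc = np.ones(cfg.n_genes)
    fc[program_idx] = cfg.effect_size

    # per-sample mean matrix: baseline * FC^t * library factor
    lib = np.exp(rng.normal(0.0, cfg.library_size_cv, n))
    mean = base[:, None] * np.power(fc[:, None], t[None, :]) * lib[None, :]

    # NB via gamma-poisson, then logistic dropout on the log mean
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mean * cfg.dispersion)
    counts = rng.poisson(lam).astype(float)
    with np.errstate(divide="ignore"):
        log_mean = np.where(mean > 0, np.log(mean), -np.inf)
    p_drop = _sigmoid(cfg.dropout_midpoint - cfg.dropout_slope * log_mean)
    counts *= rng.random(counts.shape) >= p_drop

    col_sums = counts.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    tpm = counts / col_sums * 1e6

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=sample_ids)

    mapped = np.maximum(
        1, rng.normal(cfg.library_size_mean, cfg.library_size_cv * cfg.library_size_mean, n)
    ).astype(int)
    meta = [
        SampleMetadata(
            sample_id=sample_ids[i],
            condition=Condition.NE,
            stain=Stain.FOS_POS if assigned_pos[i] else Stain.FOS_NEG,
            mapped_reads=int(mapped[i]),
        )
        for i in range(n)
    ]

    idx = pd.Index(sample_ids, name="sample_id")
    truth = GroundTruth(
        pseudotime=pd.Series(t, index=idx),
        program_genes=[gene_ids[i] for i in sorted(program_idx)],
        fold_change=pd.Series(fc, index=pd.Index(gene_ids, name="gene_id")),
        true_label=pd.Series(
            np.where(true_pos, Stain.FOS_POS.value, Stain.FOS_NEG.value), index=idx
        ),
        assigned_label=pd.Series(
            np.where(assigned_pos, Stain.FOS_POS.value, Stain.FOS_NEG.value), index=idx
        ),
        pseudo_positive=pd.Series(assigned_pos & ~true_pos, index=idx),
    )
    return CountMatrix(counts_df), ExpressionMatrix(tpm_df), meta, truth


def generate_bulk(expr: ExpressionMatrix, rng: np.random.Generator | None = None,
                  noise_sd: float = 0.0) -> pd.Series:
    """Bulk profile formed from many nuclei: the mean TPM across all samples,
    rescaled to 1e6, optionally perturbed by lognormal measurement noise."""
    bulk = expr.data.mean(axis=1)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        bulk = bulk * np.exp(rng.normal(0.0, noise_sd, len(bulk)))
    total = bulk.sum()
    return bulk / total * 1e6 if total > 0 else bulk


def generate_ercc(
    cfg: SimulationConfig,
    n_samples: int | None = None,
    shuffle_fraction: float = 0.0,
    efficiency: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Spike-in concentrations plus per-sample observed TPM.

    Expected concentrations span five orders of magnitude; observed TPM is
    concentration x capture efficiency x lognormal noise. A
    ``shuffle_fraction`` of samples get their spike-in values permuted
    (engineered QC failures). Returns (expected table, observed block,
    shuffled sample ids).
    """
    if cfg.ercc_n < 2:
        raise ValidationError("ercc_n must be >= 2")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if n_samples is None:
        n_samples = cfg.n_fos_pos + cfg.n_fos_neg
    ercc_ids = [f"ERCC-{i:05d}" for i in range(cfg.ercc_n)]
    conc = np.logspace(-1, 4, cfg.ercc_n)
    expected = pd.DataFrame({"concentration": conc}, index=pd.Index(ercc_ids, name="ercc_id"))

    sample_ids = [f"nucleus_{i:03d}" for i in range(n_samples)]
    noise = np.exp(rng.normal(0.0, cfg.ercc_noise_sd, (cfg.ercc_n, n_samples)))
    observed = conc[:, None] * efficiency * noise

    n_shuffled = int(round(shuffle_fraction * n_samples))
    shuffled = list(rng.choice(n_samples, size=n_shuffled, replace=False))
    for j in shuffled:
        observed[:, j] = rng.permutation(observed[:, j])
    obs_df = pd.DataFrame(observed, index=ercc_ids, columns=sample_ids)
    return expected, obs_df, [sample_ids[j] for j in sorted(shuffled)]


# ---------------------------------------------------------------------------
# Retrotransposon read simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_consensus_library(
    n_elements: int = 5, length: int = 300, seed: int = 0
) -> dict[str, str]:
    """Random nucleotide consensus sequences named like repeat families."""
    rng = np.random.default_rng(seed)
    return {
        f"TE_{i:02d}": "".join(rng.choice(_BASES, size=length))
        for i in range(n_elements)
    }


def generate_te_reads(
    cfg: SimulationConfig,
    consensus_library: dict[str, str],
    tso: str,
    n_start_reads: dict[str, int] | None = None,
    n_internal_reads: int = 10,
    n_no_tso_reads: int = 10,
    read_length: int = 80,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Reads in three classes with a truth table of TSO-adjacent counts.

    (a) TSO followed immediately by the consensus start — the promoter-driven
    class the scanner must count; (b) TSO followed by an internal consensus
    window (adapter present but transcript not promoter-initiated); (c)
    consensus sequence with no TSO. Returns (list of (read_id, sequence),
    truth table with the class-(a) count per element).
    """
    for name, seq in consensus_library.items():
        if len(seq) < 50:
            raise ValidationError(f"consensus {name} shorter than 50 nt")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = sorted(consensus_library)
    if n_start_reads is None:
        n_start_reads = {name: int(rng.integers(3, 15)) for name in names}
    body_len = read_length - len(tso)
    if body_len < 30:
        raise ValidationError("read_length too short for the TSO")

    reads: list[tuple[str, str]] = []
    k = 0
    for name in names:
        seq = consensus_library[name]
        for _ in range(int(n_start_reads.get(name, 0))):
            reads.append((f"read_{k:05d}_a_{name}", tso + seq[:body_len]))
            k += 1
        for _ in range(n_internal_reads):
            off = int(rng.integers(30, max(31, len(seq) - body_len)))
            reads.append((f"read_{k:05d}_b_{name}", tso + seq[off : off + body_len]))
            k += 1
        for _ in range(n_no_tso_reads):
            filler = "".join(rng.choice(_BASES, size=len(tso)))
            reads.append((f"read_{k:05d}_c_{name}", filler + seq[:body_len]))
            k += 1
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    truth = pd.DataFrame(
        {"tso_adjacent_truth": [int(n_start_reads.get(name, 0)) for name in names]},
        index=pd.Index(names, name="element"),
    )
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(library: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(library):
            fh.write(f">{name}\n{library[name]}\n")
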