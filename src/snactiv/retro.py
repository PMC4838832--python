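"""Promoter-normalized retrotransposon expression from TSO-anchored reads.

A read supports promoter-driven expression of a retrotransposon when the
template-switch oligo (TSO) appears in the read and the bases immediately
following it match the start of the element's consensus sequence — evidence
that the cDNA was template-switched at the element's own 5' end rather than
within a host transcript. TSO-adjacent counts are normalized by all reads
aligned to the same consensus, giving the promoter-normalized count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .core import ValidationError

DEFAULT_PREFIX_LEN = 20
DEFAULT_MAX_MISMATCH = 2
DEFAULT_START_WINDOW = 5


def load_consensus_library(path: str | Path) -> dict[str, str]:
    """RepeatMasker-style consensus FASTA into {element name: sequence}."""
    lib: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lib:
            raise ValidationError(f"duplicate consensus name {record.id!r}")
        seq = str(record.seq).upper()
        if len(seq) < 50:
            raise ValidationError(f"consensus {record.id!r} shorter than 50 nt")
        lib[record.id] = seq
    if not lib:
        raise ValidationError(f"no sequences in {path}")
    return lib


def iter_fastq(path: str | Path):
    """Yield (read id, sequence) from a FASTQ file (gzip accepted)."""
    path = str(path)
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "rt") as fh:
            yield from ((r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fastq"))
    else:
        yield from ((r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fastq"))


@dataclass
class ScanResult:
    counts: pd.Series            # per element: TSO-adjacent read count
    assignments: pd.DataFrame    # read_id, element, mismatches, tie
    n_skipped_short: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_tso_adjacent(
    reads,
    library: dict[str, str],
    tso: str,
    prefix_len: int = DEFAULT_PREFIX_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    start_window: int = DEFAULT_START_WINDOW,
) -> ScanResult:
    """Count reads whose TSO is directly adjacent to a consensus start.

    A read is TSO-adjacent to element E iff it contains the TSO exactly
    (forward orientation) and the ``prefix_len`` bases following the TSO
    match a window of E's consensus starting within its first
    ``start_window`` bases with at most ``max_mismatch`` mismatches. A read
    matching several elements goes to the fewest-mismatch one; ties resolve
    alphabetically and are flagged.
    """
    if not library:
        raise ValidationError("empty consensus library")
    if len(tso) < 10:
        raise ValidationError("TSO must be >= 10 nt")
    tso = tso.upper()
    names = sorted(library)
    # candidate consensus windows: (element, start offset) -> prefix string
    windows = [
        (name, off, library[name][off : off + prefix_len])
        for name in names
        for off in range(start_window)
        if len(library[name]) >= off + prefix_len
    ]
    counts = {name: 0 for name in names}
    rows = []
    skipped = 0
    min_len = len(tso) + prefix_len
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < min_len:
            skipped += 1
            continue
        pos = seq.find(tso)
        if pos < 0 or len(seq) - (pos + len(tso)) < prefix_len:
            continue
        prefix = seq[pos + len(tso) : pos + len(tso) + prefix_len]
        best: dict[str, int] = {}
        for name, _off, window in windows:
            mm = _hamming(prefix, window)
            if mm <= max_mismatch and mm < best.get(name, max_mismatch + 1):
                best[name] = mm
        if not best:
            continue
        min_mm = min(best.values())
        hits = sorted(name for name, mm in best.items() if mm == min_mm)
        counts[hits[0]] += 1
        rows.append(
            {
                "read_id": read_id,
                "element": hits[0],
                "mismatches": min_mm,
                "tie": len(hits) > 1,
            }
        )
    return ScanResult(
        counts=pd.Series(counts, name="tso_adjacent_count"),
        assignments=pd.DataFrame(rows, columns=["read_id", "element", "mismatches", "tie"]),
        n_skipped_short=skipped,
    )


def promoter_normalized_counts(
    tso_counts: pd.Series, total_counts: pd.Series
) -> pd.DataFrame:
    """TERecord table: TSO-adjacent / total aligned reads per consensus.

    Elements with zero total coverage get ratio 0 and a zero-coverage flag;
    a TSO-adjacent count exceeding the total signals inconsistent inputs.
    """
    elements = tso_counts.index.union(total_counts.index)
    tso = tso_counts.reindex(elements, fill_value=0).astype(int)
    total = total_counts.reindex(elements, fill_value=0).astype(int)
    bad = tso > total
    if bad.any():
        raise ValidationError(
            f"tso_adjacent > total for {list(elements[bad])[:5]}"
        )
    with pd.option_context("mode.chained_assignment", None):
        ratio = (tso / total.replace(0, 1)).where(total > 0, 0.0)
    return pd.DataFrame(
        {
            "element": elements,
            "tso_adjacent_count": tso.to_numpy(),
            "total_count": total.to_numpy(),
            "promoter_normalized": ratio.to_numpy(),
            "zero_coverage": (total == 0).to_numpy(),
        }
    ).set_index("element", drop=False)
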