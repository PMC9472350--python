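"""Copy-number variation reporting and match distributions.

The copy-number variation percentage of gain (CNVPG) compares the pattern
count of a subject genome (SPC) with that of a reference genome (RPC):

    CNVPG = (SPC - RPC) / RPC * 100

Positive values are gains, negative values losses.  Per-chromosome counts
and positional histograms summarize where the detected elements sit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pattern_chaining import PatternMatch

__all__ = [
    "CnvReport",
    "cnvpg",
    "counts_per_chromosome",
    "positional_distribution",
    "write_cnv_tsv",
    "plot_per_chromosome",
]


def cnvpg(spc: int | float, rpc: int | float) -> float:
    """CNV percentage of gain.  Exact internally; round to 5 decimals for
    presentation."""
    if rpc <= 0:
        raise ValueError("reference pattern count must be positive")
    if spc < 0:
        raise ValueError("subject pattern count must be non-negative")
    return (spc - rpc) / rpc * 100.0


@dataclass(frozen=True)
class CnvReport:
    sample: str
    spc: int
    rpc: int

    @property
    def cnvpg(self) -> float:
        return cnvpg(self.spc, self.rpc)


def counts_per_chromosome(
    matches: Sequence[PatternMatch], seqids: Iterable[str] | None = None
) -> dict[str, int]:
    """Match tally per chromosome.  ``seqids`` adds zero rows for
    chromosomes without matches (e.g. all genome records)."""
    counts: dict[str, int] = {s: 0 for s in seqids} if seqids is not None else {}
    for m in matches:
        counts[m.chrom] = counts.get(m.chrom, 0) + 1
    return counts


def positional_distribution(
    matches: Sequence[PatternMatch],
    seqid: str,
    bin_size: int,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Counts of match starts per half-open bin [i*bin, (i+1)*bin) along one
    chromosome.  The bin total equals the chromosome's match count."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    starts = [m.element_start for m in matches if m.chrom == seqid]
    extent = chrom_length if chrom_length is not None else (max(starts) + 1 if starts else 0)
    n_bins = max(1, -(-extent // bin_size)) if extent else 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for s in starts:
        counts[s // bin_size] += 1
    return counts


def write_cnv_tsv(
    samples: Sequence[tuple[str, int]], rpc: int, path: str | Path
) -> None:
    """CNV report TSV (sample, pattern_count, cnvpg rounded to 5 decimals)."""
    with open(path, "w") as fh:
        fh.write("sample\tpattern_count\tcnvpg\n")
        for name, spc in samples:
            fh.write(f"{name}\t{spc}\t{round(cnvpg(spc, rpc), 5)}\n")


def plot_per_chromosome(counts: dict[str, int], path: str | Path) -> None:
    """Bar chart of per-chromosome counts (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(counts) * 0.5), 3))
    ax.bar(list(counts), list(counts.values()))
    ax.set_xlabel("chromosome")
    ax.set_ylabel("detected elements")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
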