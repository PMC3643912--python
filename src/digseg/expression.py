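"""Expression quantification: RPKM, detection flags, per-library summaries.

RPKM (reads per kilobase of gene model per million mapped reads) for gene g
in library s is

    RPKM = 1e9 * C / (N * L)

with C the mapped read count of the gene, L its exonic length in nucleotides
and N the library's total mapped reads. A gene counts as *expressed*
(detected) in a library when it has at least ``min_count`` mapped reads
(default 1, i.e. RPKM > 0); the RPKM >= 1 / >= 5 tallies are separate,
stricter summaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

RPKM_SCALE = 1e9


def _align_genes(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    if "length" not in genes.columns:
        raise ValidationError("gene table must have a 'length' column")
    missing = counts.index.difference(genes.index)
    if len(missing):
        raise ValidationError(
            f"no gene length for: {', '.join(map(str, missing[:5]))}"
            + ("..." if len(missing) > 5 else "")
        )
    lengths = genes.loc[counts.index, "length"]
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValidationError(f"gene {bad!r} has non-positive length")
    return lengths.astype(float)


def _align_libraries(counts: pd.DataFrame, libraries: pd.DataFrame) -> pd.Series:
    if "total_mapped_reads" not in libraries.columns:
        raise ValidationError("library table must have a 'total_mapped_reads' column")
    missing = counts.columns.difference(libraries.index)
    if len(missing):
        raise ValidationError(
            f"no library metadata for: {', '.join(map(str, missing[:5]))}"
        )
    sizes = libraries.loc[counts.columns, "total_mapped_reads"]
    if (sizes < 1).any():
        bad = sizes.index[sizes < 1][0]
        raise ValidationError(f"library {bad!r} has non-positive total_mapped_reads")
    return sizes.astype(float)


def compute_rpkm(
    counts: pd.DataFrame, genes: pd.DataFrame, libraries: pd.DataFrame
) -> pd.DataFrame:
    """RPKM matrix: entry(g, s) = 1e9 * C(g, s) / (N_s * L_g).

    ``genes`` must carry a length for every row of ``counts`` and
    ``libraries`` a total_mapped_reads for every column; missing entries
    raise a :class:`ValidationError` naming the offender.
    """
    lengths = _align_genes(counts, genes)
    sizes = _align_libraries(counts, libraries)
    rpkm = counts.astype(float).div(lengths, axis=0).div(sizes, axis=1) * RPKM_SCALE
    return rpkm


def detection_flags(counts: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    """Boolean genes x libraries table: count >= min_count."""
    if min_count < 0:
        raise ValidationError(f"min_count must be non-negative, got {min_count}")
    return counts >= min_count


def library_summary(
    rpkm: pd.DataFrame,
    counts: pd.DataFrame,
    thresholds: Sequence[float] = (1.0, 5.0),
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-library detection tallies.

    One row per library: number of genes detected (count >= ``min_count``)
    and number of genes at or above each RPKM cutoff. Tallies are monotone
    non-increasing across increasing cutoffs.
    """
    if not len(thresholds):
        raise ValidationError("thresholds must be non-empty")
    out = pd.DataFrame(index=counts.columns.copy())
    out.index.name = "library_id"
    out["genes_detected"] = (counts >= min_count).sum(axis=0)
    for t in sorted(thresholds):
        out[f"genes_rpkm_ge_{t:g}"] = (rpkm >= t).sum(axis=0)
    return out
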