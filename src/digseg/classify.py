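"""Five-type per-stage gene classification and cross-stage gene sets.

At each stage every gene falls into exactly one of seven labels. Genes
detected in both genotypes are differentially expressed (DIG) when they pass
both FDR <= 0.01 and |log2(XX_RPKM/XY_RPKM)| >= 1 — XX-DIG when the ratio is
positive, XY-DIG when negative — and co-expressed (COG) otherwise. Genes
detected in exactly one genotype have an infinite log2 ratio, so the
fold-change clause holds automatically and specific expression (XX-SEG /
XY-SEG) reduces to the FDR test; candidates failing it are ND-SEG. Genes
detected in neither library are NOT-EXPRESSED.

Cross-stage sets:

* sex-specific genes — detected in at least one library of one genotype and
  in none of the other's, over all stages;
* all-stage co-expressed genes — labelled COG at every stage;
* enhanced genes — DIG or SEG for the same sex at the anchor stage (5 days
  after hatching) and at a minimum number of the remaining stages (default
  two). A gene not expressed at some stage simply fails that stage's
  criterion; it can still qualify through the other stages.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

LABEL_NOT_EXPRESSED = "NOT-EXPRESSED"
LABEL_ND_SEG = "ND-SEG"


def stage_labels(
    group1: str = "XX", group2: str = "XY"
) -> tuple[str, str, str, str, str]:
    """(COG, g1-DIG, g2-DIG, g1-SEG, g2-SEG) label strings for a group pair."""
    return (
        "COG",
        f"{group1}-DIG",
        f"{group2}-DIG",
        f"{group1}-SEG",
        f"{group2}-SEG",
    )


def classify_stage(
    tests: pd.DataFrame,
    flags1: pd.Series,
    flags2: pd.Series,
    groups: tuple[str, str] = ("XX", "XY"),
    fdr_threshold: float = 1e-2,
    log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Assign the per-stage label to every gene in the universe.

    ``tests`` is the stage's pairwise test table (genes detected in >= 1 of
    the two libraries); ``flags1``/``flags2`` are the detection flags of the
    two libraries over the *full* gene universe. Genes absent from ``tests``
    must be undetected in both libraries.
    """
    if fdr_threshold <= 0 or log2_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    if not flags1.index.equals(flags2.index):
        raise ValidationError("detection-flag gene universes differ")
    universe = flags1.index
    extra = tests.index.difference(universe)
    if len(extra):
        raise ValidationError(
            f"tested genes missing from the flag universe: {list(extra[:5])}"
        )

    cog, dig1, dig2, seg1, seg2 = stage_labels(*groups)
    g1, g2 = (g.lower() for g in groups)

    out = pd.DataFrame(index=universe.copy())
    out.index.name = "gene_id"
    for col in (f"rpkm_{g1}", f"rpkm_{g2}", "log2_ratio", "p_value", "q_value"):
        out[col] = tests[col].reindex(universe) if col in tests else np.nan
    out[f"detected_{g1}"] = flags1.astype(bool)
    out[f"detected_{g2}"] = flags2.astype(bool)

    d1 = out[f"detected_{g1}"].to_numpy()
    d2 = out[f"detected_{g2}"].to_numpy()
    if ((d1 | d2) & ~universe.isin(tests.index)).any():
        raise ValidationError("a detected gene is missing from the test table")

    q = out["q_value"].to_numpy()
    lr = out["log2_ratio"].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = q <= fdr_threshold
        big = np.abs(lr) >= log2_threshold

    label = np.full(len(universe), LABEL_NOT_EXPRESSED, dtype=object)
    both = d1 & d2
    label[both] = cog
    label[both & sig & big & (lr > 0)] = dig1
    label[both & sig & big & (lr < 0)] = dig2
    only1 = d1 & ~d2
    only2 = d2 & ~d1
    label[only1] = np.where(sig[only1], seg1, LABEL_ND_SEG)
    label[only2] = np.where(sig[only2], seg2, LABEL_ND_SEG)
    out.insert(0, "label", label)
    return out


def label_matrix(calls_by_stage: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x stages table of per-stage labels."""
    if not calls_by_stage:
        raise ValidationError("no stage calls supplied")
    cols = {str(stage): calls["label"] for stage, calls in calls_by_stage.items()}
    wide = pd.DataFrame(cols)
    if wide.isna().any().any():
        raise ValidationError("stage calls cover different gene universes")
    wide.index.name = "gene_id"
    return wide


def five_type_counts(calls_by_stage: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-stage tally of every label (one row per stage)."""
    rows = {}
    for stage, calls in calls_by_stage.items():
        rows[str(stage)] = calls["label"].value_counts()
    out = pd.DataFrame(rows).T.fillna(0).astype(int)
    out.index.name = "stage"
    return out


def _group_columns(libraries: pd.DataFrame, group: str) -> list:
    cols = libraries.index[libraries["group"] == group]
    if not len(cols):
        raise ValidationError(f"no libraries for group {group!r}")
    return list(cols)


def sex_specific_genes(
    flags: pd.DataFrame,
    libraries: pd.DataFrame,
    groups: tuple[str, str] = ("XX", "XY"),
) -> tuple[set, set]:
    """Genes detected only in one genotype's libraries, across all stages."""
    in1 = flags[_group_columns(libraries, groups[0])].any(axis=1)
    in2 = flags[_group_columns(libraries, groups[1])].any(axis=1)
    spec1 = set(flags.index[in1 & ~in2])
    spec2 = set(flags.index[in2 & ~in1])
    return spec1, spec2


def venn_partitions(
    flags: pd.DataFrame,
    libraries: pd.DataFrame,
    groups: tuple[str, str] = ("XX", "XY"),
) -> dict[str, int]:
    """Partition of the gene universe by any-stage detection in each group."""
    in1 = flags[_group_columns(libraries, groups[0])].any(axis=1)
    in2 = flags[_group_columns(libraries, groups[1])].any(axis=1)
    return {
        "both": int((in1 & in2).sum()),
        f"{groups[0]}_only": int((in1 & ~in2).sum()),
        f"{groups[1]}_only": int((in2 & ~in1).sum()),
        "neither": int((~in1 & ~in2).sum()),
    }


def cog_all_stages(calls_by_stage: Mapping[str, pd.DataFrame]) -> set:
    """Genes labelled COG at every stage."""
    wide = label_matrix(calls_by_stage)
    return set(wide.index[(wide == "COG").all(axis=1)])


def enhanced_genes(
    calls_by_stage: Mapping[str, pd.DataFrame],
    anchor_stage: str = "5",
    min_other_stages: int = 2,
    groups: tuple[str, str] = ("XX", "XY"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sex-enhanced genes with their supporting stages.

    A gene is enhanced toward group 1 when its label is group-1 DIG or SEG at
    the anchor stage and at >= ``min_other_stages`` of the remaining stages
    (symmetrically for group 2). Returns one table per group: gene_id index,
    ``stages`` column holding the comma-joined supporting stages and
    ``n_stages`` their number. The two sets are disjoint by construction
    (a gene has one label at the anchor stage).
    """
    wide = label_matrix(calls_by_stage)
    anchor = str(anchor_stage)
    if anchor not in wide.columns:
        raise ValidationError(
            f"anchor stage {anchor!r} not among stages {list(wide.columns)}"
        )
    others = [c for c in wide.columns if c != anchor]
    if len(others) < min_other_stages:
        raise ValidationError(
            f"need >= {min_other_stages} non-anchor stages, have {len(others)}"
        )
    results = []
    for g in groups:
        qualifying = {f"{g}-DIG", f"{g}-SEG"}
        hit = wide.isin(qualifying)
        selected = hit[anchor] & (hit[others].sum(axis=1) >= min_other_stages)
        sel_hits = hit.loc[selected]
        stages_list = sel_hits.apply(
            lambda row: [s for s in wide.columns if row[s]], axis=1
        )
        df = pd.DataFrame(index=wide.index[selected])
        df.index.name = "gene_id"
        df["stages"] = [",".join(s) for s in stages_list] if len(df) else []
        df["n_stages"] = [len(s) for s in stages_list] if len(df) else []
        results.append(df)
    xx_enh, xy_enh = results
    overlap = xx_enh.index.intersection(xy_enh.index)
    assert len(overlap) == 0, "a gene cannot be enhanced toward both sexes"
    return xx_enh, xy_enh
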