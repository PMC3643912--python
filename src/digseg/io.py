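"""File formats, run configuration and the end-to-end pipeline.

All tables are UTF-8 tab-separated with a header row. Undefined values are
written as ``NA``, infinite log2 ratios as ``Inf``/``-Inf``. Floats carry 6
significant digits except p- and q-values, written with 3 significant digits
in scientific notation. GFF3 coordinates are 1-based end-inclusive (the
format's convention); a gene's length is the total length of the union of
its exon intervals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import detest as _detest
from . import expression as _expression
from .errors import ValidationError

# ---------------------------------------------------------------------------
# TSV dialect


def format_float(v: float) -> str:
    if pd.isna(v):
        return "NA"
    if v == np.inf:
        return "Inf"
    if v == -np.inf:
        return "-Inf"
    return f"{v:.6g}"


def format_pq(v: float) -> str:
    if pd.isna(v):
        return "NA"
    return f"{v:.2e}"


def parse_float(tok: str) -> float:
    if tok == "NA":
        return np.nan
    if tok == "Inf":
        return np.inf
    if tok == "-Inf":
        return -np.inf
    return float(tok)


def write_table(df: pd.DataFrame, path, pq_columns: Sequence[str] = ()) -> Path:
    """Write a table in the package dialect, index included."""
    out = df.copy()
    for col in out.columns:
        if col in pq_columns:
            out[col] = out[col].map(format_pq)
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(format_float)
    path = Path(path)
    out.to_csv(path, sep="\t")
    return path


def write_float_matrix(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(format_float)
    path = Path(path)
    out.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# Readers


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: gene_id column plus one integer column per library."""
    raw = _read_tsv(path)
    _require_columns(raw, ["gene_id"], path)
    if raw["gene_id"].duplicated().any():
        dup = raw["gene_id"][raw["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: no library columns")
    counts = raw.set_index("gene_id")
    for col in counts.columns:
        try:
            vals = pd.to_numeric(counts[col])
        except (ValueError, TypeError):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric count in column {col!r}, "
                f"gene {bad.index[0]!r}: {bad.iloc[0]!r}"
            ) from None
        if (vals < 0).any():
            g = vals.index[vals < 0][0]
            raise ValidationError(
                f"{path}: negative count in column {col!r}, gene {g!r}"
            )
        if (vals != vals.astype(np.int64)).any():
            g = vals.index[vals != vals.astype(np.int64)][0]
            raise ValidationError(
                f"{path}: non-integer count in column {col!r}, gene {g!r}"
            )
        counts[col] = vals.astype(np.int64)
    return counts


def read_gene_lengths(path) -> pd.DataFrame:
    """Gene-length TSV: columns gene_id, length (nucleotides)."""
    raw = _read_tsv(path)
    _require_columns(raw, ["gene_id", "length"], path)
    if raw["gene_id"].duplicated().any():
        dup = raw["gene_id"][raw["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    genes = raw.set_index("gene_id")
    try:
        genes["length"] = pd.to_numeric(genes["length"]).astype(np.int64)
    except (ValueError, TypeError):
        raise ValidationError(f"{path}: non-integer length value") from None
    if (genes["length"] < 1).any():
        g = genes.index[genes["length"] < 1][0]
        raise ValidationError(f"{path}: non-positive length for gene {g!r}")
    return genes[["length"]]


def read_library_metadata(path) -> pd.DataFrame:
    """Library metadata TSV: library_id, group, stage, total_mapped_reads."""
    raw = _read_tsv(path)
    _require_columns(
        raw, ["library_id", "group", "stage", "total_mapped_reads"], path
    )
    if raw["library_id"].duplicated().any():
        dup = raw["library_id"][raw["library_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate library_id {dup!r}")
    libs = raw.set_index("library_id")
    libs["stage"] = libs["stage"].astype(str)
    try:
        libs["total_mapped_reads"] = pd.to_numeric(
            libs["total_mapped_reads"]
        ).astype(np.int64)
    except (ValueError, TypeError):
        raise ValidationError(f"{path}: non-integer total_mapped_reads") from None
    if (libs["total_mapped_reads"] < 1).any():
        lib = libs.index[libs["total_mapped_reads"] < 1][0]
        raise ValidationError(
            f"{path}: non-positive total_mapped_reads for {lib!r}"
        )
    return libs[["group", "stage", "total_mapped_reads"]]


def check_counts_metadata(counts: pd.DataFrame, libraries: pd.DataFrame) -> None:
    missing = counts.columns.difference(libraries.index)
    if len(missing):
        raise ValidationError(
            f"counts columns without metadata: {list(missing[:5])}"
        )


def write_counts(counts: pd.DataFrame, path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    return path


def write_gene_lengths(genes: pd.DataFrame, path) -> Path:
    path = Path(path)
    genes[["length"]].to_csv(path, sep="\t")
    return path


def write_library_metadata(libraries: pd.DataFrame, path) -> Path:
    path = Path(path)
    libraries.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# GFF3 gene lengths


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based end-inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def read_gff3_lengths(path) -> pd.DataFrame:
    """Per-gene exonic length from a GFF3 annotation.

    L(gene) = total length of the union of the gene's exon intervals. Exons
    are attached to a gene through a ``gene_id`` attribute when present, or
    else through the Parent chain up to a feature of type ``gene``.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise ValidationError(f"cannot parse GFF3 {path}: {exc}") from exc

    per_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        if "gene_id" in exon.attributes:
            gene_ids = exon.attributes["gene_id"]
        else:
            gene_ids = [g.id for g in db.parents(exon, featuretype="gene")]
            if not gene_ids:
                gene_ids = exon.attributes.get("Parent", [])
        for gid in gene_ids:
            per_gene.setdefault(gid, []).append((exon.start, exon.end))
    if not per_gene:
        raise ValidationError(f"{path}: no exon features with resolvable genes")
    genes = pd.DataFrame(
        {"length": {g: _merged_length(iv) for g, iv in per_gene.items()}}
    )
    genes.index.name = "gene_id"
    return genes.sort_index()


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    counts: str
    library_metadata: str
    output_dir: str
    gene_lengths: str | None = None
    gff3: str | None = None
    fdr_threshold: float = 1e-2
    log2_threshold: float = 1.0
    min_count: int = 1
    rpkm_summary_cutoffs: tuple[float, ...] = (1.0, 5.0)
    anchor_stage: str = "5"
    min_other_stages: int = 2
    fdr_method: str = "bh"
    groups: tuple[str, str] | None = None

    def validate(self) -> None:
        if self.fdr_threshold <= 0 or self.log2_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.min_count < 0:
            raise ValidationError("min_count must be non-negative")
        if (self.gene_lengths is None) == (self.gff3 is None):
            raise ValidationError(
                "exactly one of gene_lengths / gff3 must be supplied"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.groups is not None:
            cfg.groups = tuple(cfg.groups)
        cfg.rpkm_summary_cutoffs = tuple(cfg.rpkm_summary_cutoffs)
        cfg.anchor_stage = str(cfg.anchor_stage)
        return cfg


def _infer_groups(libraries: pd.DataFrame) -> tuple[str, str]:
    seen = list(dict.fromkeys(libraries["group"]))
    if len(seen) != 2:
        raise ValidationError(f"expected exactly two groups, found {seen}")
    if set(seen) == {"XX", "XY"}:
        return ("XX", "XY")
    return tuple(seen)  # type: ignore[return-value]


def _stage_order(libraries: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(libraries["stage"].astype(str)))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute quantification, testing and classification end to end.

    Writes, under ``config.output_dir``: the RPKM matrix, the per-library
    summary, one test table and one classification table per stage, the
    per-stage five-type tallies, the cross-stage gene sets (sex-specific,
    all-stage co-expressed, enhanced with supporting stages), the detection
    Venn partition and a JSON run log. Re-running with identical inputs
    reproduces identical files.
    """
    config.validate()
    counts = read_counts(config.counts)
    libraries = read_library_metadata(config.library_metadata)
    check_counts_metadata(counts, libraries)
    if config.gff3 is not None:
        genes = read_gff3_lengths(config.gff3)
    else:
        genes = read_gene_lengths(config.gene_lengths)

    groups = config.groups or _infer_groups(libraries)
    stages = _stage_order(libraries)
    if config.anchor_stage not in stages:
        raise ValidationError(
            f"anchor stage {config.anchor_stage!r} not among stages {stages}"
        )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rpkm = _expression.compute_rpkm(counts, genes, libraries)
    flags = _expression.detection_flags(counts, config.min_count)
    summary = _expression.library_summary(
        rpkm, counts, config.rpkm_summary_cutoffs, config.min_count
    )
    paths["rpkm"] = write_float_matrix(rpkm, outdir / "rpkm.tsv")
    paths["library_summary"] = write_table(summary, outdir / "library_summary.tsv")

    calls_by_stage: dict[str, pd.DataFrame] = {}
    tallies = {}
    for stage in stages:
        tests = _detest.test_stage(
            counts, rpkm, libraries, stage, groups,
            min_count=config.min_count, fdr_method=config.fdr_method,
        )
        lib1, lib2 = _detest._stage_pair(libraries, stage, groups)
        calls = _classify.classify_stage(
            tests, flags[lib1], flags[lib2], groups,
            config.fdr_threshold, config.log2_threshold,
        )
        calls_by_stage[stage] = calls
        tallies[stage] = calls["label"].value_counts().to_dict()
        paths[f"tests_{stage}"] = write_table(
            tests, outdir / f"tests_{stage}.tsv", pq_columns=("p_value", "q_value")
        )
        paths[f"classification_{stage}"] = write_table(
            calls,
            outdir / f"classification_{stage}.tsv",
            pq_columns=("p_value", "q_value"),
        )

    paths["five_type_counts"] = write_table(
        _classify.five_type_counts(calls_by_stage), outdir / "five_type_counts.tsv"
    )

    spec1, spec2 = _classify.sex_specific_genes(flags, libraries, groups)
    for g, spec in zip(groups, (spec1, spec2)):
        p = outdir / f"{g.lower()}_specific_genes.txt"
        p.write_text("".join(f"{gid}\n" for gid in sorted(spec)))
        paths[f"{g.lower()}_specific"] = p

    cogs = _classify.cog_all_stages(calls_by_stage)
    p = outdir / "cog_all_stages.txt"
    p.write_text("".join(f"{gid}\n" for gid in sorted(cogs)))
    paths["cog_all_stages"] = p

    enh1, enh2 = _classify.enhanced_genes(
        calls_by_stage, config.anchor_stage, config.min_other_stages, groups
    )
    for g, enh in zip(groups, (enh1, enh2)):
        paths[f"{g.lower()}_enhanced"] = write_table(
            enh.sort_index(), outdir / f"{g.lower()}_enhanced_genes.tsv"
        )

    venn = _classify.venn_partitions(flags, libraries, groups)
    venn_df = pd.DataFrame(
        {"partition": list(venn), "n_genes": list(venn.values())}
    ).set_index("partition")
    paths["venn"] = write_table(venn_df, outdir / "venn_partitions.tsv")

    from . import __version__

    log = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "groups": list(groups),
        "stages": stages,
        "n_genes": int(counts.shape[0]),
        "per_stage_label_counts": tallies,
        "venn": venn,
        "n_sex_specific": {groups[0]: len(spec1), groups[1]: len(spec2)},
        "n_cog_all_stages": len(cogs),
        "n_enhanced": {groups[0]: int(len(enh1)), groups[1]: int(len(enh2))},
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return paths
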