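"""Synthetic count data with planted gene classes.

Emulates a two-genotype (XX/XY) by four-stage gonadal RNA-seq design: one
library per genotype per stage, per-gene mapped read counts drawn Poisson
around an expression level expressed on the RPKM scale. Planted classes:

* ``cog``     — identical true expression in both genotypes,
* ``xx_dig``  — expression multiplied by ``dig_fold`` in XX only,
* ``xy_dig``  — expression multiplied by ``dig_fold`` in XY only,
* ``xx_seg``  — expressed in XX, true expression exactly 0 in XY,
* ``xy_seg``  — expressed in XY, true expression exactly 0 in XX,
* ``silent``  — true expression 0 everywhere.

The count for gene g in library s is Poisson with mean

    mu = q_gs * L_g * N_s / 1e9

where q_gs is the true RPKM-scale level, L_g the gene length in nucleotides
and N_s the library's total mapped reads — i.e. the RPKM formula inverted, so
the downstream RPKM estimate is unbiased for q. Counts are Poisson, matching
the sampling model of the two-library exact test so that null simulations are
a calibrated type-I-error check.

Each library draws from its own deterministic substream (master seed spawned
per library index), so adding stages or libraries never perturbs the counts
of earlier columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PLANTED_CLASSES = ("cog", "xx_dig", "xy_dig", "xx_seg", "xy_seg", "silent")

#: Default planted-class mix.  XY-biased classes are more frequent than
#: XX-biased ones, mirroring the asymmetry typical of gonadal transcriptomes.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "cog": 0.55,
    "xx_dig": 0.10,
    "xy_dig": 0.15,
    "xx_seg": 0.01,
    "xy_seg": 0.04,
    "silent": 0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``library_sizes`` is either a single integer applied to every library or
    a mapping from library id (``"<group>_<stage>"``) to total mapped reads.
    ``class_schedule`` optionally re-labels a planted class at chosen stages,
    e.g. ``{"xx_dig": {"180": "cog"}}`` makes every gene planted as
    ``xx_dig`` behave as a co-expressed gene at stage 180 — the hook used to
    exercise the cross-stage enhanced-gene rule.
    """

    n_genes: int = 21000
    stages: tuple[str, ...] = ("5", "30", "90", "180")
    groups: tuple[str, str] = ("XX", "XY")
    library_sizes: int | Mapping[str, int] = 5_000_000
    gene_length_range: tuple[int, int] = (500, 3000)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    dig_fold: float = 8.0
    base_expression_range: tuple[float, float] = (50.0, 500.0)
    seed: int = 0
    class_schedule: Mapping[str, Mapping[str, str]] | None = None

    def library_ids(self) -> list[str]:
        return [f"{g}_{s}" for s in self.stages for g in self.groups]

    def library_size_of(self, library_id: str) -> int:
        if isinstance(self.library_sizes, Mapping):
            try:
                return int(self.library_sizes[library_id])
            except KeyError:
                raise ConfigurationError(
                    f"library_sizes has no entry for library {library_id!r}"
                ) from None
        return int(self.library_sizes)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.groups) != 2 or len(set(self.groups)) != 2:
            raise ConfigurationError("exactly two distinct group labels required")
        stages = [str(s) for s in self.stages]
        if not stages or len(set(stages)) != len(stages):
            raise ConfigurationError("stages must be non-empty and unique")
        fractions = dict(self.class_fractions)
        unknown = set(fractions) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in fractions.values()):
            raise ConfigurationError("class fractions must be non-negative")
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class fractions must sum to 1, got {sum(fractions.values())!r}"
            )
        if self.dig_fold < 2:
            raise ConfigurationError(
                f"dig_fold must be >= 2 so planted DIGs pass |log2| >= 1, "
                f"got {self.dig_fold}"
            )
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"bad gene_length_range {self.gene_length_range}")
        qlo, qhi = self.base_expression_range
        if qlo <= 0 or qhi < qlo:
            raise ConfigurationError(
                f"bad base_expression_range {self.base_expression_range}"
            )
        for lib in self.library_ids():
            if self.library_size_of(lib) <= 0:
                raise ConfigurationError(f"library size for {lib!r} must be positive")
        if self.class_schedule:
            for cls, per_stage in self.class_schedule.items():
                if cls not in PLANTED_CLASSES:
                    raise ConfigurationError(f"schedule for unknown class {cls!r}")
                for stage, target in per_stage.items():
                    if str(stage) not in stages:
                        raise ConfigurationError(
                            f"schedule stage {stage!r} not among stages {stages}"
                        )
                    if target not in PLANTED_CLASSES:
                        raise ConfigurationError(
                            f"schedule target class {target!r} unknown"
                        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene-per-stage labels and true RPKM-scale expression."""

    labels: pd.DataFrame     # genes x stages, planted class label strings
    true_rpkm: pd.DataFrame  # genes x libraries, RPKM-scale means


def _apportion(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n genes to classes (deterministic)."""
    quotas = {c: n * fractions.get(c, 0.0) for c in PLANTED_CLASSES}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(
        PLANTED_CLASSES, key=lambda c: (counts[c] - quotas[c], c)
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _stage_label(cls: str, stage: str, schedule) -> str:
    if schedule and cls in schedule:
        return str(schedule[cls].get(stage, schedule[cls].get(str(stage), cls)))
    return cls


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns ``(counts, genes, libraries, truth)``: a genes x libraries count
    matrix, a gene table (gene_id, length), a library metadata table
    (library_id, group, stage, total_mapped_reads) and the ground truth.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    stages = [str(s) for s in config.stages]
    library_ids = config.library_ids()

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(1 + len(library_ids))
    rng_structure = np.random.default_rng(streams[0])

    n = config.n_genes
    gene_ids = [f"gene{i:06d}" for i in range(n)]

    counts_per_class = _apportion(n, dict(config.class_fractions))
    label_pool = np.repeat(
        list(counts_per_class.keys()), list(counts_per_class.values())
    )
    planted = rng_structure.permutation(label_pool)

    lmin, lmax = config.gene_length_range
    lengths = rng_structure.integers(lmin, lmax + 1, size=n)

    qlo, qhi = config.base_expression_range
    base_q = np.exp(rng_structure.uniform(np.log(qlo), np.log(qhi), size=n))

    # True RPKM-scale expression per gene per library.
    labels = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"), columns=stages)
    true_q = np.zeros((n, len(library_ids)))
    lib_meta = []
    for j, lib in enumerate(library_ids):
        group = lib.rsplit("_", 1)[0]
        stage = lib.rsplit("_", 1)[1]
        lib_meta.append(
            {
                "library_id": lib,
                "group": group,
                "stage": stage,
                "total_mapped_reads": config.library_size_of(lib),
            }
        )
    for si, stage in enumerate(stages):
        stage_labels = np.array(
            [_stage_label(c, stage, config.class_schedule) for c in planted]
        )
        labels[stage] = stage_labels
        for group in config.groups:
            j = library_ids.index(f"{group}_{stage}")
            q = base_q.copy()
            q[stage_labels == "silent"] = 0.0
            if group == config.groups[0]:  # the XX-like group
                q[stage_labels == "xy_seg"] = 0.0
                q[stage_labels == "xx_dig"] *= config.dig_fold
            else:
                q[stage_labels == "xx_seg"] = 0.0
                q[stage_labels == "xy_dig"] *= config.dig_fold
            true_q[:, j] = q

    counts = np.zeros((n, len(library_ids)), dtype=np.int64)
    for j, lib in enumerate(library_ids):
        rng_lib = np.random.default_rng(streams[1 + j])
        mu = true_q[:, j] * lengths * lib_meta[j]["total_mapped_reads"] / 1e9
        counts[:, j] = rng_lib.poisson(mu)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=library_ids
    )
    genes_df = pd.DataFrame(
        {"length": lengths}, index=pd.Index(gene_ids, name="gene_id")
    )
    libraries_df = pd.DataFrame(lib_meta).set_index("library_id")
    truth = GroundTruth(
        labels=labels,
        true_rpkm=pd.DataFrame(
            true_q, index=pd.Index(gene_ids, name="gene_id"), columns=library_ids
        ),
    )
    return counts_df, genes_df, libraries_df, truth


def write_fixture(
    dataset: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth],
    directory: str | Path,
) -> dict[str, Path]:
    """Write a generated dataset as the pipeline's TSV fixture files.

    Emits counts, gene-length, library-metadata and truth tables in the
    formats the readers in :mod:`digseg.io` accept, and returns their paths.
    """
    from . import io as dio

    counts, genes, libraries, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "gene_lengths": directory / "gene_lengths.tsv",
        "libraries": directory / "libraries.tsv",
        "truth_labels": directory / "truth_labels.tsv",
        "truth_rpkm": directory / "truth_rpkm.tsv",
    }
    dio.write_counts(counts, paths["counts"])
    dio.write_gene_lengths(genes, paths["gene_lengths"])
    dio.write_library_metadata(libraries, paths["libraries"])
    truth.labels.to_csv(paths["truth_labels"], sep="\t")
    dio.write_float_matrix(truth.true_rpkm, paths["truth_rpkm"])
    return paths


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
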