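"""Strictly-maternal-factor calling from normalized expression matrices.

A probe is called maternal when its egg-stage expression is at least
``fold`` (default 4, inclusive) times the expression in *every* late-stage
somatic sample. Samples whose class is listed as excluded (early embryos,
gonads, embryonic stem cells in the original design) take no part in the
comparison. A gene is maternal when *any* of its probes is — inconsistent
multi-probe genes are retained, on the view that the discrepancy may reflect
alternative isoforms.

The matrix must be on a linear scale after normalization (e.g. GCRMA);
normalization itself is out of scope here. Egg replicates are aggregated by
mean (default) or min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

#: Heuristic ceiling: a linear-scale microarray matrix essentially always
#: exceeds this; a matrix that never does is probably still log2.
LOG_SCALE_SUSPECT_MAX = 30.0


@dataclass
class ExpressionMatrix:
    """Probes x samples linear-scale values plus probe->gene and sample->class maps."""

    values: pd.DataFrame            # index: probe_id, columns: sample_id
    gene_map: pd.Series             # probe_id -> gene_id
    sample_classes: dict[str, str]  # sample_id -> class name

    def __post_init__(self) -> None:
        if (self.values.values <= 0).any():
            raise InputError("expression values must be positive (linear scale)")
        missing = set(self.values.columns) - set(self.sample_classes)
        if missing:
            raise InputError(f"samples without a class: {sorted(missing)[:5]}")
        unmapped = self.values.index.difference(self.gene_map.index)
        if len(unmapped):
            import warnings

            warnings.warn(f"dropping {len(unmapped)} unmapped probe(s)", stacklevel=2)
            self.values = self.values.drop(index=unmapped)
        self.gene_map = self.gene_map.loc[self.values.index]


@dataclass(frozen=True)
class SampleGroups:
    """Egg classes vs excluded classes; everything else is somatic."""

    egg_classes: frozenset[str]
    excluded_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.egg_classes & self.excluded_classes
        if overlap:
            raise ConfigurationError(f"classes both egg and excluded: {sorted(overlap)}")

    def resolve(self, sample_classes: Mapping[str, str]) -> tuple[list[str], list[str]]:
        egg = [s for s, c in sample_classes.items() if c in self.egg_classes]
        somatic = [
            s
            for s, c in sample_classes.items()
            if c not in self.egg_classes and c not in self.excluded_classes
        ]
        if not egg:
            raise ConfigurationError("no egg samples resolved")
        if not somatic:
            raise ConfigurationError("no somatic samples left after exclusion")
        return egg, somatic


def call_probes(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    fold: float = 4.0,
    egg_stat: str = "mean",
    input_scale: str = "auto",
) -> pd.Series:
    """Per-probe maternal call: egg statistic >= fold x every somatic value.

    ``input_scale="auto"`` rejects matrices that look log2-transformed
    (no value above ~30); pass ``input_scale="linear"`` to assert the scale.
    """
    if fold <= 1:
        raise ConfigurationError(f"fold must be > 1, got {fold}")
    if egg_stat not in ("mean", "min"):
        raise ConfigurationError(f"egg_stat must be 'mean' or 'min', got {egg_stat!r}")
    if input_scale not in ("auto", "linear"):
        raise ConfigurationError(f"input_scale must be 'auto' or 'linear', got {input_scale!r}")
    if input_scale == "auto" and float(matrix.values.values.max()) < LOG_SCALE_SUSPECT_MAX:
        raise ConfigurationError(
            "matrix looks log2-scaled (no value above "
            f"{LOG_SCALE_SUSPECT_MAX}); unlog it or pass input_scale='linear'"
        )
    egg_samples, somatic_samples = groups.resolve(matrix.sample_classes)
    egg = matrix.values[egg_samples]
    stat = egg.mean(axis=1) if egg_stat == "mean" else egg.min(axis=1)
    somatic = matrix.values[somatic_samples].values
    calls = (stat.values[:, None] >= fold * somatic).all(axis=1)
    return pd.Series(calls, index=matrix.values.index, name="mf_probe")


def collapse_to_genes(probe_calls: pd.Series, gene_map: pd.Series) -> pd.DataFrame:
    """Gene table with the any-probe retention rule.

    Columns: gene_id, n_probes, n_mf_probes, mf_flag.
    """
    missing = probe_calls.index.difference(gene_map.index)
    if len(missing):
        raise InputError(f"probes without gene mapping: {list(missing[:5])}")
    df = pd.DataFrame({"gene_id": gene_map.loc[probe_calls.index], "mf": probe_calls})
    out = (
        df.groupby("gene_id", sort=True)
        .agg(n_probes=("mf", "size"), n_mf_probes=("mf", "sum"))
        .reset_index()
    )
    out["mf_flag"] = out["n_mf_probes"] > 0
    return out


def call_maternal_factors(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    fold: float = 4.0,
    egg_stat: str = "mean",
    input_scale: str = "auto",
) -> pd.DataFrame:
    """Probe calls collapsed to the gene level; convenience front door."""
    calls = call_probes(matrix, groups, fold=fold, egg_stat=egg_stat, input_scale=input_scale)
    return collapse_to_genes(calls, matrix.gene_map)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read the probe_id/gene_id/sample... TSV plus the sample-class table."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    if "probe_id" not in df.columns or "gene_id" not in df.columns:
        raise InputError(f"{path}: expected 'probe_id' and 'gene_id' columns")
    df = df.set_index("probe_id")
    gene_map = df.pop("gene_id")
    classes = read_groups_tsv(groups_path)
    return ExpressionMatrix(df.astype(float), gene_map, classes)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "class"], dtype=str)
    return dict(zip(df["sample_id"], df["class"]))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         groups_path: str | Path | None = None) -> None:
    df = matrix.values.copy()
    df.insert(0, "gene_id", matrix.gene_map)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s, c in matrix.sample_classes.items():
                fh.write(f"{s}\t{c}\n")
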