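"""Flat-text artifact readers shared by the CLI and pipeline.

All pipeline artifacts are TSV so runs are diffable; writers live next to
the objects they serialize (fixtures writers, ``SISResults.save``,
``mf.write_expression_tsv``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import AnnotatedGeneSet
from .errors import ParseError
from .labeling import CategoryLabels, GeneMetadata


def read_feature_table(path: str | Path) -> AnnotatedGeneSet:
    """Read a ``gene_id <tab> comma-joined-features`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "features"]:
        raise ParseError(f"{path}: expected columns gene_id, features")
    return AnnotatedGeneSet.from_mapping(
        {r["gene_id"]: frozenset(str(r["features"]).split(",")) for _, r in df.iterrows()}
    )


def read_labels(path: str | Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "categories" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id, categories")
    return {r["gene_id"]: frozenset(str(r["categories"]).split(",")) for _, r in df.iterrows()}


def write_labels(labels: dict[str, CategoryLabels], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategories\tprovenance\n")
        for gid in sorted(labels):
            lab = labels[gid]
            fh.write(f"{gid}\t{','.join(sorted(lab.categories))}\t{';'.join(lab.provenance)}\n")


def read_metadata(path: str | Path) -> list[GeneMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = []
    for _, r in df.iterrows():
        metas.append(
            GeneMetadata(
                gene_id=r["gene_id"],
                name=r.get("name", ""),
                description=r.get("description", ""),
                keywords=tuple(k for k in str(r.get("keywords", "")).split(";") if k),
                go_descriptions=tuple(k for k in str(r.get("go_descriptions", "")).split(";") if k),
                pfam_descriptions=tuple(k for k in str(r.get("pfam_descriptions", "")).split(";") if k),
                ec_number_present=str(r.get("ec_flag", "0")) in ("1", "True", "true"),
                tmhmm_positive=str(r.get("tmhmm_flag", "0")) in ("1", "True", "true"),
            )
        )
    return metas
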