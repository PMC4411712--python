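"""End-to-end pipeline: annotation evidence -> features -> labels -> fit -> predict.

Each stage writes one flat-text artifact another invocation can resume from;
a stage is skipped when its artifact already exists, so deleting a
downstream artifact and rerunning regenerates only the downstream stages.
The fully resolved configuration is echoed to ``config.resolved.json`` next
to the outputs, and identical configurations produce byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotations, io, labeling
from .core import SISModel, SISResults
from .errors import ConfigurationError, SistfError


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the method's published values."""

    # annotation
    pfam_evalue: float = 1e-3
    go_evalue: float = 1e-10
    go_top_hits: int = 10
    go_min_frac: float = 0.5
    min_gene_count: int = 20
    # homology labeling
    homology_min_hits: int = 2
    homology_top_hits: int = 10
    homology_min_frac: float = 0.5
    homology_min_identity: float = 25.0
    homology_evalue: float = 1e-20
    # classifier
    w_max: float = 1e6
    k_grid: tuple[int, ...] | None = None
    threads: int = 1
    seed: int = 0
    # inputs (either raw evidence or a prebuilt feature table)
    domtblout: str | None = None
    blast: str | None = None
    go_map: str | None = None
    feature_table: str | None = None
    metadata: str | None = None
    homology_blast: str | None = None   # defaults to ``blast`` when unset
    labels: str | None = None
    query_features: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        if "k_grid" in raw and raw["k_grid"] is not None:
            raw["k_grid"] = tuple(int(k) for k in raw["k_grid"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid) if self.k_grid is not None else None
        return d


def run_pipeline(config: RunConfig, outdir: str | Path, resume: bool = True) -> dict[str, Path]:
    """Run the stages in order, resuming from existing artifacts.

    Returns a mapping of stage name to artifact path. Raises
    :class:`SistfError` subclasses with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    (outdir / "config.resolved.json").write_text(
        json.dumps(config.resolved(), indent=1, sort_keys=True) + "\n"
    )

    # -- stage: features ----------------------------------------------------
    feat_path = outdir / "features.tsv"
    artifacts["features"] = feat_path
    if not (resume and feat_path.exists()):
        try:
            if config.feature_table:
                geneset = io.read_feature_table(config.feature_table)
            else:
                if not (config.domtblout and config.blast and config.go_map):
                    raise ConfigurationError(
                        "stage features: need feature_table or domtblout+blast+go_map"
                    )
                dhits = annotations.parse_domtblout(config.domtblout)
                bhits = annotations.parse_blast_tab(config.blast)
                go_map = annotations.read_go_map(config.go_map)
                pf = annotations.assign_pfam_features(dhits, config.pfam_evalue)
                go = annotations.assign_go_features(
                    bhits, go_map, config.go_evalue, config.go_top_hits, config.go_min_frac
                )
                geneset = annotations.build_feature_table(pf, go, config.min_gene_count)
            from .fixtures import write_feature_table

            write_feature_table(geneset, feat_path)
        except SistfError as exc:
            raise type(exc)(f"stage features: {exc}") from exc

    # -- stage: labels ------------------------------------------------------
    labels_path = outdir / "labels.tsv"
    artifacts["labels"] = labels_path
    if not (resume and labels_path.exists()):
        try:
            if config.labels:
                labels_path = Path(config.labels)
                artifacts["labels"] = labels_path
            else:
                if not config.metadata:
                    raise ConfigurationError("stage labels: need metadata or labels input")
                metas = io.read_metadata(config.metadata)
                hom = config.homology_blast or config.blast
                bhits = annotations.parse_blast_tab(hom) if hom else []
                labs = labeling.label_dataset(
                    metas,
                    bhits,
                    min_hits=config.homology_min_hits,
                    top_n=config.homology_top_hits,
                    min_frac=config.homology_min_frac,
                    min_identity=config.homology_min_identity,
                    evalue_max=config.homology_evalue,
                )
                io.write_labels(labs, labels_path)
        except SistfError as exc:
            raise type(exc)(f"stage labels: {exc}") from exc

    # -- stage: fit ---------------------------------------------------------
    model_dir = outdir / "model"
    artifacts["model"] = model_dir
    if not (resume and (model_dir / "model.json").exists()):
        try:
            geneset = io.read_feature_table(feat_path)
            labels = io.read_labels(artifacts["labels"])
            # the model only needs labels for genes that survived annotation
            model = SISModel(geneset, labels)
            results = model.fit(k_grid=config.k_grid, w_max=config.w_max,
                                threads=config.threads)
            results.save(model_dir)
            (model_dir / "summary.txt").write_text(results.summary() + "\n")
        except SistfError as exc:
            raise type(exc)(f"stage fit: {exc}") from exc

    # -- stage: predict -----------------------------------------------------
    pred_path = outdir / "predictions.tsv"
    artifacts["predictions"] = pred_path
    if not (resume and pred_path.exists()):
        try:
            results = SISResults.load(model_dir)
            if config.query_features:
                queries = io.read_feature_table(config.query_features)
            else:
                queries = io.read_feature_table(feat_path)
            preds = results.predict(queries, threads=config.threads)
            preds.to_csv(pred_path, sep="\t", index=False, float_format="%.12g")
        except SistfError as exc:
            raise type(exc)(f"stage predict: {exc}") from exc

    return artifacts
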