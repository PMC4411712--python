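"""Synthetic data generators with planted ground truth.

Everything downstream is testable offline against these generators:

* :func:`generate_geneset` plants category-specific Pfam/GO feature
  signatures into four balanced gene categories;
* :func:`generate_metadata` writes metadata (and a synthetic BLAST table)
  from which the labeling rules recover the planted categories exactly;
* :func:`make_annotation_evidence` re-expresses a gene set as hmmscan/BLAST/
  GO-map evidence files that round-trip through the annotation readers;
* :func:`generate_expression` plants strictly-maternal genes into a
  linear-scale expression matrix.

RNG layout (documented so the sampling can be re-simulated independently):
``generate_geneset`` uses one :func:`numpy.random.default_rng` substream per
category, seeded ``[seed, category_index]``. For each gene, in generation
order, a single uniform draw is made per candidate feature: first every
signature feature (category blocks 0..3, each block in feature order), then
every noise feature. A signature feature is included with probability
``signature_presence_prob`` in its own category and ``leak_prob`` elsewhere;
noise features with probability ``noise_presence_prob`` everywhere. A gene
that ends up featureless (possible only at extreme settings) receives one of
its own signature features drawn from the same substream.

Noiseless expression fixtures (``noise_sd = 0``) use integer egg levels and
place every planted gene's somatic values at exactly ``egg / fold``, so the
inclusive four-fold boundary is exact in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import BlastHit, DomainHit
from .datatypes import CATEGORIES, AnnotatedGene, AnnotatedGeneSet
from .errors import ConfigurationError
from .labeling import GeneMetadata
from .mf import ExpressionMatrix

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# gene sets with planted signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureSpec:
    """Design of a planted-signature gene set (per-category sizes and rates)."""

    n_genes_per_category: int = 100
    n_signature_features_per_category: int = 10
    n_noise_features: int = 60
    signature_presence_prob: float = 0.9
    leak_prob: float = 0.05
    noise_presence_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_genes_per_category >= 1, "n_genes_per_category", "must be >= 1")
        _check(self.n_signature_features_per_category >= 1,
               "n_signature_features_per_category", "must be >= 1")
        _check(self.n_noise_features >= 1, "n_noise_features", "must be >= 1")
        _check(0 <= self.leak_prob <= 1, "leak_prob", "must be in [0, 1]")
        _check(0 <= self.signature_presence_prob <= 1,
               "signature_presence_prob", "must be in [0, 1]")
        _check(self.signature_presence_prob > self.leak_prob,
               "signature_presence_prob", "must exceed leak_prob")
        _check(0 <= self.noise_presence_prob <= 1, "noise_presence_prob", "must be in [0, 1]")


def signature_feature_ids(spec: SignatureSpec) -> dict[str, tuple[str, ...]]:
    """Planted signature feature IDs per category (disjoint PF/GO namespaces)."""
    out: dict[str, tuple[str, ...]] = {}
    for c, cat in enumerate(CATEGORIES):
        ids = []
        for t in range(spec.n_signature_features_per_category):
            if t % 2 == 0:
                ids.append(f"PF{10000 + 1000 * c + t:05d}")
            else:
                ids.append(f"GO:{1000000 + 1000 * c + t:07d}")
        out[cat] = tuple(ids)
    return out


def noise_feature_ids(spec: SignatureSpec) -> tuple[str, ...]:
    ids = []
    for i in range(spec.n_noise_features):
        if i % 2 == 0:
            ids.append(f"PF{90000 + i:05d}")
        else:
            ids.append(f"GO:{9000000 + i:07d}")
    return tuple(ids)


def generate_geneset(
    spec: SignatureSpec,
) -> tuple[AnnotatedGeneSet, dict[str, frozenset[str]], dict[str, tuple[str, ...]]]:
    """Generate a planted-signature gene set.

    Returns ``(geneset, truth_labels, planted)`` where ``truth_labels`` maps
    gene_id to its planted category (as a singleton frozenset) and
    ``planted`` maps category to its signature feature IDs.
    """
    sig = signature_feature_ids(spec)
    noise = noise_feature_ids(spec)
    sig_blocks = [sig[cat] for cat in CATEGORIES]
    genes: list[AnnotatedGene] = []
    truth: dict[str, frozenset[str]] = {}
    for c, cat in enumerate(CATEGORIES):
        rng = np.random.default_rng([spec.seed, c])
        for g in range(spec.n_genes_per_category):
            gid = f"{cat}{g:05d}"
            feats: set[str] = set()
            for cp, block in enumerate(sig_blocks):
                p = spec.signature_presence_prob if cp == c else spec.leak_prob
                draws = rng.random(len(block))
                feats.update(f for f, d in zip(block, draws) if d < p)
            draws = rng.random(len(noise))
            feats.update(f for f, d in zip(noise, draws) if d < spec.noise_presence_prob)
            if not feats:
                feats.add(sig_blocks[c][int(rng.integers(len(sig_blocks[c])))])
            genes.append(AnnotatedGene(gid, frozenset(feats)))
            truth[gid] = frozenset({cat})
    return AnnotatedGeneSet(genes), truth, sig


def make_protein_fasta(
    geneset: AnnotatedGeneSet, seed: int, min_len: int = 120, max_len: int = 480
) -> list[SeqRecord]:
    """Random protein sequences for the gene set (pre-filter plumbing only)."""
    rng = np.random.default_rng([seed, 99])
    recs = []
    for g in geneset:
        n = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_AA[i] for i in rng.integers(0, len(_AA), n))
        recs.append(SeqRecord(Seq(seq), id=g.gene_id, description=""))
    return recs


# ---------------------------------------------------------------------------
# metadata + BLAST tables for the labeling rules
# ---------------------------------------------------------------------------

_RULE_TEXT = {
    "TFS": dict(
        description="homeobox transcription factor",
        go_descriptions=("sequence-specific dna binding transcription factor activity",),
        pfam_descriptions=("Homeobox domain",),
    ),
    "MEM": dict(
        description="integral plasma membrane receptor",
        go_descriptions=("integral to membrane",),
        keywords=("Transmembrane",),
    ),
    "ENZ": dict(
        description="serine/threonine protein kinase, EC 2.7.11.1",
        ec_number_present=True,
    ),
    "OTS": dict(description="uncharacterized protein"),
}


def generate_metadata(
    geneset: AnnotatedGeneSet,
    truth: dict[str, frozenset[str]],
    seed: int,
) -> tuple[list[GeneMetadata], list[BlastHit]]:
    """Metadata and a synthetic BLAST table that the labeling rules decode.

    Layout, per category and generation order: every fifth gene is
    "rule-silent" and labeled only via homology to five rule-labeled genes of
    its category (plus two decoy hits failing the identity and E-value
    filters); every seventh OTS gene gets transcription-cofactor wording that
    must veto the TF keyword and land in OTS. All other genes carry their
    category's standard wording. Categories with fewer than seven genes fall
    back to rule wording only.
    """
    missing = [g.gene_id for g in geneset if g.gene_id not in truth]
    if missing:
        raise ConfigurationError(f"truth labels missing for {missing[:3]}")
    rng = np.random.default_rng([seed, 11])
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for g in geneset:
        (cat,) = truth[g.gene_id]
        by_cat[cat].append(g.gene_id)

    metas: list[GeneMetadata] = []
    blast: list[BlastHit] = []
    for cat, gids in by_cat.items():
        use_homology = len(gids) >= 7
        rule_ids = [g for i, g in enumerate(gids) if not (use_homology and i % 5 == 4)]
        for i, gid in enumerate(gids):
            homolog = use_homology and i % 5 == 4
            cofactor = cat == "OTS" and not homolog and i % 7 == 3
            if cofactor:
                metas.append(GeneMetadata(
                    gene_id=gid, name=gid,
                    description="transcription factor coactivator complex subunit",
                ))
            elif homolog:
                metas.append(GeneMetadata(gene_id=gid, name=gid,
                                          description="hypothetical protein"))
                subjects = [s for s in rule_ids if s != gid][:5]
                rank = 1
                if cat == "OTS":
                    # propagation covers TFS/MEM/ENZ only: give hits that fail
                    # the identity filter so the gene falls back to OTS
                    for s in subjects:
                        blast.append(BlastHit(gid, s, 20.0, 1e-40, rank))
                        rank += 1
                else:
                    for s in subjects:
                        ident = 70.0 + 25.0 * float(rng.random())
                        blast.append(BlastHit(gid, s, ident, 1e-40, rank))
                        rank += 1
                    blast.append(BlastHit(gid, f"DECOY_ID_{gid}", 20.0, 1e-40, rank))
                    rank += 1
                    blast.append(BlastHit(gid, f"DECOY_EV_{gid}", 90.0, 1e-5, rank))
            else:
                kw = dict(_RULE_TEXT[cat])
                metas.append(GeneMetadata(gene_id=gid, name=gid, **kw))
    return metas, blast


# ---------------------------------------------------------------------------
# annotation evidence (round-trips through the readers)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationEvidence:
    domain_hits: list[DomainHit]
    blast_hits: list[BlastHit]
    go_map: dict[str, frozenset[str]]


def make_annotation_evidence(geneset: AnnotatedGeneSet, evalue: float = 1e-12) -> AnnotationEvidence:
    """Express a gene set as hmmscan + BLAST + GO-map evidence.

    Each Pfam feature becomes one passing domain hit; each gene's GO features
    ride on two synthetic reference subjects, both carrying the full GO set,
    so the 50% transfer rule reassigns them exactly.
    """
    dhits: list[DomainHit] = []
    bhits: list[BlastHit] = []
    go_map: dict[str, frozenset[str]] = {}
    for g in geneset:
        pfams = sorted(f for f in g.features if f.startswith("PF"))
        gos = frozenset(f for f in g.features if f.startswith("GO:"))
        for pf in pfams:
            dhits.append(DomainHit(g.gene_id, pf, evalue))
        if gos:
            for r, suffix in enumerate(("A", "B"), start=1):
                subj = f"SP_{g.gene_id}_{suffix}"
                bhits.append(BlastHit(g.gene_id, subj, 95.0, evalue * r, r))
                go_map[subj] = gos
    return AnnotationEvidence(dhits, bhits, go_map)


# ---------------------------------------------------------------------------
# expression matrices with planted maternal factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Design of a planted-MF expression matrix.

    ``excluded_high_classes`` are sample classes (early embryos, gonads in
    the emulated design) in which planted genes are expressed HIGH; a caller
    that fails to exclude them misses every planted gene, which is what makes
    the exclusion rule testable.
    """

    n_genes: int = 500
    n_probes_per_gene: int = 2
    egg_samples: int = 3
    somatic_sample_classes: tuple[str, ...] = ("liver", "kidney", "brain", "heart", "lung")
    planted_mf_fraction: float = 0.1
    mf_fold: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0
    excluded_high_classes: tuple[str, ...] = ("blastocyst", "testis")
    samples_per_class: int = 2

    def __post_init__(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_probes_per_gene >= 1, "n_probes_per_gene", "must be >= 1")
        _check(self.egg_samples >= 1, "egg_samples", "must be >= 1")
        _check(len(self.somatic_sample_classes) >= 1, "somatic_sample_classes",
               "need at least one somatic class")
        _check(0 < self.planted_mf_fraction < 1, "planted_mf_fraction", "must be in (0, 1)")
        _check(self.mf_fold >= 4, "mf_fold", "must be >= 4")
        _check(0 <= self.noise_sd < 1 / 3, "noise_sd",
               "must be in [0, 1/3) so the construction margin holds")
        _check(self.samples_per_class >= 1, "samples_per_class", "must be >= 1")


def generate_expression(spec: ExpressionSpec) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Generate a planted-MF linear-scale expression matrix.

    Planted genes satisfy the inclusive ``mf_fold`` rule in every probe
    against every somatic sample (noiseless: exactly at the boundary) and are
    HIGH in the ``excluded_high_classes``; every non-planted gene has one
    somatic sample at egg level, violating the rule. log2-scale Gaussian
    noise (clipped at 3 sd) is added when ``noise_sd > 0``; the construction
    margin ``6*noise_sd + 0.25`` keeps the planted/violating status exact.
    """
    rng = np.random.default_rng([spec.seed, 7])
    gene_ids = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    n_planted = int(round(spec.n_genes * spec.planted_mf_fraction))
    perm = rng.permutation(spec.n_genes)
    planted_idx = set(int(i) for i in perm[:n_planted])
    planted_ids = tuple(gene_ids[i] for i in sorted(planted_idx))

    samples: list[tuple[str, str]] = [(f"egg_{r + 1}", "egg") for r in range(spec.egg_samples)]
    for cls in spec.somatic_sample_classes:
        samples += [(f"{cls}_{r + 1}", cls) for r in range(spec.samples_per_class)]
    for cls in spec.excluded_high_classes:
        samples += [(f"{cls}_{r + 1}", cls) for r in range(spec.samples_per_class)]
    sample_ids = [s for s, _ in samples]
    classes = {s: c for s, c in samples}
    egg_cols = [s for s, c in samples if c == "egg"]
    somatic_cols = [s for s, c in samples if c in spec.somatic_sample_classes]
    high_cols = [s for s, c in samples if c in spec.excluded_high_classes]

    def noise(n: int) -> np.ndarray:
        if spec.noise_sd == 0:
            return np.zeros(n)
        return np.clip(rng.normal(0.0, spec.noise_sd, n), -3 * spec.noise_sd, 3 * spec.noise_sd)

    probe_rows = []
    probe_ids = []
    gene_of_probe = []
    margin = 0.0 if spec.noise_sd == 0 else 6 * spec.noise_sd + 0.25
    for gi, gid in enumerate(gene_ids):
        is_planted = gi in planted_idx
        for p in range(spec.n_probes_per_gene):
            probe_ids.append(f"{gid}_at{p + 1}")
            gene_of_probe.append(gid)
            row = np.empty(len(sample_ids))
            if spec.noise_sd == 0:
                egg_val = float(rng.integers(256, 4097))
                vals = {s: egg_val for s in egg_cols}
                if is_planted:
                    vals.update({s: egg_val / spec.mf_fold for s in somatic_cols})
                    vals.update({s: egg_val for s in high_cols})
                else:
                    viol = somatic_cols[gi % len(somatic_cols)]
                    for s in somatic_cols:
                        vals[s] = egg_val if s == viol else egg_val / 8.0
                    vals.update({s: egg_val / 8.0 for s in high_cols})
                row[:] = [vals[s] for s in sample_ids]
            else:
                level = float(rng.uniform(8.0, 12.0))
                log2row = {}
                for s, e in zip(egg_cols, noise(len(egg_cols))):
                    log2row[s] = level + e
                if is_planted:
                    target = level - np.log2(spec.mf_fold) - margin
                    for s, e in zip(somatic_cols, noise(len(somatic_cols))):
                        log2row[s] = target + e
                    for s, e in zip(high_cols, noise(len(high_cols))):
                        log2row[s] = level + e
                else:
                    viol = somatic_cols[gi % len(somatic_cols)]
                    for s, e in zip(somatic_cols, noise(len(somatic_cols))):
                        log2row[s] = (level if s == viol else level - 3.0) + e
                    for s, e in zip(high_cols, noise(len(high_cols))):
                        log2row[s] = level - 3.0 + e
                row[:] = [2.0 ** log2row[s] for s in sample_ids]
            probe_rows.append(row)

    values = pd.DataFrame(np.asarray(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    gene_map = pd.Series(gene_of_probe, index=values.index, name="gene_id")
    return ExpressionMatrix(values, gene_map, classes), planted_ids


def default_sample_groups(spec: ExpressionSpec):
    """The SampleGroups matching :func:`generate_expression`'s design."""
    from .mf import SampleGroups

    return SampleGroups(frozenset({"egg"}), frozenset(spec.excluded_high_classes))


# ---------------------------------------------------------------------------
# writers (exact dialects the readers consume)
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")


def write_domtblout(hits: Sequence[DomainHit], path: str | Path) -> None:
    """hmmscan ``--domtblout`` dialect (23 whitespace-delimited columns)."""
    with open(path, "w") as fh:
        fh.write("# synthetic hmmscan --domtblout\n")
        for h in hits:
            fh.write(
                f"{h.pfam_id}_dom      {h.pfam_id}.1    100 {h.gene_id} - 300 "
                f"{h.evalue:.3g} 75.0 0.1 1 1 {h.evalue:.3g} {h.evalue:.3g} "
                f"74.0 0.1 1 100 10 110 9 111 0.95 synthetic domain\n"
            )


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path) -> None:
    """12-column tabular BLAST dialect (one row per hit, rank order)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query_id, h.rank)):
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t200\t10\t2\t"
                f"1\t200\t1\t200\t{h.evalue:.3g}\t250.0\n"
            )


def write_go_map(go_map: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for subj in sorted(go_map):
            for go in sorted(go_map[subj]):
                fh.write(f"{subj}\t{go}\n")


def write_metadata_tsv(metas: Sequence[GeneMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tname\tdescription\tkeywords\tgo_descriptions\t"
                 "pfam_descriptions\tec_flag\ttmhmm_flag\n")
        for m in metas:
            fh.write(
                f"{m.gene_id}\t{m.name}\t{m.description}\t{';'.join(m.keywords)}\t"
                f"{';'.join(m.go_descriptions)}\t{';'.join(m.pfam_descriptions)}\t"
                f"{int(m.ec_number_present)}\t{int(m.tmhmm_positive)}\n"
            )


def write_feature_table(geneset: AnnotatedGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfeatures\n")
        for g in sorted(geneset, key=lambda g: g.gene_id):
            fh.write(f"{g.gene_id}\t{','.join(sorted(g.features))}\n")


def write_truth_labels(truth: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategories\tprovenance\n")
        for gid in sorted(truth):
            fh.write(f"{gid}\t{','.join(sorted(truth[gid]))}\tplanted\n")
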