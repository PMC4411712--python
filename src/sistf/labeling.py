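"""Rule-based training-category labeling (TFS / MEM / ENZ / OTS).

Genes are first labeled from their metadata (names, descriptions, keywords,
GO/Pfam term descriptions, EC flags, TMHMM calls). Genes the rules leave
unlabeled are then labeled by homology: if at least two of the top-ten BLASTP
hits (identity >= 25%, E-value <= 1e-20) that already carry labels agree on a
category, the query inherits it; otherwise it falls to OTS. After both passes
every gene carries at least one category (OTS is the fallback), and a gene
may belong to several categories.

The "transcription factor activity" phrase list that drives GO/Pfam-based TF
detection is configurable; the shipped default is a documented stand-in list
of the standard molecular-function wordings. Transcription *cofactors*
(coactivator/corepressor/coregulator/cofactor wording) are vetoed out of TFS
and forced to OTS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datatypes import CATEGORIES
from .errors import InputError
from .annotations import BlastHit

#: Default stand-in phrase list for "transcription factor activity"-related
#: GO/Pfam descriptions (case-insensitive substring match).
DEFAULT_TF_ACTIVITY_PHRASES: tuple[str, ...] = (
    "transcription factor activity",
    "sequence-specific dna binding transcription factor activity",
    "dna-binding transcription factor activity",
    "rna polymerase ii transcription factor activity",
    "transcription regulator activity",
    "regulation of transcription",
)

COFACTOR_KEYWORDS: tuple[str, ...] = ("cofactor", "coregulator", "coactivator", "corepressor")

#: Frequent English words ending in "ase" that are not enzyme names.
_ASE_STOPWORDS = frozenset(
    {"base", "case", "phase", "disease", "decrease", "increase", "release",
     "cease", "purchase", "database", "lease", "please", "erase"}
)

_EC_RE = re.compile(r"\bec[ :]?\d+\.\d+(?:\.(?:\d+|-)){0,2}", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[a-z0-9-]+")


@dataclass(frozen=True)
class GeneMetadata:
    """Free-text and flag metadata used by the labeling rules."""

    gene_id: str
    name: str = ""
    description: str = ""
    keywords: tuple[str, ...] = ()
    go_descriptions: tuple[str, ...] = ()
    pfam_descriptions: tuple[str, ...] = ()
    ec_number_present: bool = False
    tmhmm_positive: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")


@dataclass(frozen=True)
class CategoryLabels:
    gene_id: str
    categories: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = self.categories - set(CATEGORIES)
        if bad:
            raise InputError(f"unknown categories {sorted(bad)}")


def _is_enzyme_text(description: str) -> bool:
    """EC-number pattern or an '-ase' word in a free-text description."""
    if _EC_RE.search(description):
        return True
    for tok in _TOKEN_RE.findall(description.lower()):
        if len(tok) > 4 and tok.endswith("ase") and tok not in _ASE_STOPWORDS:
            return True
    return False


def label_by_rules(
    meta: GeneMetadata,
    tf_phrases: Sequence[str] = DEFAULT_TF_ACTIVITY_PHRASES,
) -> CategoryLabels:
    """Apply the metadata rules; the result may be empty (homology pass next).

    TFS: a TF-activity phrase in any GO/Pfam description, or "transcription
    factor" / "transcription initiation factor" in the name or description —
    unless a cofactor keyword fires, which vetoes TFS and forces OTS.
    MEM: "membrane" in the description, "integral to membrane" among GO
    descriptions, "transmembrane" among keywords, or a positive TMHMM call.
    ENZ: EC number present/parsed, or an enzyme-like description.
    All matching is case-insensitive substring matching.
    """
    cats: set[str] = set()
    prov: list[str] = []
    name_desc = f"{meta.name} {meta.description}".lower()
    term_texts = [t.lower() for t in (*meta.go_descriptions, *meta.pfam_descriptions)]
    keywords = [k.lower() for k in meta.keywords]

    tf_hit = (
        any(p.lower() in t for p in tf_phrases for t in term_texts)
        or "transcription factor" in name_desc
        or "transcription initiation factor" in name_desc
    )
    cofactor = any(k in name_desc for k in COFACTOR_KEYWORDS) or any(
        c in k for c in COFACTOR_KEYWORDS for k in keywords
    )
    if cofactor:
        cats.add("OTS")
        prov.append("cofactor-veto")
    elif tf_hit:
        cats.add("TFS")
        prov.append("tf-keyword")

    if (
        "membrane" in meta.description.lower()
        or any("integral to membrane" in t for t in (g.lower() for g in meta.go_descriptions))
        or any("transmembrane" in k for k in keywords)
        or meta.tmhmm_positive
    ):
        cats.add("MEM")
        prov.append("membrane-rule")

    if meta.ec_number_present or _is_enzyme_text(meta.description):
        cats.add("ENZ")
        prov.append("enzyme-rule")

    return CategoryLabels(meta.gene_id, frozenset(cats), tuple(prov))


def propagate_by_homology(
    gene_id: str,
    hits: Sequence[BlastHit],
    labels_so_far: Mapping[str, frozenset[str]],
    min_hits: int = 2,
    top_n: int = 10,
    min_frac: float = 0.5,
    min_identity: float = 25.0,
    evalue_max: float = 1e-20,
) -> CategoryLabels:
    """Label an unlabeled gene from the labels of its qualifying BLAST hits.

    Among the top ``top_n`` hits passing the identity and E-value filters,
    every category in {TFS, MEM, ENZ} shared by at least ``min_frac`` of them
    is assigned, provided at least ``min_hits`` hits qualify; otherwise OTS.
    """
    kept = [
        h
        for h in sorted(hits, key=lambda h: h.rank)
        if h.rank <= top_n and h.identity_pct >= min_identity and h.evalue <= evalue_max
    ]
    if len(kept) >= min_hits:
        cats: set[str] = set()
        for cat in ("TFS", "MEM", "ENZ"):
            n = sum(1 for h in kept if cat in labels_so_far.get(h.subject_id, frozenset()))
            if n >= min_frac * len(kept):
                cats.add(cat)
        if cats:
            return CategoryLabels(gene_id, frozenset(cats), ("homology",))
    return CategoryLabels(gene_id, frozenset({"OTS"}), ("homology-fallback",))


def finalize_labels(partials: Iterable[CategoryLabels]) -> dict[str, CategoryLabels]:
    """OTS fallback for label-less genes; error on duplicate gene IDs."""
    out: dict[str, CategoryLabels] = {}
    for lab in partials:
        if lab.gene_id in out:
            raise InputError(f"duplicate gene_id {lab.gene_id!r}")
        if lab.categories:
            out[lab.gene_id] = lab
        else:
            out[lab.gene_id] = CategoryLabels(lab.gene_id, frozenset({"OTS"}), ("ots-fallback",))
    return out


def label_dataset(
    metadata: Sequence[GeneMetadata],
    blast: Sequence[BlastHit] = (),
    tf_phrases: Sequence[str] = DEFAULT_TF_ACTIVITY_PHRASES,
    **homology_kwargs,
) -> dict[str, CategoryLabels]:
    """Full labeling pipeline: metadata rules, homology pass, OTS fallback.

    The homology pass runs only for genes the rules left unlabeled, using the
    rule-derived labels of their hit subjects; output is independent of input
    ordering.
    """
    rule_labels = {m.gene_id: label_by_rules(m, tf_phrases) for m in metadata}
    known = {gid: lab.categories for gid, lab in rule_labels.items() if lab.categories}
    hits_by_query: dict[str, list[BlastHit]] = {}
    for h in blast:
        hits_by_query.setdefault(h.query_id, []).append(h)
    final: list[CategoryLabels] = []
    for gid in sorted(rule_labels):
        lab = rule_labels[gid]
        if not lab.categories:
            lab = propagate_by_homology(gid, hits_by_query.get(gid, ()), known, **homology_kwargs)
        final.append(lab)
    return finalize_labels(final)


def category_totals(labels: Mapping[str, CategoryLabels]) -> dict[str, int]:
    """Per-category gene totals (multi-label genes counted in each)."""
    totals = {c: 0 for c in CATEGORIES}
    for lab in labels.values():
        for c in lab.categories:
            totals[c] += 1
    return totals
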