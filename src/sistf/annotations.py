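"""Build the binary feature table from raw annotation evidence.

Pfam features come from HMMER ``hmmscan --domtblout`` output (full-sequence
E-value, threshold 1e-3, accession version suffix stripped). GO features are
transferred from tabular BLASTP hits against an annotated reference using the
conservative criteria: E-value <= 1e-10, top 10 hits per query, and a GO term
is adopted only when it occurs in at least half of the kept hits. Two corpus
filters follow: features observed in fewer than ``min_gene_count`` genes are
removed, then genes left without any feature are excluded.

Sequence pre-filters (length 50-5000, standard amino-acid alphabet) and the
longest-per-cluster redundancy reduction (from a precomputed CD-HIT-style
cluster table) live here as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO
from Bio.SeqRecord import SeqRecord

from .datatypes import AnnotatedGene, AnnotatedGeneSet
from .errors import ConfigurationError, ConsistencyError, ParseError

#: 20 standard amino acids plus the common ambiguity codes X/B/Z and
#: selenocysteine U. Anything else (e.g. ``*``) counts as irregular.
DEFAULT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

_PFAM_ACC_RE = re.compile(r"^(PF\d{5})(?:\.\d+)?$")

BLAST12_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class DomainHit:
    """One hmmscan domain hit: gene, Pfam accession (unversioned), E-value."""

    gene_id: str
    pfam_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ConsistencyError(f"E-value must be positive, got {self.evalue}")
        if not re.fullmatch(r"PF\d{5}", self.pfam_id):
            raise ConsistencyError(f"malformed Pfam accession {self.pfam_id!r}")


@dataclass(frozen=True)
class BlastHit:
    """One BLASTP hit with its 1-based rank (ascending E-value within query)."""

    query_id: str
    subject_id: str
    identity_pct: float
    evalue: float
    rank: int


# ---------------------------------------------------------------------------
# sequence pre-filters
# ---------------------------------------------------------------------------

def filter_sequences(
    records: Iterable[SeqRecord],
    min_len: int = 50,
    max_len: int = 5000,
    alphabet: frozenset[str] = DEFAULT_ALPHABET,
) -> tuple[list[SeqRecord], list[tuple[str, str]]]:
    """Retain sequences with 50 <= length <= 5000 and a regular alphabet.

    Returns ``(retained, report)`` where the report lists ``(id, reason)``
    per rejected record.
    """
    kept: list[SeqRecord] = []
    report: list[tuple[str, str]] = []
    for rec in records:
        if not rec.id:
            raise ParseError("FASTA record with empty identifier")
        seq = str(rec.seq).upper()
        n = len(seq)
        if n < min_len:
            report.append((rec.id, f"too short ({n} < {min_len})"))
        elif n > max_len:
            report.append((rec.id, f"too long ({n} > {max_len})"))
        else:
            bad = set(seq) - alphabet
            if bad:
                report.append((rec.id, f"irregular characters {''.join(sorted(bad))!r}"))
            else:
                kept.append(rec)
    return kept, report


def read_fasta(path: str | Path) -> list[SeqRecord]:
    try:
        return list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython message passthrough
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc


def apply_cluster_table(
    gene_lengths: Mapping[str, int], clusters: pd.DataFrame
) -> set[str]:
    """Keep the longest member of each cluster (ties: smallest gene_id).

    ``clusters`` has columns cluster_id, member_id, length (a precomputed
    CD-HIT-style table); genes absent from the table are kept unchanged.
    """
    keep: set[str] = set(gene_lengths) - set(clusters["member_id"])
    for _, grp in clusters.groupby("cluster_id", sort=False):
        best = grp.sort_values(["length", "member_id"], ascending=[False, True]).iloc[0]
        keep.add(str(best["member_id"]))
    return keep


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["cluster_id", "member_id", "length"])
    return df


# ---------------------------------------------------------------------------
# readers for hmmscan / BLAST output
# ---------------------------------------------------------------------------

def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse hmmscan ``--domtblout`` output into :class:`DomainHit` records.

    Comment lines (``#``) are skipped; the Pfam accession version suffix
    (``.N``) is stripped; the full-sequence E-value (column 7) is used.
    """
    path = Path(path)
    # Pre-scan for truncated rows so parse errors carry a row number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.split(None, 22)) < 23:
                raise ParseError(f"{path}: row {lineno}: expected >= 23 whitespace-delimited columns")
    hits: list[DomainHit] = []
    for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
        for hit in qresult:
            m = _PFAM_ACC_RE.match(hit.accession)
            if m is None:
                raise ParseError(f"{path}: malformed Pfam accession {hit.accession!r} for query {qresult.id}")
            hits.append(DomainHit(gene_id=qresult.id, pfam_id=m.group(1), evalue=float(hit.evalue)))
    return hits


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output.

    Multiple HSPs to the same subject are collapsed to the best E-value; hits
    are ranked 1..n within each query by ascending E-value (stable, so file
    order breaks ties).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 1: str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 tab-delimited columns, found {df.shape[1]}")
    df.columns = list(BLAST12_COLUMNS)
    hits: list[BlastHit] = []
    for _, grp in df.groupby("qseqid", sort=False):
        grp = grp.sort_values("evalue", kind="stable")
        grp = grp.drop_duplicates("sseqid", keep="first")
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            hits.append(
                BlastHit(
                    query_id=str(row["qseqid"]),
                    subject_id=str(row["sseqid"]),
                    identity_pct=float(row["pident"]),
                    evalue=float(row["evalue"]),
                    rank=rank,
                )
            )
    return hits


def read_go_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a subject_id -> GO terms mapping from a two-column TSV."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: row {lineno}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# feature assignment
# ---------------------------------------------------------------------------

def assign_pfam_features(
    hits: Sequence[DomainHit], evalue_max: float = 1e-3
) -> dict[str, frozenset[str]]:
    """Map gene -> Pfam feature set, keeping hits with E-value <= threshold."""
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue <= evalue_max:
            out.setdefault(h.gene_id, set()).add(h.pfam_id)
    return {k: frozenset(v) for k, v in out.items()}


def assign_go_features(
    blast: Sequence[BlastHit],
    hit_go: Mapping[str, frozenset[str]],
    evalue_max: float = 1e-10,
    top_n: int = 10,
    min_frac: float = 0.5,
) -> dict[str, frozenset[str]]:
    """Transfer GO terms from BLAST hits under the conservative criteria.

    Per query: keep hits with E-value <= ``evalue_max``, truncate to the top
    ``top_n`` by rank, then adopt every GO term occurring in at least
    ``min_frac`` of the kept hits. Subjects absent from ``hit_go`` contribute
    empty GO sets (they still count in the denominator).
    """
    if not (0 < min_frac <= 1):
        raise ConfigurationError(f"min_frac must be in (0, 1], got {min_frac}")
    by_query: dict[str, list[BlastHit]] = {}
    for h in blast:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, frozenset[str]] = {}
    for query, qhits in by_query.items():
        qhits = sorted(qhits, key=lambda h: h.rank)
        kept = [h for h in qhits if h.evalue <= evalue_max][:top_n]
        if not kept:
            out[query] = frozenset()
            continue
        counts: dict[str, int] = {}
        for h in kept:
            for go in hit_go.get(h.subject_id, frozenset()):
                counts[go] = counts.get(go, 0) + 1
        need = min_frac * len(kept)
        out[query] = frozenset(go for go, c in counts.items() if c >= need)
    return out


def build_feature_table(
    pfam_features: Mapping[str, frozenset[str]],
    go_features: Mapping[str, frozenset[str]],
    min_gene_count: int = 20,
) -> AnnotatedGeneSet:
    """Union Pfam and GO features per gene, then apply the corpus filters.

    In order: (1) drop features present in fewer than ``min_gene_count``
    genes; (2) drop genes left without any feature. Raises
    :class:`ConsistencyError` when nothing survives.
    """
    if min_gene_count < 1:
        raise ConfigurationError(f"min_gene_count must be >= 1, got {min_gene_count}")
    merged: dict[str, set[str]] = {}
    for mapping in (pfam_features, go_features):
        for gid, feats in mapping.items():
            merged.setdefault(gid, set()).update(feats)
    counts: dict[str, int] = {}
    for feats in merged.values():
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    surviving = {f for f, c in counts.items() if c >= min_gene_count}
    genes = [
        AnnotatedGene(gid, frozenset(feats & surviving))
        for gid, feats in merged.items()
        if feats & surviving
    ]
    if not genes:
        raise ConsistencyError("no informative features: every feature fell below min_gene_count")
    return AnnotatedGeneSet(sorted(genes, key=lambda g: g.gene_id))
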