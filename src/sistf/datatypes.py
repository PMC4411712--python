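"""Core containers: annotated genes, the feature space, and category constants.

A *feature* is a Pfam accession (``PF#####``) or a GO term (``GO:#######``).
Genes are represented by the set of features annotated on them; the
:class:`FeatureSpace` fixes the coordinate order (ascending byte-wise sort of
the feature IDs) used when genes are encoded as binary vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ConsistencyError, InputError

#: The four training categories, in the column order used by weight tables:
#: transcription factors, transmembrane proteins, enzymes, everything else.
CATEGORIES: tuple[str, ...] = ("TFS", "MEM", "ENZ", "OTS")

#: Priority order used to break exact score ties in nearest-neighbor
#: classification (highest priority first).
NNA_TIE_ORDER: tuple[str, ...] = ("TFS", "ENZ", "MEM", "OTS")


class FeatureSpace:
    """Ordered, duplicate-free universe of feature IDs.

    The order is ascending byte-wise ("alphabetical") order; index ``i`` of a
    feature is its coordinate in every binary gene vector.
    """

    __slots__ = ("ids", "_index")

    def __init__(self, ids: Iterable[str]):
        uniq = sorted(set(ids))
        if not uniq:
            raise InputError("feature space must contain at least one feature")
        self.ids: tuple[str, ...] = tuple(uniq)
        self._index = {f: i for i, f in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureSpace) and self.ids == other.ids

    def __hash__(self) -> int:
        return hash(self.ids)

    def index_of(self, feature_id: str) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            raise ConsistencyError(f"feature {feature_id!r} is not in the feature space") from None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FeatureSpace(n={len(self)})"


@dataclass(frozen=True)
class AnnotatedGene:
    """A gene/protein with its identifier and set of annotated features."""

    gene_id: str
    features: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if not self.features:
            raise InputError(f"gene {self.gene_id!r} has no features")


class AnnotatedGeneSet:
    """A collection of annotated genes plus the feature space spanning them.

    Invariants enforced at construction: unique gene IDs, every gene has at
    least one feature, and every feature of every gene lies in the feature
    space.
    """

    def __init__(self, genes: Iterable[AnnotatedGene], feature_space: FeatureSpace | None = None):
        self.genes: list[AnnotatedGene] = list(genes)
        if not self.genes:
            raise InputError("gene set is empty")
        seen: set[str] = set()
        all_feats: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise InputError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            all_feats.update(g.features)
        if feature_space is None:
            feature_space = FeatureSpace(all_feats)
        else:
            missing = all_feats - set(feature_space.ids)
            if missing:
                raise ConsistencyError(
                    f"{len(missing)} feature(s) outside the feature space, e.g. {sorted(missing)[:3]}"
                )
        self.feature_space = feature_space

    @classmethod
    def from_mapping(cls, feats: Mapping[str, Iterable[str]]) -> "AnnotatedGeneSet":
        """Build from a ``gene_id -> iterable of feature IDs`` mapping."""
        genes = [AnnotatedGene(gid, frozenset(fs)) for gid, fs in feats.items()]
        return cls(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[AnnotatedGene]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def sorted_by_id(self) -> "AnnotatedGeneSet":
        """Return a copy with genes in ascending gene_id order (same space)."""
        out = AnnotatedGeneSet(sorted(self.genes, key=lambda g: g.gene_id), self.feature_space)
        return out

    def to_matrix(self) -> np.ndarray:
        """Binary M x N indicator matrix in gene order x feature-space order."""
        mat = np.zeros((len(self.genes), len(self.feature_space)), dtype=np.uint8)
        for m, g in enumerate(self.genes):
            for f in g.features:
                mat[m, self.feature_space.index_of(f)] = 1
        return mat

    def feature_counts(self) -> dict[str, int]:
        """Number of genes carrying each feature."""
        counts: dict[str, int] = {f: 0 for f in self.feature_space}
        for g in self.genes:
            for f in g.features:
                counts[f] += 1
        return counts

    def as_mapping(self) -> dict[str, frozenset[str]]:
        return {g.gene_id: g.features for g in self.genes}
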