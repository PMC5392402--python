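"""Sparse ER feature vectors for interaction classification.

The classifier sees an interaction as the vector of enrichment ratios
of the *significant* term pairs it contains; non-significant pairs and
absent pairs contribute nothing (implicit zero).  An interaction that
contains no significant pair at all cannot be scored — that case is the
distinguished ``NO_FEATURE`` outcome, never a silent all-zero vector,
so downstream code can report coverage honestly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .enrichment import PairScoreTable, TermPair, extract_term_pairs
from .io_formats import AnnotationCatalog, InteractionRecord


class _NoFeature:
    """Singleton marker: the interaction carries no significant pair."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_FEATURE"

    def __bool__(self) -> bool:
        return False


NO_FEATURE = _NoFeature()

FEATURE_SCALES = ("raw", "log2")


@dataclass
class FeatureIndex:
    """Ordered universe of significant term pairs with their ER values."""

    namespace: str
    pairs: list[TermPair] = field(default_factory=list)
    er_lookup: dict[TermPair, float] = field(default_factory=dict)
    p_lookup: dict[TermPair, float] = field(default_factory=dict)
    feature_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_scale not in FEATURE_SCALES:
            raise ValueError(f"unknown feature scale {self.feature_scale!r}")
        self._position = {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    def position(self, pair: TermPair) -> int | None:
        return self._position.get(pair)

    def value(self, pair: TermPair) -> float:
        er = self.er_lookup[pair]
        if self.feature_scale == "log2":
            # ER = 0 (pair absent from reference class) maps to a large
            # negative value rather than -inf
            return math.log2(er) if er > 0 else math.log2(np.nextafter(0.0, 1.0))
        return er

    def digest(self) -> str:
        """Checksum tying a trained model to the index it was built on."""
        h = hashlib.sha256()
        h.update(self.namespace.encode())
        h.update(self.feature_scale.encode())
        for p in self.pairs:
            h.update(f"{p.left}\t{p.right}\t{self.er_lookup[p]:.12g}\n".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class FeatureVector:
    """Sparse map (index position -> feature value) of fixed dimension."""

    entries: tuple[tuple[int, float], ...]
    dimension: int

    def to_dense(self) -> np.ndarray:
        x = np.zeros(self.dimension)
        for i, v in self.entries:
            x[i] = v
        return x


def build_feature_index(table: PairScoreTable, feature_scale: str = "raw") -> FeatureIndex:
    """Index of the table's significant pairs, lexicographically ordered."""
    sig = table.significant_scores()
    pairs = sorted(s.pair for s in sig)
    er = {s.pair: s.er for s in sig}
    p = {s.pair: s.p_value for s in sig}
    return FeatureIndex(
        namespace=table.namespace, pairs=pairs, er_lookup=er, p_lookup=p,
        feature_scale=feature_scale,
    )


def featurize(
    interaction: InteractionRecord,
    catalog: AnnotationCatalog,
    index: FeatureIndex,
    directed: bool = True,
):
    """ER feature vector of one interaction, or ``NO_FEATURE``.

    Entries appear for exactly the indexed pairs present in the
    interaction's term-pair set; the value is the pair's (possibly
    log-scaled) ER from the index.
    """
    if catalog.namespace != index.namespace:
        raise ValueError(
            f"namespace mismatch: catalog {catalog.namespace!r} vs index {index.namespace!r}"
        )
    present = extract_term_pairs(interaction, catalog, directed)
    entries = sorted(
        (pos, index.value(pair))
        for pair in present
        if (pos := index.position(pair)) is not None
    )
    if not entries:
        return NO_FEATURE
    return FeatureVector(entries=tuple(entries), dimension=len(index))


def featurize_many(
    interactions,
    catalog: AnnotationCatalog,
    index: FeatureIndex,
    directed: bool = True,
):
    """Featurize a batch; returns (vectors, kept_positions, no_feature_positions)."""
    vectors: list[FeatureVector] = []
    kept: list[int] = []
    dropped: list[int] = []
    for i, rec in enumerate(interactions):
        fv = featurize(rec, catalog, index, directed)
        if fv is NO_FEATURE:
            dropped.append(i)
        else:
            vectors.append(fv)
            kept.append(i)
    return vectors, kept, dropped


def to_sparse_matrix(vectors: list[FeatureVector]) -> sparse.csr_matrix:
    """Stack feature vectors into a CSR design matrix."""
    if not vectors:
        raise ValueError("no feature vectors to stack")
    dim = vectors[0].dimension
    if any(v.dimension != dim for v in vectors):
        raise ValueError("feature vectors have inconsistent dimensions")
    data, indices, indptr = [], [], [0]
    for v in vectors:
        for i, val in v.entries:
            indices.append(i)
            data.append(val)
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(len(vectors), dim),
    )


# -- debug/export formats ---------------------------------------------------

def write_feature_index(index: FeatureIndex, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("left_term\tright_term\ter\tp_value\n")
        for pair in index.pairs:
            p = index.p_lookup.get(pair, float("nan"))
            fh.write(f"{pair.left}\t{pair.right}\t{index.er_lookup[pair]:.10g}\t{p:.10g}\n")
    return len(index)


def read_feature_index(path: str, namespace: str, feature_scale: str = "raw") -> FeatureIndex:
    pairs: list[TermPair] = []
    er: dict[TermPair, float] = {}
    pv: dict[TermPair, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            pair = TermPair(cols[0], cols[1], namespace)
            pairs.append(pair)
            er[pair] = float(cols[2])
            pv[pair] = float(cols[3]) if len(cols) > 3 else float("nan")
    return FeatureIndex(
        namespace=namespace, pairs=sorted(pairs), er_lookup=er, p_lookup=pv,
        feature_scale=feature_scale,
    )


def format_sparse(vector) -> str:
    """`index:value` text rendering of a vector (or ``NO_FEATURE``)."""
    if vector is NO_FEATURE:
        return "NO_FEATURE"
    return " ".join(f"{i}:{v:.6g}" for i, v in vector.entries)
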