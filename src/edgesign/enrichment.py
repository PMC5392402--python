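"""Term-pair enrichment scoring for signed interaction sets.

For a directed interaction (source regulates target) the candidate
features are the annotation pairs (term of source, term of target).
Each pair that occurs in at least one interaction is scored with an
enrichment ratio

    ER = (m/M) / (n/N)

where N is the number of interactions in the whole labeled set, M the
number in the reference class (activation by default), n the number of
interactions containing the pair, and m the number of reference-class
interactions containing it.  ER > 1 means the pair is over-represented
among activations, ER < 1 among inhibitions.

Significance is judged with the exact hypergeometric tail: drawing n
interactions without replacement from a population of N containing M
reference-class ones, the p-value is the upper tail P(X >= m) when
ER >= 1 and the lower tail P(X <= m) when ER < 1.  Tails are summed in
log space (gammaln + logsumexp) for stability; p-values are corrected
for multiple testing (Benjamini-Hochberg by default) across all tested
pairs.

The table of ERs can be pivoted into a (source-term x target-term)
matrix with hierarchically clustered row/column orders, the standard
view for spotting blocks of correlated pairs in a pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    ACTIVATION,
    INHIBITION,
    LABELS,
    AnnotationCatalog,
    InteractionRecord,
    InteractionSet,
    _check_namespace,
)

CORRECTIONS = ("bh", "bonferroni", "none")


class TermPair(NamedTuple):
    """(annotation of source, annotation of target) in one namespace."""

    left: str
    right: str
    namespace: str = "go"

    def canonical(self) -> "TermPair":
        """Endpoint-sorted copy, for undirected analyses."""
        if self.left <= self.right:
            return self
        return TermPair(self.right, self.left, self.namespace)


class ContingencyCounts(NamedTuple):
    """The (N, M, n, m) quadruple behind the ER and its tail test."""

    N: int
    M: int
    n: int
    m: int

    def validate(self) -> "ContingencyCounts":
        N, M, n, m = self
        if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
            raise ValueError(f"invalid contingency counts {self}")
        return self


def enrichment_ratio(counts: ContingencyCounts) -> float:
    """ER = (m/M)/(n/N); requires N, M, n >= 1."""
    N, M, n, m = counts.validate()
    if N == 0 or M == 0 or n == 0:
        raise ValueError(f"enrichment ratio undefined for counts {counts}")
    return (m / M) / (n / N)


def _exact_er_at_least_one(counts: ContingencyCounts) -> bool:
    # exact rational comparison m/M >= n/N, immune to float rounding
    N, M, n, m = counts
    return Fraction(m, M) >= Fraction(n, N)


def _log_pmf_terms(N: int, M: int, n: int, ms: np.ndarray) -> np.ndarray:
    # log C(M, m) + log C(N-M, n-m) - log C(N, n)
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(M, ms) + logC(N - M, n - ms) - logC(N, n)


def hypergeom_pvalue(counts: ContingencyCounts) -> float:
    """Exact hypergeometric tail probability for an ER.

    Upper tail P(X >= m) when ER >= 1 (ties go to the upper branch),
    lower tail P(X <= m) when ER < 1.  The support is
    max(0, n-(N-M)) <= X <= min(n, M); terms are accumulated with
    logsumexp so small counts are exact to well past 12 significant
    digits.
    """
    N, M, n, m = counts.validate()
    if N == 0 or M == 0 or n == 0:
        raise ValueError(f"p-value undefined for counts {counts}")
    lo = max(0, n - (N - M))
    hi = min(n, M)
    if _exact_er_at_least_one(counts):
        ms = np.arange(max(m, lo), hi + 1)
    else:
        ms = np.arange(lo, min(m, hi) + 1)
    if ms.size == 0:
        return 0.0
    p = float(np.exp(logsumexp(_log_pmf_terms(N, M, n, ms))))
    return min(p, 1.0)


def upper_tail(counts: ContingencyCounts) -> float:
    """P(X >= m) regardless of the ER branch (used by property checks)."""
    N, M, n, m = counts.validate()
    lo = max(0, n - (N - M))
    hi = min(n, M)
    ms = np.arange(max(m, lo), hi + 1)
    if ms.size == 0:
        return 0.0
    return min(float(np.exp(logsumexp(_log_pmf_terms(N, M, n, ms)))), 1.0)


def lower_tail(counts: ContingencyCounts) -> float:
    """P(X <= m) regardless of the ER branch."""
    N, M, n, m = counts.validate()
    lo = max(0, n - (N - M))
    hi = min(n, M)
    ms = np.arange(lo, min(m, hi) + 1)
    if ms.size == 0:
        return 0.0
    return min(float(np.exp(logsumexp(_log_pmf_terms(N, M, n, ms)))), 1.0)


# ---------------------------------------------------------------------------
# pair extraction and counting
# ---------------------------------------------------------------------------

def extract_term_pairs(
    interaction: InteractionRecord,
    catalog: AnnotationCatalog,
    directed: bool = True,
) -> frozenset[TermPair]:
    """Cartesian product of the endpoints' annotation sets.

    Empty when either protein is unannotated.  With ``directed=False``
    each pair is canonicalized (endpoints sorted lexicographically).
    """
    src_terms = catalog.terms(interaction.source)
    tgt_terms = catalog.terms(interaction.target)
    if not src_terms or not tgt_terms:
        return frozenset()
    pairs = (
        TermPair(a, b, catalog.namespace) for a in src_terms for b in tgt_terms
    )
    if not directed:
        pairs = (p.canonical() for p in pairs)
    return frozenset(pairs)


def count_pair_occurrences(
    interactions: InteractionSet,
    catalog: AnnotationCatalog,
    reference_class: str = ACTIVATION,
    directed: bool = True,
) -> dict[TermPair, ContingencyCounts]:
    """Contingency counts for every pair occurring in >= 1 interaction.

    Each interaction contributes at most 1 to n (and to m when its label
    is the reference class) per pair, however many times the pair could
    be formed.  N and M are shared across all entries.
    """
    if reference_class not in LABELS:
        raise ValueError(f"invalid reference class {reference_class!r}")
    N = len(interactions)
    M = 0
    n_by_pair: dict[TermPair, int] = {}
    m_by_pair: dict[TermPair, int] = {}
    for rec in interactions:
        if rec.label not in LABELS:
            raise ValueError(
                f"unlabeled interaction {rec.source}->{rec.target}; "
                "enrichment needs activation/inhibition labels"
            )
        is_ref = rec.label == reference_class
        if is_ref:
            M += 1
        for pair in extract_term_pairs(rec, catalog, directed):
            n_by_pair[pair] = n_by_pair.get(pair, 0) + 1
            if is_ref:
                m_by_pair[pair] = m_by_pair.get(pair, 0) + 1
    return {
        pair: ContingencyCounts(N, M, n, m_by_pair.get(pair, 0))
        for pair, n in n_by_pair.items()
    }


# ---------------------------------------------------------------------------
# scoring table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairScore:
    pair: TermPair
    counts: ContingencyCounts
    er: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class PairScoreTable:
    """All tested pairs with ER, p, corrected q and significance flag."""

    scores: list[PairScore] = field(default_factory=list)
    alpha: float = 0.05
    correction: str = "bh"
    reference_class: str = ACTIVATION
    namespace: str = "go"

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def significant_scores(self) -> list[PairScore]:
        return [s for s in self.scores if s.significant]


def _adjust(pvalues: np.ndarray, correction: str, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    if correction == "none":
        return pvalues <= alpha, pvalues.copy()
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
    reject, qvals, _, _ = multipletests(pvalues, alpha=alpha, method=method)
    return reject, qvals


def score_all_pairs(
    interactions: InteractionSet,
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
    correction: str = "bh",
    reference_class: str = ACTIVATION,
    directed: bool = True,
) -> PairScoreTable:
    """Score every occurring term pair and flag significance.

    q-values come from the chosen correction over all tested pairs;
    ``significant`` means q <= alpha.  The table is sorted by
    (q_value, p_value, pair) so output order is deterministic.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    counts_map = count_pair_occurrences(interactions, catalog, reference_class, directed)
    if not counts_map:
        return PairScoreTable(
            alpha=alpha, correction=correction,
            reference_class=reference_class, namespace=catalog.namespace,
        )
    pairs = sorted(counts_map)
    pvalues = np.array([hypergeom_pvalue(counts_map[p]) for p in pairs])
    reject, qvalues = _adjust(pvalues, correction, alpha)
    scores = [
        PairScore(
            pair=pair,
            counts=counts_map[pair],
            er=enrichment_ratio(counts_map[pair]),
            p_value=float(pv),
            q_value=float(qv),
            significant=bool(sig),
        )
        for pair, pv, qv, sig in zip(pairs, pvalues, qvalues, reject)
    ]
    scores.sort(key=lambda s: (s.q_value, s.p_value, s.pair))
    return PairScoreTable(
        scores=scores, alpha=alpha, correction=correction,
        reference_class=reference_class, namespace=catalog.namespace,
    )


SCORE_COLUMNS = ("left_term", "right_term", "N", "M", "n", "m", "er", "p_value", "q_value", "significant")


def write_pair_scores(table: PairScoreTable, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for s in table:
            fh.write(
                f"{s.pair.left}\t{s.pair.right}\t{s.counts.N}\t{s.counts.M}\t"
                f"{s.counts.n}\t{s.counts.m}\t{s.er:.10g}\t{s.p_value:.10g}\t"
                f"{s.q_value:.10g}\t{int(s.significant)}\n"
            )
    return len(table.scores)


# ---------------------------------------------------------------------------
# ER matrix (clustered heat-map data)
# ---------------------------------------------------------------------------

@dataclass
class ErMatrix:
    row_terms: list[str]
    col_terms: list[str]
    values: np.ndarray  # ER; 0 where the pair was never tested
    row_order: list[int]
    col_order: list[int]

    def ordered_values(self) -> np.ndarray:
        return self.values[np.ix_(self.row_order, self.col_order)]


def _leaf_order(matrix: np.ndarray, linkage: str, metric: str) -> list[int]:
    if matrix.shape[0] < 2:
        return list(range(matrix.shape[0]))
    Z = hierarchy.linkage(matrix, method=linkage, metric=metric)
    return list(hierarchy.leaves_list(Z))


def er_matrix(
    table: PairScoreTable,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ErMatrix:
    """Pivot a score table into a clustered source-term x target-term grid.

    Untested cells are 0.  Terms are pre-sorted lexicographically before
    clustering, which fixes tie-breaking and makes the leaf orders
    deterministic for a given table.
    """
    if not table.scores:
        raise ValueError("cannot build an ER matrix from an empty score table")
    row_terms = sorted({s.pair.left for s in table})
    col_terms = sorted({s.pair.right for s in table})
    ri = {t: i for i, t in enumerate(row_terms)}
    ci = {t: i for i, t in enumerate(col_terms)}
    values = np.zeros((len(row_terms), len(col_terms)))
    for s in table:
        values[ri[s.pair.left], ci[s.pair.right]] = s.er
    return ErMatrix(
        row_terms=row_terms,
        col_terms=col_terms,
        values=values,
        row_order=_leaf_order(values, linkage, metric),
        col_order=_leaf_order(values.T, linkage, metric),
    )


def write_er_matrix(matrix: ErMatrix, path: str, clustered: bool = True) -> None:
    """TSV matrix with header row/column, in clustered order by default."""
    rows = matrix.row_order if clustered else range(len(matrix.row_terms))
    cols = matrix.col_order if clustered else range(len(matrix.col_terms))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.col_terms[j] for j in cols) + "\n")
        for i in rows:
            vals = "\t".join(f"{matrix.values[i, j]:.10g}" for j in cols)
            fh.write(f"{matrix.row_terms[i]}\t{vals}\n")
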