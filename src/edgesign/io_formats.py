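"""Readers and writers for the plain-text formats the tool touches.

Annotation tables (two-column TSV or a GAF 2.x subset), interaction edge
lists (2-3 column TSV with an optional activation/inhibition label), and
the prediction output (summary TSV plus a per-interaction detail file).
All files are UTF-8, tab-delimited; lines starting with ``#`` are skipped
in TSV files and lines starting with ``!`` in GAF files.

Also implements the dataset-hygiene step used when assembling a test set:
deduplication of an edge list and exclusion of edges already present in a
training/known set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNKNOWN = "unknown"

LABELS = frozenset({ACTIVATION, INHIBITION})

NAMESPACES = ("go", "domain")


class FormatError(ValueError):
    """A malformed row in an input file (message names the line number)."""


def _check_protein_id(pid: str, path: str = "<memory>", lineno: int = 0) -> str:
    if not pid or any(c.isspace() for c in pid):
        raise FormatError(
            f"{path}:{lineno}: invalid protein identifier {pid!r} "
            "(must be non-empty, no whitespace)"
        )
    return pid


def _check_namespace(namespace: str) -> str:
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
    return namespace


@dataclass
class AnnotationCatalog:
    """Protein -> set of annotation term IDs for a single vocabulary.

    ``namespace`` is ``"go"`` (Gene Ontology terms) or ``"domain"``
    (e.g. Pfam accessions).  Proteins without annotations are simply
    absent from ``entries``.
    """

    namespace: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_namespace(self.namespace)

    def terms(self, protein: str) -> frozenset[str]:
        """Annotation set of ``protein`` (empty if unannotated)."""
        return frozenset(self.entries.get(protein, ()))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCatalog):
            return NotImplemented
        return self.namespace == other.namespace and self.entries == other.entries


@dataclass(frozen=True)
class InteractionRecord:
    """One directed interaction: ``source`` regulates ``target``."""

    source: str
    target: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        _check_protein_id(self.source)
        _check_protein_id(self.target)
        if self.label not in LABELS and self.label != UNKNOWN:
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def is_self_edge(self) -> bool:
        return self.source == self.target

    def key(self, directed: bool = True) -> tuple[str, str]:
        """Identity key; endpoints sorted when ``directed`` is False."""
        if directed or self.source <= self.target:
            return (self.source, self.target)
        return (self.target, self.source)


@dataclass
class InteractionSet:
    """Ordered list of interaction records with a provenance tag."""

    records: list[InteractionRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: str, comment: str):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(comment):
                continue
            yield lineno, line


def read_annotations(
    path: str,
    format: str = "tsv",
    namespace: str = "go",
    gaf_id_column: str = "symbol",
) -> AnnotationCatalog:
    """Read an annotation table into a catalog.

    Parameters
    ----------
    format
        ``"tsv"`` for a plain two-column ``protein<TAB>term`` file or
        ``"gaf"`` for a GAF 2.x file, of which only the object
        identifier (column 2 or 3, per ``gaf_id_column``) and the GO ID
        (column 5) are consumed; qualifiers, including ``NOT``, are
        ignored.
    gaf_id_column
        ``"symbol"`` (GAF column 3, DB Object Symbol) or ``"id"``
        (column 2, DB Object ID).

    Duplicate (protein, term) rows collapse under set semantics.
    """
    _check_namespace(namespace)
    if format not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {format!r}")
    entries: dict[str, set[str]] = {}
    comment = "!" if format == "gaf" else "#"
    for lineno, line in _data_lines(path, comment):
        cols = line.split("\t")
        if format == "tsv":
            if len(cols) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            protein, term = cols
        else:
            if len(cols) < 5:
                raise FormatError(
                    f"{path}:{lineno}: GAF row has {len(cols)} columns, need >= 5"
                )
            protein = cols[2] if gaf_id_column == "symbol" else cols[1]
            term = cols[4]
        protein = _check_protein_id(protein.strip(), path, lineno)
        term = term.strip()
        if not term:
            raise FormatError(f"{path}:{lineno}: empty term field")
        entries.setdefault(protein, set()).add(term)
    return AnnotationCatalog(namespace=namespace, entries=entries)


def write_annotations(catalog: AnnotationCatalog, path: str) -> int:
    """Write a catalog as sorted two-column TSV; returns row count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(catalog.entries):
            for term in sorted(catalog.entries[protein]):
                fh.write(f"{protein}\t{term}\n")
                n += 1
    return n


def read_interactions(path: str, labeled: bool = False, provenance: str = "") -> InteractionSet:
    """Read a 2-3 column TSV edge list (source, target[, label]).

    With ``labeled=True`` a third column holding ``activation`` or
    ``inhibition`` is required; without it any third column is still
    validated if present, and missing labels default to ``unknown``.
    """
    records: list[InteractionRecord] = []
    for lineno, line in _data_lines(path, "#"):
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}")
        if labeled and len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: labeled file requires a third column")
        source = _check_protein_id(cols[0].strip(), path, lineno)
        target = _check_protein_id(cols[1].strip(), path, lineno)
        label = UNKNOWN
        if len(cols) >= 3 and cols[2].strip():
            label = cols[2].strip()
            if label not in LABELS:
                raise FormatError(
                    f"{path}:{lineno}: unrecognized label {label!r} "
                    f"(expected {ACTIVATION!r} or {INHIBITION!r})"
                )
        records.append(InteractionRecord(source, target, label))
    return InteractionSet(records=records, provenance=provenance or os.path.basename(path))


def write_interactions(interactions: InteractionSet, path: str, labeled: bool = True) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in interactions:
            if labeled:
                fh.write(f"{rec.source}\t{rec.target}\t{rec.label}\n")
            else:
                fh.write(f"{rec.source}\t{rec.target}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# dataset hygiene
# ---------------------------------------------------------------------------

def deduplicate_and_exclude(
    candidates: InteractionSet,
    exclude: InteractionSet | None = None,
    directed: bool = True,
) -> InteractionSet:
    """Drop duplicate edges (first occurrence wins) and edges in ``exclude``.

    Keys are (source, target) tuples; with ``directed=False`` endpoints
    are sorted before comparison so A->B and B->A collide.  Idempotent.
    """
    excluded: set[tuple[str, str]] = set()
    if exclude is not None:
        excluded = {rec.key(directed) for rec in exclude}
    seen: set[tuple[str, str]] = set()
    kept: list[InteractionRecord] = []
    for rec in candidates:
        k = rec.key(directed)
        if k in seen or k in excluded:
            continue
        seen.add(k)
        kept.append(rec)
    return InteractionSet(records=kept, provenance=candidates.provenance)


# ---------------------------------------------------------------------------
# prediction output
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ("source", "target", "status", "label", "probability", "n_contributing_pairs")


def detail_path_for(path: str) -> str:
    """Sibling detail-file path for a prediction summary file."""
    base, ext = os.path.splitext(path)
    return f"{base}.details{ext or '.tsv'}"


def write_predictions(records: Sequence, path: str) -> int:
    """Write prediction records as TSV; returns the data-row count.

    ``records`` are pipeline ``PredictionRecord`` objects (duck-typed:
    ``interaction``, ``status``, ``label``, ``probability``,
    ``contributing_pairs`` attributes).  A sibling ``*.details.tsv``
    lists every contributing term pair with its ER and p-value.
    """
    detail_path = detail_path_for(path)
    n = 0
    with open(path, "w", encoding="utf-8") as fh, open(detail_path, "w", encoding="utf-8") as dh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        dh.write("source\ttarget\tleft_term\tright_term\ter\tp_value\n")
        for rec in records:
            inter = rec.interaction
            prob = "" if rec.probability is None else f"{rec.probability:.6f}"
            fh.write(
                f"{inter.source}\t{inter.target}\t{rec.status}\t{rec.label}\t"
                f"{prob}\t{len(rec.contributing_pairs)}\n"
            )
            for pair, er, p in rec.contributing_pairs:
                dh.write(
                    f"{inter.source}\t{inter.target}\t{pair.left}\t{pair.right}\t"
                    f"{er:.6g}\t{p:.6g}\n"
                )
            n += 1
    return n


def read_predictions(path: str) -> list[dict]:
    """Re-read a prediction summary TSV into a list of row dicts."""
    rows: list[dict] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path, "#"):
        cols = line.split("\t")
        if header is None:
            header = cols
            if tuple(header) != PREDICTION_COLUMNS:
                raise FormatError(f"{path}:{lineno}: unexpected header {header}")
            continue
        row = dict(zip(header, cols))
        row["probability"] = float(row["probability"]) if row["probability"] else None
        row["n_contributing_pairs"] = int(row["n_contributing_pairs"])
        rows.append(row)
    return rows
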