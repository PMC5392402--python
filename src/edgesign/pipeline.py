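"""End-to-end prediction flow and signed-network export.

For each query interaction the tool first consults a store of curated
regulations and, on a hit, emits the stored sign verbatim (status
``known``).  Otherwise the interaction is featurized against the
significant-pair index: if it contains no indexed pair the outcome is
``no_feature`` (the method's stated coverage limitation), else the
logistic model supplies a label and probability (status ``predicted``)
together with the contributing term pairs, their ERs and p-values.

Predicted/known edges can be exported as a SIF-style signed edge list
plus a node table with degrees, the shape downstream network viewers
consume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import enrichment, features as feat, model as model_mod
from .io_formats import (
    ACTIVATION,
    INHIBITION,
    LABELS,
    AnnotationCatalog,
    InteractionRecord,
    InteractionSet,
)

STATUS_KNOWN = "known"
STATUS_PREDICTED = "predicted"
STATUS_NO_FEATURE = "no_feature"
LABEL_NONE = "none"


@dataclass
class KnownRegulationStore:
    """Curated (source, target) -> sign lookup, consulted before the model."""

    directed: bool = True
    _map: dict[tuple[str, str], str] = field(default_factory=dict)
    lookups: int = 0
    hits: int = 0

    @classmethod
    def from_interactions(cls, interactions: InteractionSet, directed: bool = True):
        store = cls(directed=directed)
        for rec in interactions:
            if rec.label not in LABELS:
                raise ValueError(
                    f"known-store entry {rec.source}->{rec.target} lacks a sign label"
                )
            store._map.setdefault(rec.key(directed), rec.label)
        return store

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, interaction: InteractionRecord) -> str | None:
        self.lookups += 1
        label = self._map.get(interaction.key(self.directed))
        if label is not None:
            self.hits += 1
        return label


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome for one query interaction."""

    interaction: InteractionRecord
    status: str
    label: str
    probability: float | None = None
    contributing_pairs: tuple = ()

    def __post_init__(self) -> None:
        if self.status == STATUS_KNOWN:
            assert self.probability is None and not self.contributing_pairs
        elif self.status == STATUS_NO_FEATURE:
            assert self.label == LABEL_NONE and self.probability is None
        elif self.status == STATUS_PREDICTED:
            assert self.probability is not None and self.contributing_pairs
        else:
            raise ValueError(f"invalid status {self.status!r}")


def pairs_predict(
    interaction: InteractionRecord,
    store: KnownRegulationStore | None,
    model: model_mod.LogisticModel,
    catalog: AnnotationCatalog,
    index: feat.FeatureIndex,
    directed: bool = True,
) -> PredictionRecord:
    """Known-store lookup first; classifier only on a miss.

    The model is never consulted for stored interactions (the store's
    ``hits`` counter instruments this precedence).
    """
    if catalog.namespace != index.namespace or model.namespace != index.namespace:
        raise ValueError(
            f"namespace mismatch: catalog={catalog.namespace!r} "
            f"index={index.namespace!r} model={model.namespace!r}"
        )
    if store is not None:
        known = store.lookup(interaction)
        if known is not None:
            return PredictionRecord(interaction, STATUS_KNOWN, known)
    fv = feat.featurize(interaction, catalog, index, directed)
    if fv is feat.NO_FEATURE:
        return PredictionRecord(interaction, STATUS_NO_FEATURE, LABEL_NONE)
    p_act, _, label = model_mod.predict_proba(model, fv)
    contributing = tuple(
        (pair, index.er_lookup[pair], index.p_lookup.get(pair, float("nan")))
        for pair in sorted(index.pairs[i] for i, _ in fv.entries)
    )
    return PredictionRecord(
        interaction, STATUS_PREDICTED, label,
        probability=p_act, contributing_pairs=contributing,
    )


def run_batch(
    interactions: InteractionSet,
    store: KnownRegulationStore | None,
    model: model_mod.LogisticModel,
    catalog: AnnotationCatalog,
    index: feat.FeatureIndex,
    directed: bool = True,
    log=None,
) -> list[PredictionRecord]:
    """One record per input, input order preserved, deterministic."""
    records = [
        pairs_predict(rec, store, model, catalog, index, directed)
        for rec in interactions
    ]
    if log is not None:
        counts = status_counts(records)
        log(
            "predicted %d interactions: %d known, %d predicted, %d no_feature"
            % (len(records), counts[STATUS_KNOWN], counts[STATUS_PREDICTED],
               counts[STATUS_NO_FEATURE])
        )
    return records


def status_counts(records) -> dict[str, int]:
    counts = {STATUS_KNOWN: 0, STATUS_PREDICTED: 0, STATUS_NO_FEATURE: 0}
    for rec in records:
        counts[rec.status] += 1
    return counts


def coverage(records) -> float:
    """Fraction of inputs the method could sign (1 - no_feature rate)."""
    if not records:
        return 0.0
    return 1.0 - status_counts(records)[STATUS_NO_FEATURE] / len(records)


def export_network(records, path: str) -> int:
    """SIF edge list ``source<TAB>relation<TAB>target`` plus node table.

    ``no_feature`` records are excluded.  The sibling ``*.nodes.tsv``
    lists every node with its incident-edge degree (self-edges count
    once).  Returns the number of edges written.
    """
    base, ext = os.path.splitext(path)
    nodes_path = f"{base}.nodes{ext or '.tsv'}"
    degree: dict[str, int] = {}
    n_edges = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.status == STATUS_NO_FEATURE:
                continue
            inter = rec.interaction
            fh.write(f"{inter.source}\t{rec.label}\t{inter.target}\n")
            n_edges += 1
            degree[inter.source] = degree.get(inter.source, 0) + 1
            if inter.target != inter.source:
                degree[inter.target] = degree.get(inter.target, 0) + 1
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("node\tdegree\n")
        for node in sorted(degree):
            fh.write(f"{node}\t{degree[node]}\n")
    return n_edges


# ---------------------------------------------------------------------------
# leakage-safe cross-validation over raw interactions
# ---------------------------------------------------------------------------

def crossvalidate_interactions(
    interactions: InteractionSet,
    catalog: AnnotationCatalog,
    k: int = 5,
    penalty: str = "l1",
    lambda_: float | None = None,
    alpha: float = 0.05,
    correction: str = "bh",
    seed: int = 0,
    leaky_er: bool = False,
    directed: bool = True,
    stratified: bool = True,
    tol: float = 1e-6,
) -> model_mod.EvalReport:
    """k-fold CV that re-runs the whole scoring stack per training fold.

    By default ER scoring and the significant-pair index are recomputed
    from each fold's training interactions only, so no held-out label
    leaks into the features; ``leaky_er=True`` scores once on the
    pooled data instead.  Held-out interactions with no indexed pair
    (NO_FEATURE) are excluded from the metrics; their rate is reported
    as ``1 - coverage`` in the pooled block.
    """
    y = model_mod._encode_labels(interactions.labels())
    recs = np.array(interactions.records, dtype=object)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    pooled_index = None
    if leaky_er:
        table = enrichment.score_all_pairs(
            interactions, catalog, alpha, correction, directed=directed)
        pooled_index = feat.build_feature_index(table)

    fold_metrics = []
    pooled_true, pooled_pred = [], []
    n_no_feature = 0
    for tr, te in splitter.split(np.zeros(len(y)), y):
        if pooled_index is not None:
            index = pooled_index
        else:
            train_set = InteractionSet(records=list(recs[tr]))
            table = enrichment.score_all_pairs(
                train_set, catalog, alpha, correction, directed=directed)
            index = feat.build_feature_index(table)
        tr_vecs, tr_kept, _ = feat.featurize_many(recs[tr], catalog, index, directed)
        te_vecs, te_kept, te_dropped = feat.featurize_many(recs[te], catalog, index, directed)
        n_no_feature += len(te_dropped)
        if not tr_vecs or not te_vecs:
            fold_metrics.append({
                "n": 0, "accuracy": float("nan"),
                "precision_activation": float("nan"), "recall_activation": float("nan"),
                "precision_inhibition": float("nan"), "recall_inhibition": float("nan"),
            })
            continue
        lam = lambda_
        if lam is None:
            lam = model_mod.select_lambda(
                tr_vecs, [recs[tr][i].label for i in tr_kept], penalty, seed=seed)
        m = model_mod.train(
            tr_vecs, [recs[tr][i].label for i in tr_kept], penalty, lam,
            tol=tol, seed=seed, index=index)
        pred = model_mod._encode_labels(model_mod.predict_labels(m, te_vecs))
        true = y[te][te_kept]
        fold_metrics.append(model_mod._metrics(true, pred))
        pooled_true.append(true)
        pooled_pred.append(pred)
    if pooled_true:
        pooled = model_mod._metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    else:
        pooled = {"n": 0, "accuracy": float("nan")}
    pooled["coverage"] = 1.0 - n_no_feature / len(y)
    return model_mod.EvalReport(
        k=k, seed=seed, penalty=penalty, lambda_=lambda_,
        fold_metrics=fold_metrics, pooled=pooled,
        class_counts={
            ACTIVATION: int(np.sum(y == 1)),
            INHIBITION: int(np.sum(y == 0)),
        },
    )
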