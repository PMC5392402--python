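"""Synthetic annotation catalogs and labeled interaction sets.

The generator builds exactly the world the method assumes: proteins
carry random annotation sets in two vocabularies (GO-style term IDs and
Pfam-style domain accessions), a handful of "planted" term pairs carry
signed logit-scale effects, and each interaction's activation
probability is

    P(activation) = logistic(base_logit + sum of effects of the
                             planted pairs the interaction contains)

with the label drawn Bernoulli from that probability.  Defaults mimic
the shape of a multi-species curated training set: ~2000 interactions
with a roughly 4:1 activation:inhibition imbalance (base_logit =
log 4), 10 planted pairs with effects of magnitude 3 and alternating
sign.  Everything is reproducible from a single integer seed, and the
fixture bundle round-trips through the package's own readers, so the
full stack is testable with no database download.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .enrichment import TermPair, extract_term_pairs
from .io_formats import (
    ACTIVATION,
    INHIBITION,
    AnnotationCatalog,
    InteractionRecord,
    InteractionSet,
    read_annotations,
    read_interactions,
    write_annotations,
    write_interactions,
)

_DEFAULT_EFFECT_MAGNITUDE = 3.0

# Planted family-pair cells (source family, target family), in order of
# decreasing carrier mass under the default family prevalences.  The first
# five carry the activation effects, the next five the inhibition effects;
# the arrangement keeps every family's row- and column-wise expected sign
# mixture near-neutral, so a single protein's class is (almost)
# uninformative and only the class *pair* carries signal — the premise the
# scoring method rests on.  Remaining grid cells extend the list for
# configs that plant more than ten pairs.
_POS_CELLS = ((0, 0), (0, 1), (1, 0), (1, 1), (2, 2))
_NEG_CELLS = ((0, 4), (1, 2), (2, 3), (3, 1), (4, 0))


def _planted_cells(n: int, n_families: int) -> list[tuple[int, int]]:
    cells = list(_POS_CELLS + _NEG_CELLS)
    if n <= len(cells):
        return cells[:n]
    rest = [
        (i, j)
        for i in range(n_families)
        for j in range(n_families)
        if (i, j) not in set(cells)
    ]
    rest.sort(key=lambda ij: (ij[0] + ij[1], ij))
    cells += rest
    if n > len(cells):
        raise ValueError(f"cannot plant {n} pairs on a {n_families}x{n_families} family grid")
    return cells[:n]


def _default_effects(n: int, magnitude: float = _DEFAULT_EFFECT_MAGNITUDE):
    n_pos = min(n, len(_POS_CELLS))
    return tuple(magnitude if i < n_pos else -magnitude for i in range(n))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the package's stated world.

    Each annotated protein carries exactly one "family" term — its
    principal functional class (kinase-, phosphatase-, receptor-like),
    drawn with the skewed prevalences real proteomes show — plus a
    Poisson number of background terms, so the mean annotation count
    of an annotated protein is ``annotations_per_protein``.  An
    ``annotated_fraction`` of proteins is annotated at all; the rest
    exercise the no-feature path.  Planted pairs sit on family-pair
    grid cells in ``planted_namespace``; the other namespace has the
    same marginal structure but carries no signal.
    """

    n_proteins: int = 500
    vocab_size: int = 30
    n_families: int = 5
    family_prevalences: tuple = (0.30, 0.25, 0.20, 0.15, 0.10)
    annotations_per_protein: float = 3.0
    annotated_fraction: float = 0.9
    n_interactions: int = 2000
    n_planted_pairs: int = 10
    planted_effects: tuple = ()
    base_logit: float = math.log(4.0)  # ~4:1 activation:inhibition
    namespaces: tuple = ("go", "domain")
    planted_namespace: str = "go"
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.planted_effects:
            self.planted_effects = _default_effects(self.n_planted_pairs)
        self.planted_effects = tuple(float(e) for e in self.planted_effects)
        self.namespaces = tuple(self.namespaces)
        self.family_prevalences = tuple(float(p) for p in self.family_prevalences)
        if min(self.n_proteins, self.vocab_size, self.n_interactions) <= 0:
            raise ValueError("n_proteins, vocab_size, n_interactions must be positive")
        if self.n_planted_pairs < 0 or len(self.planted_effects) != self.n_planted_pairs:
            raise ValueError("planted_effects length must equal n_planted_pairs")
        if not (0.0 < self.annotated_fraction <= 1.0):
            raise ValueError("annotated_fraction must be in (0, 1]")
        if self.annotations_per_protein < 1.0:
            raise ValueError("annotations_per_protein must be >= 1")
        if self.planted_namespace not in self.namespaces:
            raise ValueError("planted_namespace must be one of namespaces")
        if len(self.family_prevalences) != self.n_families:
            raise ValueError("family_prevalences length must equal n_families")
        if abs(sum(self.family_prevalences) - 1.0) > 1e-9:
            raise ValueError("family_prevalences must sum to 1")
        if not (0 < self.n_families < self.vocab_size):
            raise ValueError("need 0 < n_families < vocab_size")
        _planted_cells(self.n_planted_pairs, self.n_families)  # raises if too many


@dataclass
class GroundTruth:
    """What the generator planted and what it realized."""

    planted_pairs: list[TermPair]
    planted_effects: list[float]
    true_labels: list[str]
    true_probabilities: list[float]
    class_counts: dict
    config: SimulationConfig = field(repr=False, default=None)

    def effect_of(self, pair: TermPair) -> float:
        return dict(zip(self.planted_pairs, self.planted_effects))[pair]


def _vocab(namespace: str, size: int) -> list[str]:
    if namespace == "go":
        return [f"GO:{i + 1:07d}" for i in range(size)]
    return [f"PF{i + 1:05d}" for i in range(size)]


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[dict[str, AnnotationCatalog], InteractionSet, GroundTruth]:
    """Draw catalogs (one per namespace), a labeled set and the truth."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]

    catalogs: dict[str, AnnotationCatalog] = {}
    for ns in cfg.namespaces:
        vocab = _vocab(ns, cfg.vocab_size)
        family_terms = vocab[: cfg.n_families]
        background = np.array(vocab[cfg.n_families :])
        entries: dict[str, set[str]] = {}
        annotated = rng.random(cfg.n_proteins) < cfg.annotated_fraction
        families = rng.choice(cfg.n_families, size=cfg.n_proteins, p=cfg.family_prevalences)
        n_background = rng.poisson(cfg.annotations_per_protein - 1.0, size=cfg.n_proteins)
        for i, prot in enumerate(proteins):
            if not annotated[i]:
                continue
            k = min(int(n_background[i]), len(background))
            terms = {family_terms[families[i]]}
            if k:
                terms |= set(rng.choice(background, size=k, replace=False))
            entries[prot] = terms
        catalogs[ns] = AnnotationCatalog(namespace=ns, entries=entries)

    family_terms = _vocab(cfg.planted_namespace, cfg.vocab_size)[: cfg.n_families]
    planted = [
        TermPair(family_terms[i], family_terms[j], cfg.planted_namespace)
        for i, j in _planted_cells(cfg.n_planted_pairs, cfg.n_families)
    ]
    effect_of = dict(zip(planted, cfg.planted_effects))

    planted_catalog = catalogs[cfg.planted_namespace]
    records: list[InteractionRecord] = []
    probs: list[float] = []
    labels: list[str] = []
    for _ in range(cfg.n_interactions):
        si = int(rng.integers(cfg.n_proteins))
        ti = int(rng.integers(cfg.n_proteins))
        while ti == si:
            ti = int(rng.integers(cfg.n_proteins))
        rec = InteractionRecord(proteins[si], proteins[ti])
        pairs = extract_term_pairs(rec, planted_catalog, directed=True)
        logit = cfg.base_logit + sum(effect_of.get(p, 0.0) for p in pairs)
        p_act = 1.0 / (1.0 + math.exp(-logit))
        label = ACTIVATION if rng.random() < p_act else INHIBITION
        records.append(InteractionRecord(rec.source, rec.target, label))
        probs.append(p_act)
        labels.append(label)

    truth = GroundTruth(
        planted_pairs=planted,
        planted_effects=list(cfg.planted_effects),
        true_labels=labels,
        true_probabilities=probs,
        class_counts={
            ACTIVATION: labels.count(ACTIVATION),
            INHIBITION: labels.count(INHIBITION),
        },
        config=cfg,
    )
    interactions = InteractionSet(records=records, provenance=f"synthetic(seed={cfg.seed})")
    return catalogs, interactions, truth


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def write_fixture_bundle(
    catalogs: dict[str, AnnotationCatalog],
    interactions: InteractionSet,
    truth: GroundTruth,
    directory: str,
) -> dict:
    """Write TSVs + manifest; returns the manifest dict.

    Files: one annotation TSV per namespace, the labeled interaction
    TSV, and a ground-truth TSV of planted pairs with effects.  The
    manifest records the config and seed, so the bundle can be
    regenerated byte-identically.
    """
    os.makedirs(directory, exist_ok=True)
    files: dict[str, str] = {}
    for ns, catalog in sorted(catalogs.items()):
        name = f"annotations_{ns}.tsv"
        write_annotations(catalog, os.path.join(directory, name))
        files[f"annotations_{ns}"] = name
    write_interactions(interactions, os.path.join(directory, "interactions.tsv"))
    files["interactions"] = "interactions.tsv"
    with open(os.path.join(directory, "ground_truth.tsv"), "w", encoding="utf-8") as fh:
        fh.write("left_term\tright_term\tnamespace\teffect\n")
        for pair, eff in zip(truth.planted_pairs, truth.planted_effects):
            fh.write(f"{pair.left}\t{pair.right}\t{pair.namespace}\t{eff:.10g}\n")
    files["ground_truth"] = "ground_truth.tsv"
    manifest = {
        "files": files,
        "config": dataclasses.asdict(truth.config),
        "seed": truth.config.seed,
        "class_counts": truth.class_counts,
    }
    with open(os.path.join(directory, MANIFEST_NAME), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_fixture_bundle(directory: str):
    """Load a bundle back: (catalogs, interactions, manifest)."""
    with open(os.path.join(directory, MANIFEST_NAME), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    catalogs: dict[str, AnnotationCatalog] = {}
    for key, name in manifest["files"].items():
        if key.startswith("annotations_"):
            ns = key.removeprefix("annotations_")
            catalogs[ns] = read_annotations(
                os.path.join(directory, name), format="tsv", namespace=ns)
    interactions = read_interactions(
        os.path.join(directory, manifest["files"]["interactions"]), labeled=True)
    return catalogs, interactions, manifest


def config_from_manifest(manifest: dict) -> SimulationConfig:
    return SimulationConfig(**manifest["config"])
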