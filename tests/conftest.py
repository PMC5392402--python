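"""Shared fixtures: hand-built toys and the default synthetic bundle."""

import warnings

import pytest

import edgesign as es

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def toy_catalog():
    return es.AnnotationCatalog(
        namespace="go",
        entries={
            "A": {"t1", "t2"},
            "B": {"t3"},
            "C": {"t1"},
            "D": {"t4"},
            # E unannotated
        },
    )


@pytest.fixture
def toy_interactions():
    mk = es.InteractionRecord
    return es.InteractionSet(
        records=[
            mk("A", "B", "activation"),
            mk("C", "B", "activation"),
            mk("A", "D", "activation"),
            mk("C", "D", "inhibition"),
        ],
        provenance="toy",
    )


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic world (seed 42): catalogs, interactions, truth."""
    return es.simulate_dataset(es.SimulationConfig())


@pytest.fixture(scope="session")
def fitted(bundle):
    """Score table, index, features and a trained L1 model on the bundle."""
    catalogs, interactions, truth = bundle
    catalog = catalogs["go"]
    table = es.score_all_pairs(interactions, catalog)
    index = es.build_feature_index(table)
    vectors, kept, dropped = es.featurize_many(interactions, catalog, index)
    labels = [interactions.records[i].label for i in kept]
    lam = es.select_lambda(vectors, labels, "l1", seed=0)
    model = es.train(vectors, labels, "l1", lam, seed=0, index=index)
    return {
        "catalog": catalog,
        "interactions": interactions,
        "truth": truth,
        "table": table,
        "index": index,
        "vectors": vectors,
        "kept": kept,
        "dropped": dropped,
        "labels": labels,
        "lambda": lam,
        "model": model,
    }
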