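import pandas as pd
import pytest

import biomon
from biomon.fixtures import (
    generate_community,
    generate_reference,
    generate_scores,
    generate_traits,
)


@pytest.fixture(scope="session")
def ref():
    return generate_reference(
        seed=0, order_names=["Ephemeroptera", "Plecoptera", "Trichoptera"]
    )


@pytest.fixture(scope="session")
def community(ref):
    return generate_community(ref, n_samples=5, seed=0)


@pytest.fixture(scope="session")
def agg(ref, community):
    tagged, _ = biomon.as_biomonitor(community, ref)
    return biomon.aggregate_taxa(tagged)


@pytest.fixture(scope="session")
def traits(ref):
    return generate_traits(ref, seed=0)


@pytest.fixture(scope="session")
def scores(ref):
    return {
        kind: generate_scores(ref, kind, seed=0)
        for kind in ("bmwp", "dehli", "whpt", "life", "psi", "epsi", "ibmr",
                     "eptd", "aliens")
    }


def make_agg(ref, rows: dict[str, list[float]], samples: list[str] | None = None):
    """Aggregated community from an explicit taxon -> abundances mapping."""
    first = next(iter(rows.values()))
    samples = samples or [f"s{i + 1}" for i in range(len(first))]
    cm = biomon.CommunityMatrix(pd.DataFrame(rows, index=samples).T)
    tagged, _ = biomon.as_biomonitor(cm, ref)
    return biomon.aggregate_taxa(tagged)


@pytest.fixture(scope="session")
def tiny_ref():
    """Hand-built 6-taxon reference with known lineages."""
    tree = {
        "Ephemeroptera": {
            "rank": "Order",
            "children": {
                "Baetidae": {
                    "rank": "Family",
                    "children": {
                        "Baetis": {
                            "rank": "Genus",
                            "children": {
                                "Baetis rhodani": {"rank": "Species", "children": {}}
                            },
                        },
                        "Cloeon": {"rank": "Genus", "children": {}},
                    },
                }
            },
        }
    }
    return biomon.ref_from_tree(tree)
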