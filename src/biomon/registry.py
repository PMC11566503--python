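"""The index registry: one enumerable inventory of every computable index.

Each entry names its category (diversity / biomonitoring / functional),
what it needs beyond the aggregated community (a score table, traits, a
trait space, ...), and the default score-table kind used when none is
supplied.  ``show_scores`` exposes the packaged default score tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import pandas as pd

from . import biotic, diversity, functional
from .biotic import ScoreTable
from .ranks import TAXA
from .taxonomy import ArgumentError


@dataclass(frozen=True)
class IndexEntry:
    name: str
    category: str  # diversity | biomonitoring | functional
    needs: str  # none | scores | aliens | traits | space | dist
    func: Callable
    score_kind: str | None = None  # default score-table kind for `needs=scores`


def _d(name):
    fn = diversity.DIVERSITY_INDICES[name]
    return lambda agg, tax_lev=TAXA, **kw: fn(agg, tax_lev)


REGISTRY: dict[str, IndexEntry] = {}


def _register(entry: IndexEntry) -> None:
    REGISTRY[entry.name] = entry


for _name in diversity.DIVERSITY_INDICES:
    _register(IndexEntry(_name, "diversity", "none", _d(_name)))

_register(IndexEntry("bmwp", "biomonitoring", "scores", biotic.bmwp, "bmwp"))
_register(IndexEntry("aspt", "biomonitoring", "scores", biotic.aspt, "bmwp"))
_register(IndexEntry("dehli", "biomonitoring", "scores", biotic.dehli, "dehli"))
_register(IndexEntry("whpt", "biomonitoring", "scores", biotic.whpt, "whpt"))
_register(IndexEntry("life", "biomonitoring", "scores", biotic.life, "life"))
_register(IndexEntry("psi", "biomonitoring", "scores", biotic.psi, "psi"))
_register(IndexEntry("epsi", "biomonitoring", "scores", biotic.epsi, "epsi"))
_register(IndexEntry("ibmr", "biomonitoring", "scores", biotic.ibmr, "ibmr"))
_register(IndexEntry("eptd", "biomonitoring", "scores", biotic.eptd, "eptd"))
_register(IndexEntry("ept", "biomonitoring", "none", biotic.ept))
_register(IndexEntry("igold", "biomonitoring", "none", biotic.igold))
_register(IndexEntry("bioco", "biomonitoring", "aliens", biotic.bioco, "aliens"))
# Flow-T is an instance of fuzzy_trait_ratio over flow-intermittency
# affinities; registered as its own index for the inventory.
_register(IndexEntry("flow_t", "biomonitoring", "traits", functional.flow_t))

_register(IndexEntry("f_rich", "functional", "space", functional.f_rich))
_register(IndexEntry("f_disp", "functional", "space", functional.f_disp))
_register(IndexEntry("f_eve", "functional", "space", functional.f_eve))
_register(IndexEntry("f_divs", "functional", "dist", functional.f_divs))
_register(IndexEntry("f_red", "functional", "dist", functional.f_red))
_register(IndexEntry("cwm", "functional", "traits", functional.cwm))
_register(IndexEntry("csi", "functional", "traits", functional.csi))
_register(
    IndexEntry("fuzzy_trait_ratio", "functional", "traits", functional.fuzzy_trait_ratio)
)


def list_indices() -> pd.DataFrame:
    rows = [
        {"name": e.name, "category": e.category, "needs": e.needs}
        for e in REGISTRY.values()
    ]
    return pd.DataFrame(rows).sort_values(["category", "name"]).reset_index(drop=True)


def get_index(name: str) -> IndexEntry:
    if name not in REGISTRY:
        raise ArgumentError(
            f"unknown index {name!r}; available: {sorted(REGISTRY)}"
        )
    return REGISTRY[name]


# ---------------------------------------------------------------------------
# Default score tables
# ---------------------------------------------------------------------------

#: index name -> default score-table kind
_SCORE_KIND = {
    e.name: e.score_kind for e in REGISTRY.values() if e.score_kind is not None
}


@lru_cache(maxsize=None)
def _default_scores(kind: str, origin: str) -> ScoreTable:
    from .fixtures import generate_reference, generate_scores

    try:
        seed = int(origin.removeprefix("synthetic-"))
    except ValueError:
        raise ArgumentError(
            f"unknown score-table origin {origin!r}; available: "
            f"['synthetic-<seed>'] (published national tables are "
            f"user-loadable, not redistributed)"
        ) from None
    ref = generate_reference(
        seed=seed, order_names=["Ephemeroptera", "Plecoptera", "Trichoptera"]
    )
    return generate_scores(ref, kind, seed=seed)


def show_scores(index: str, origin: str = "synthetic-0") -> ScoreTable:
    """Default :class:`ScoreTable` for an index (round-trips through the
    score CSV/JSON format).  Unknown names raise an error listing what is
    available."""
    if index not in _SCORE_KIND:
        raise ArgumentError(
            f"no default scores for {index!r}; available: "
            f"{sorted(_SCORE_KIND)}"
        )
    return _default_scores(_SCORE_KIND[index], origin)
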