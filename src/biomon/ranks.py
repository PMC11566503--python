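"""Ordered taxonomic rank list shared by every module.

``TAXA`` is not a true rank: it is the synthetic "finest available" column
that every reference row must fill.  Users may supply a custom ordered rank
list through :class:`biomon.config.Config`.
"""

from __future__ import annotations

from typing import Sequence

#: Fixed ordered rank list, coarsest to finest.
RANKS: tuple[str, ...] = (
    "Phylum",
    "Class",
    "Subclass",
    "Order",
    "Family",
    "Subfamily",
    "Tribus",
    "Genus",
    "Species",
    "Subspecies",
)

#: Name of the mixed finest-resolution pseudo-rank.
TAXA: str = "Taxa"

#: All reference-table columns, in order.
REF_COLUMNS: tuple[str, ...] = RANKS + (TAXA,)


def rank_index(rank: str, ranks: Sequence[str] = RANKS) -> int:
    """Position of *rank* in the ordered list (0 = coarsest).

    Raises ``KeyError`` for unknown ranks; ``TAXA`` is not accepted here
    because it has no fixed depth.
    """
    try:
        return list(ranks).index(rank)
    except ValueError:
        raise KeyError(f"unknown rank: {rank!r} (known: {list(ranks)})") from None


def is_finer(a: str, b: str, ranks: Sequence[str] = RANKS) -> bool:
    """True when rank *a* is strictly finer (deeper) than rank *b*."""
    return rank_index(a, ranks) > rank_index(b, ranks)
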