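"""Fuzzy-coded trait dataset management.

Trait rows live at arbitrary taxonomic ranks; :func:`assign_traits` links
each community taxon to every compatible trait row (same taxon, descendant
or ancestor) tagged with a signed rank offset, and the remaining functions
filter, average or sample among candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranks import TAXA, rank_index
from .taxonomy import AggregatedCommunity, ArgumentError, ValidationError


@dataclass
class TraitDataset:
    """Taxon x trait-modality table, fuzzy coded and partitioned in blocks.

    ``data``: DataFrame indexed by taxon name, modality columns.
    ``ranks``: Series taxon -> rank.  ``blocks``: trait -> modality columns.
    """

    data: pd.DataFrame
    ranks: pd.Series
    blocks: dict[str, list[str]]

    def __post_init__(self) -> None:
        assigned: set[str] = set()
        for trait, mods in self.blocks.items():
            missing = [m for m in mods if m not in self.data.columns]
            if missing:
                raise ValidationError(f"block {trait!r}: unknown modalities {missing}")
            overlap = assigned.intersection(mods)
            if overlap:
                raise ValidationError(f"modalities in several blocks: {sorted(overlap)}")
            assigned.update(mods)
        extra = [c for c in self.data.columns if c not in assigned]
        if extra:
            raise ValidationError(f"modalities outside any block: {extra}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate trait rows per taxon")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative trait affinities")
        self.data = self.data.astype(float)
        self.ranks = self.ranks.reindex(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def block_normalized(self) -> pd.DataFrame:
        """Affinities rescaled so each block of each row sums to 1
        (all-zero blocks stay 0)."""
        out = self.data.copy()
        for mods in self.blocks.values():
            s = out[mods].sum(axis=1)
            nz = s > 0
            out.loc[nz, mods] = out.loc[nz, mods].div(s[nz], axis=0)
        return out


@dataclass
class TraitAssignment:
    """Candidate trait rows per community taxon, with signed rank offsets
    (0 same taxon, + candidate finer, - candidate coarser)."""

    candidates: dict[str, list[tuple[str, int]]]
    taxon_ranks: dict[str, str]
    traits: TraitDataset
    unmatched: list[str] = field(default_factory=list)


def assign_traits(
    agg: AggregatedCommunity,
    traits: TraitDataset,
    tax_lev: str = TAXA,
) -> TraitAssignment:
    """Match community taxa at ``tax_lev`` to trait rows through the
    reference lineages.

    A trait row is a candidate for a community taxon when it is the same
    taxon (distance 0), a descendant (its lineage at the community taxon's
    rank equals that taxon; positive distance) or an ancestor (the taxon's
    lineage contains it at a coarser rank; negative distance).  Distances
    count occupied lineage steps, so a genus row under a family-level taxon
    is at +1 even though intermediate ranks exist in the full rank list.
    """
    ref = agg.reference
    table = agg.at(tax_lev).df
    ranks = list(ref.ranks)

    trait_lineages: dict[str, dict[str, str]] = {}
    for t in traits.taxa:
        lin = ref.lineage(t)
        if lin is not None:
            trait_lineages[t] = lin

    candidates: dict[str, list[tuple[str, int]]] = {}
    taxon_ranks: dict[str, str] = {}
    unmatched: list[str] = []
    for taxon in table.index:
        if tax_lev == TAXA:
            my_rank = ref.rank_of(taxon)
            if my_rank is None:
                unmatched.append(taxon)
                continue
        else:
            my_rank = tax_lev
        taxon_ranks[taxon] = my_rank
        my_idx = rank_index(my_rank, ranks)
        my_lin = ref.lineage(taxon)
        cands: list[tuple[str, int]] = []
        for t in traits.taxa:
            lin = trait_lineages.get(t)
            if lin is None:
                continue
            keys = list(lin)
            t_rank = keys[-1]
            t_idx = rank_index(t_rank, ranks)
            if t == taxon:
                cands.append((t, 0))
            elif t_idx > my_idx and lin.get(my_rank) == taxon:
                # descendant: steps within the candidate's occupied lineage
                cands.append((t, keys.index(t_rank) - keys.index(my_rank)))
            elif (
                t_idx < my_idx
                and my_lin is not None
                and my_lin.get(t_rank) == t
            ):
                # ancestor: steps within this taxon's occupied lineage
                mkeys = list(my_lin)
                cands.append((t, mkeys.index(t_rank) - mkeys.index(my_rank)))
        cands.sort(key=lambda cd: (abs(cd[1]), cd[1], cd[0]))
        if cands:
            candidates[taxon] = cands
        else:
            unmatched.append(taxon)
    return TraitAssignment(candidates, taxon_ranks, traits, unmatched)


def manage_traits(assign: TraitAssignment, method: str = "nearest") -> TraitAssignment:
    """Keep, per taxon, only candidates at minimal |distance| subject to the
    method's sign constraint (``nearest``, ``nearest_finer``,
    ``nearest_coarser``); ties at equal |distance| are all kept."""
    if method not in {"nearest", "nearest_finer", "nearest_coarser"}:
        raise ArgumentError(f"unknown manage_traits method {method!r}")
    out: dict[str, list[tuple[str, int]]] = {}
    dropped: list[str] = list(assign.unmatched)
    for taxon, cands in assign.candidates.items():
        if method == "nearest_finer":
            pool = [cd for cd in cands if cd[1] >= 0]
        elif method == "nearest_coarser":
            pool = [cd for cd in cands if cd[1] <= 0]
        else:
            pool = list(cands)
        if not pool:
            dropped.append(taxon)
            continue
        best = min(abs(d) for _, d in pool)
        out[taxon] = [cd for cd in pool if abs(cd[1]) == best]
    return TraitAssignment(out, dict(assign.taxon_ranks), assign.traits, dropped)


def average_traits(assign: TraitAssignment) -> TraitDataset:
    """One trait row per community taxon: arithmetic mean over candidates,
    renormalized within each fuzzy block to sum 1 (all-zero blocks kept 0)."""
    src = assign.traits
    rows, ranks = {}, {}
    for taxon, cands in assign.candidates.items():
        profile = src.data.loc[[c for c, _ in cands]].mean(axis=0)
        rows[taxon] = profile
        ranks[taxon] = assign.taxon_ranks.get(taxon, "")
    data = pd.DataFrame(rows).T
    if data.empty:
        data = pd.DataFrame(columns=src.data.columns)
    out = TraitDataset(
        data[src.data.columns], pd.Series(ranks, dtype=object), dict(src.blocks)
    )
    out.data = out.block_normalized()
    return out


def sample_traits(assign: TraitAssignment, seed: int | None = None) -> TraitDataset:
    """One uniformly drawn candidate row per taxon (seeded, reproducible).

    Profiles are taken verbatim from the chosen candidate row.
    """
    rng = np.random.default_rng(seed)
    src = assign.traits
    rows, ranks = {}, {}
    for taxon in sorted(assign.candidates):
        cands = assign.candidates[taxon]
        pick = cands[rng.integers(len(cands))][0]
        rows[taxon] = src.data.loc[pick]
        ranks[taxon] = assign.taxon_ranks.get(taxon, "")
    data = pd.DataFrame(rows).T
    if data.empty:
        data = pd.DataFrame(columns=src.data.columns)
    return TraitDataset(
        data[src.data.columns], pd.Series(ranks, dtype=object), dict(src.blocks)
    )


def zerodist_rm(
    agg: AggregatedCommunity,
    traits: TraitDataset,
    tax_lev: str = TAXA,
) -> tuple[AggregatedCommunity, dict[str, str]]:
    """Merge community taxa whose trait profiles are identical.

    Abundances are summed; the merged taxon keeps the alphabetically first
    name.  Returns the updated community (table at ``tax_lev`` replaced)
    and the merge map old name -> kept name.  Taxa without a trait row are
    left untouched.
    """
    table = agg.at(tax_lev).df
    norm = traits.block_normalized()
    profiles: dict[tuple, list[str]] = {}
    for taxon in table.index:
        if taxon not in norm.index:
            continue
        key = tuple(np.round(norm.loc[taxon].to_numpy(dtype=float), 12))
        profiles.setdefault(key, []).append(taxon)
    merge_map: dict[str, str] = {}
    for members in profiles.values():
        members = sorted(members)
        for m in members:
            merge_map[m] = members[0]
    new_index = [merge_map.get(t, t) for t in table.index]
    merged = table.groupby(new_index, sort=True).sum()
    merged.index.name = None
    from .taxonomy import CommunityMatrix  # local import avoids cycle at load

    new_table = CommunityMatrix(merged, agg.occurrence)
    per_rank = dict(agg.per_rank)
    taxa_table = agg.taxa_table
    if tax_lev == TAXA:
        taxa_table = new_table
    else:
        per_rank[tax_lev] = new_table
    return (
        AggregatedCommunity(
            per_rank, taxa_table, agg.reference, agg.match_report,
            agg.samples, agg.occurrence,
        ),
        merge_map,
    )


def add_bias_to_traits(
    traits: TraitDataset,
    magnitude: float = 1e-6,
    seed: int | None = None,
) -> TraitDataset:
    """Add independent uniform(0, magnitude) noise to every modality value
    so that no two rows stay identical.

    If duplicates survive, the magnitude is doubled and redrawn (up to 3
    retries) before erroring.
    """
    rng = np.random.default_rng(seed)
    mag = float(magnitude)
    for _ in range(4):
        noise = rng.uniform(0.0, mag, size=traits.data.shape)
        data = traits.data + noise
        if not data.duplicated().any():
            return TraitDataset(data, traits.ranks.copy(), dict(traits.blocks))
        mag *= 2.0
    raise ArgumentError("could not break trait ties by adding bias")
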