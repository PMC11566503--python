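"""Reference-dataset validation, community/reference name matching and
hierarchical abundance aggregation.

The central objects are :class:`ReferenceDataset` (one row per terminal
taxon, one column per rank plus the ``Taxa`` column holding the finest
non-empty rank value) and :class:`AggregatedCommunity` (one abundance table
per rank, derived from a single mixed-resolution community table).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._strdist import damerau_levenshtein
from .ranks import RANKS, REF_COLUMNS, TAXA, rank_index


class BiomonError(Exception):
    """Base class for user-facing validation/argument errors."""


class ValidationError(BiomonError):
    pass


class ArgumentError(BiomonError):
    pass


# ---------------------------------------------------------------------------
# Reference dataset
# ---------------------------------------------------------------------------


@dataclass
class ReferenceDataset:
    """Table mapping every terminal taxon to its full ranked lineage.

    ``df`` has the columns of :data:`biomon.ranks.REF_COLUMNS`; empty string
    means "rank not assigned".  The ``Taxa`` column is the finest non-empty
    rank value of each row and must be unique.
    """

    df: pd.DataFrame
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        cols = list(self.ranks) + [TAXA]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValidationError(f"reference table missing columns: {missing}")
        self.df = self.df[cols].fillna("").astype(str).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list[str]:
        return list(self.df[TAXA])

    def lineage(self, taxon: str) -> dict[str, str] | None:
        """Full rank -> value mapping for a terminal taxon (None if absent)."""
        hit = self.df[self.df[TAXA] == taxon]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return {r: row[r] for r in self.ranks if row[r]}

    def rank_of(self, taxon: str) -> str | None:
        """Actual rank of a terminal taxon (finest non-empty rank)."""
        lin = self.lineage(taxon)
        if lin is None:
            return None
        return list(lin)[-1]

    def validate(self) -> list[str]:
        return validate_reference(self)


def validate_reference(ref: ReferenceDataset) -> list[str]:
    """Return a list of human-readable violations; empty iff valid.

    Checks: unique non-empty ``Taxa``; ``Taxa`` equals the finest non-empty
    rank of its row; lineage consistency (rows sharing a value at rank r
    share all coarser values).
    """
    violations: list[str] = []
    df = ref.df
    empties = df.index[df[TAXA] == ""].tolist()
    for i in empties:
        violations.append(f"row {i}: empty Taxa value")
    dup = df[TAXA][df[TAXA].duplicated(keep=False) & (df[TAXA] != "")]
    for name in sorted(dup.unique()):
        violations.append(f"duplicate Taxa value: {name!r}")
    for i, row in df.iterrows():
        finest = ""
        for r in ref.ranks:
            if row[r]:
                finest = row[r]
        if row[TAXA] and finest and row[TAXA] != finest:
            violations.append(
                f"row {i}: Taxa={row[TAXA]!r} is not the finest non-empty "
                f"rank value ({finest!r})"
            )
    # lineage consistency: value at rank r determines all coarser values
    for ri, r in enumerate(ref.ranks):
        sub = df[df[r] != ""]
        if sub.empty:
            continue
        coarser = list(ref.ranks[:ri])
        if not coarser:
            continue
        grouped = sub.groupby(r)[coarser].nunique()
        bad = grouped[(grouped > 1).any(axis=1)]
        for name in bad.index:
            violations.append(
                f"inconsistent lineage: {r}={name!r} has multiple parent "
                f"lineages"
            )
    return violations


def ref_from_tree(
    tree: Mapping[str, Mapping], ranks: Sequence[str] = RANKS
) -> ReferenceDataset:
    """Build a reference dataset from a nested taxonomic tree.

    ``tree`` maps node name -> ``{"rank": <rank>, "children": {...}}``.
    Every node (internal or leaf) becomes one terminal-taxon row whose
    lineage is filled from its ancestors.

    Raises :class:`ArgumentError` for unknown ranks or when a child's rank
    is not strictly finer than its parent's.
    """
    rows: list[dict[str, str]] = []

    def walk(name: str, node: Mapping, lineage: dict[str, str], parent_rank: str | None):
        rank = node.get("rank")
        if rank not in ranks:
            raise ArgumentError(f"unknown rank {rank!r} for node {name!r}")
        if parent_rank is not None and rank_index(rank, ranks) <= rank_index(
            parent_rank, ranks
        ):
            raise ArgumentError(
                f"rank order violated: {name!r} ({rank}) under rank {parent_rank}"
            )
        lineage = dict(lineage)
        lineage[rank] = name
        row = {r: lineage.get(r, "") for r in ranks}
        row[TAXA] = name
        rows.append(row)
        for child, cnode in node.get("children", {}).items():
            walk(child, cnode, lineage, rank)

    for name, node in tree.items():
        walk(name, node, {}, None)
    df = pd.DataFrame(rows, columns=list(ranks) + [TAXA])
    ref = ReferenceDataset(df, tuple(ranks))
    problems = validate_reference(ref)
    if problems:
        raise ValidationError("; ".join(problems))
    return ref


# ---------------------------------------------------------------------------
# Community matrix
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Taxa x samples abundance (or occurrence) table."""

    df: pd.DataFrame  # index: taxon names, columns: samples, float values
    occurrence: bool = False

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = sorted(set(self.df.index[self.df.index.duplicated()]))
            raise ValidationError(f"duplicate taxon names: {dups}")
        if self.df.shape[1] < 1:
            raise ValidationError("community must have at least one sample")
        vals = self.df.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValidationError("negative abundances are not allowed")
        self.df = self.df.astype(float)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchReport:
    """Outcome of matching input names against the reference."""

    matched: dict[str, str]
    unmatched: list[str]
    suggestions: dict[str, list[tuple[str, int]]]
    corrections: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "matched": self.matched,
                "unmatched": self.unmatched,
                "suggestions": {
                    k: [{"candidate": c, "distance": d} for c, d in v]
                    for k, v in self.suggestions.items()
                },
                "corrections": self.corrections,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MatchReport":
        obj = json.loads(text)
        return cls(
            matched=obj["matched"],
            unmatched=obj["unmatched"],
            suggestions={
                k: [(e["candidate"], e["distance"]) for e in v]
                for k, v in obj["suggestions"].items()
            },
            corrections=obj.get("corrections", {}),
        )


@dataclass
class TaggedCommunity:
    """Community joined to reference lineages (output of as_biomonitor)."""

    df: pd.DataFrame  # columns: REF_COLUMNS + sample columns
    samples: list[str]
    reference: ReferenceDataset
    report: MatchReport
    occurrence: bool = False


def _norm(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def as_biomonitor(
    community: CommunityMatrix,
    ref: ReferenceDataset,
    correct_names: bool = False,
    suggestion_cutoff: int = 2,
    confirm: Callable[[str, list[tuple[str, int]]], str | None] | None = None,
    force: bool = False,
) -> tuple[TaggedCommunity, MatchReport]:
    """Match community taxon names against the reference and join lineages.

    Matching is exact (case-insensitive, whitespace-trimmed).  Names that do
    not match are excluded from the joined table and reported with ranked
    suggestions: all reference taxa within ``suggestion_cutoff``
    Damerau-Levenshtein distance, sorted by (distance, name).

    Fuzzy matching never silently corrects.  With ``correct_names`` set, a
    suggestion is applied only when confirmed by the ``confirm`` callback or
    when ``force`` is set (then the single best suggestion is taken; ties at
    minimal distance are left uncorrected).
    """
    lookup = {_norm(t): t for t in ref.taxa}
    matched: dict[str, str] = {}
    unmatched: list[str] = []
    suggestions: dict[str, list[tuple[str, int]]] = {}
    corrections: dict[str, str] = {}

    for name in community.taxa:
        key = _norm(name)
        if key in lookup:
            matched[name] = lookup[key]
            continue
        cands = []
        for t in ref.taxa:
            d = damerau_levenshtein(key, _norm(t))
            if d <= suggestion_cutoff:
                cands.append((t, d))
        cands.sort(key=lambda cd: (cd[1], cd[0]))
        applied = None
        if correct_names and cands:
            if confirm is not None:
                choice = confirm(name, cands)
                if choice is not None:
                    applied = choice
            elif force:
                best_d = cands[0][1]
                ties = [c for c, d in cands if d == best_d]
                if len(ties) == 1:
                    applied = ties[0]
        if applied is not None:
            matched[name] = applied
            corrections[name] = applied
        else:
            unmatched.append(name)
            suggestions[name] = cands

    report = MatchReport(matched, unmatched, suggestions, corrections)
    if not matched:
        warnings.warn("no taxon name matched the reference", stacklevel=2)

    lin = ref.df.set_index(TAXA)
    rows = []
    for name, taxon in matched.items():
        row = lin.loc[taxon].to_dict()
        row[TAXA] = taxon
        for s in community.samples:
            row[s] = community.df.loc[name, s]
        rows.append(row)
    cols = list(REF_COLUMNS) + community.samples
    if rows:
        joined = pd.DataFrame(rows, columns=cols)
        # duplicate targets (two input spellings corrected to one taxon): sum
        joined = (
            joined.groupby(list(REF_COLUMNS), as_index=False, sort=False)[
                community.samples
            ]
            .sum()
        )[cols]
    else:
        joined = pd.DataFrame(columns=cols)
    tagged = TaggedCommunity(
        joined, community.samples, ref, report, community.occurrence
    )
    return tagged, report


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregatedCommunity:
    """Per-rank abundance tables derived from one mixed-resolution table."""

    per_rank: dict[str, CommunityMatrix]
    taxa_table: CommunityMatrix
    reference: ReferenceDataset
    match_report: MatchReport
    samples: list[str]
    occurrence: bool = False

    def at(self, tax_lev: str) -> CommunityMatrix:
        if tax_lev == TAXA:
            return self.taxa_table
        if tax_lev not in self.per_rank:
            raise ArgumentError(
                f"no data at rank {tax_lev!r}; available: "
                f"{[TAXA] + list(self.per_rank)}"
            )
        return self.per_rank[tax_lev]

    @property
    def available_ranks(self) -> list[str]:
        return list(self.per_rank) + [TAXA]


def aggregate_taxa(tagged: TaggedCommunity) -> AggregatedCommunity:
    """Sum abundances to every rank that has at least one assigned value.

    Input taxa whose lineage is empty at a rank are omitted from that rank's
    table (never pooled into a pseudo-taxon), so per-rank column totals are
    <= the Taxa-level totals.
    """
    df = tagged.df
    samples = tagged.samples
    per_rank: dict[str, CommunityMatrix] = {}
    for r in tagged.reference.ranks:
        if df.empty:
            continue
        sub = df[df[r] != ""]
        if sub.empty:
            continue
        table = sub.groupby(r, sort=True)[samples].sum()
        table.index.name = None
        per_rank[r] = CommunityMatrix(table, tagged.occurrence)
    if df.empty:
        taxa_df = pd.DataFrame(
            np.empty((0, len(samples))), columns=samples
        )
    else:
        taxa_df = df.set_index(TAXA)[samples].astype(float)
        taxa_df.index.name = None
    taxa_table = CommunityMatrix(taxa_df, tagged.occurrence)
    return AggregatedCommunity(
        per_rank, taxa_table, tagged.reference, tagged.report, samples,
        tagged.occurrence,
    )


def get_taxa_abundance(
    agg: AggregatedCommunity, taxa: Iterable[str], tax_lev: str = TAXA
) -> pd.Series:
    """Per-sample summed abundance of the named taxa at ``tax_lev``.

    Unknown names warn and contribute zero; an empty list is an error.
    """
    names = list(taxa)
    if not names:
        raise ArgumentError("taxa list must not be empty")
    table = agg.at(tax_lev).df
    total = pd.Series(0.0, index=agg.samples)
    for name in names:
        if name in table.index:
            total += table.loc[name]
        else:
            warnings.warn(
                f"taxon {name!r} not found at rank {tax_lev!r}", stacklevel=2
            )
    return total


def get_taxa_richness(
    agg: AggregatedCommunity,
    taxa: Iterable[str],
    parent_rank: str,
    count_rank: str,
) -> pd.Series:
    """Per-sample count of present ``count_rank`` taxa descending from the
    named parents at ``parent_rank``."""
    names = list(taxa)
    if not names:
        raise ArgumentError("taxa list must not be empty")
    ranks = agg.reference.ranks
    if count_rank != TAXA and rank_index(count_rank, ranks) <= rank_index(
        parent_rank, ranks
    ):
        raise ArgumentError(
            f"count_rank {count_rank!r} must be finer than parent_rank "
            f"{parent_rank!r}"
        )
    ref = agg.reference.df
    descendants = set(
        ref.loc[ref[parent_rank].isin(names), count_rank].replace("", np.nan).dropna()
    )
    table = agg.at(count_rank).df
    present = table.loc[table.index.isin(descendants)] > 0
    return present.sum(axis=0).astype(float).reindex(agg.samples, fill_value=0.0)
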