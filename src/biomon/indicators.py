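"""Indicator-taxon analysis (IndVal with permutation test) and the three
plot-ready data structures: Sankey links of indicator taxa, prevalence of a
rank within an upper rank, and cluster-ordered composition barplot data.

No graphics are rendered; every structure serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, fcluster
from scipy.spatial.distance import pdist

from .ranks import TAXA
from .taxonomy import AggregatedCommunity, ArgumentError, CommunityMatrix


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------


def _indval_matrix(
    abund: np.ndarray, labels: np.ndarray, groups: list, corrected: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and IndVal matrices (taxa x groups).

    With ``corrected`` (Dufrene-Legendre), specificity uses group *mean*
    abundances, removing group-size bias; otherwise group totals.
    """
    n_taxa = abund.shape[0]
    n_groups = len(groups)
    a_num = np.zeros((n_taxa, n_groups))
    b = np.zeros((n_taxa, n_groups))
    for gi, g in enumerate(groups):
        cols = labels == g
        block = abund[:, cols]
        a_num[:, gi] = block.mean(axis=1) if corrected else block.sum(axis=1)
        b[:, gi] = (block > 0).mean(axis=1)
    denom = a_num.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, a_num / denom, 0.0)
    return a, b, a * b * 100.0


@dataclass
class IndicatorResult:
    """Per (taxon, group) specificity A, fidelity B, IndVal and the
    permutation p-value (computed cell-wise against permuted labels)."""

    table: pd.DataFrame  # columns: taxon, group, A, B, indval, p
    n_perm: int
    seed: int | None

    def best_groups(self) -> pd.DataFrame:
        """One row per taxon: the group with the highest IndVal."""
        idx = self.table.groupby("taxon")["indval"].idxmax()
        return self.table.loc[idx].reset_index(drop=True)


def indval(
    community: CommunityMatrix,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    corrected: bool = True,
) -> IndicatorResult:
    """Indicator value analysis with a permutation test on group labels.

    p = (1 + #{permuted IndVal >= observed}) / (1 + n_perm) per cell.
    """
    labels = pd.Series(groups).reindex(community.samples)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ArgumentError(f"samples without group label: {missing}")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ArgumentError("indval requires at least two groups")
    abund = community.df.to_numpy(dtype=float)
    lab = labels.to_numpy()
    a, b, iv = _indval_matrix(abund, lab, uniq, corrected)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(iv)
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        _, _, ivp = _indval_matrix(abund, perm, uniq, corrected)
        exceed += ivp >= iv - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for ti, taxon in enumerate(community.taxa):
        for gi, g in enumerate(uniq):
            rows.append(
                {
                    "taxon": taxon,
                    "group": g,
                    "A": a[ti, gi],
                    "B": b[ti, gi],
                    "indval": iv[ti, gi],
                    "p": p[ti, gi],
                }
            )
    return IndicatorResult(pd.DataFrame(rows), n_perm, seed)


# ---------------------------------------------------------------------------
# Clustering helpers
# ---------------------------------------------------------------------------


def _sample_linkage(table: pd.DataFrame):
    """Average-linkage clustering of samples on Bray-Curtis distances."""
    x = table.T.to_numpy(dtype=float)
    if x.shape[0] < 2:
        return None
    d = pdist(x, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)
    return linkage(d, method="average")


def cluster_groups(
    agg: AggregatedCommunity, k: int, tax_lev: str = TAXA
) -> dict[str, str]:
    """Group labels from hierarchical clustering (Bray-Curtis, average
    linkage) cut at k clusters."""
    table = agg.at(tax_lev).df
    z = _sample_linkage(table)
    if z is None:
        raise ArgumentError("clustering needs at least two samples")
    assign = fcluster(z, t=k, criterion="maxclust")
    return {s: f"cluster{c}" for s, c in zip(table.columns, assign)}


# ---------------------------------------------------------------------------
# Plot-data structures
# ---------------------------------------------------------------------------


@dataclass
class SankeyData:
    nodes: list[str]
    links: list[dict] = field(default_factory=list)  # {source, target, weight}

    def validate(self) -> None:
        node_set = set(self.nodes)
        for link in self.links:
            if link["source"] not in node_set or link["target"] not in node_set:
                raise ArgumentError(f"link endpoint missing from nodes: {link}")
            if link["weight"] < 0:
                raise ArgumentError("negative link weight")

    def to_json(self) -> str:
        return json.dumps(
            {"nodes": self.nodes, "links": self.links}, indent=2, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "SankeyData":
        obj = json.loads(text)
        return cls(nodes=obj["nodes"], links=obj["links"])


def plot_indicator_taxa_data(
    agg: AggregatedCommunity,
    groups: dict[str, str] | None = None,
    cluster_k: int | None = None,
    ranks: tuple[str, str] = ("Order", "Family"),
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int | None = None,
) -> tuple[SankeyData, IndicatorResult]:
    """Sankey structure linking upper-rank taxa -> significant indicator
    taxa at the finer rank -> their best group.

    Groups come either from the caller or from hierarchical clustering of
    samples (``cluster_k``).  Only taxa whose best-group IndVal has
    p <= alpha are kept; link weights are abundance shares.
    """
    upper_rank, fine_rank = ranks
    if groups is None:
        if cluster_k is None:
            raise ArgumentError("provide either groups or cluster_k")
        groups = cluster_groups(agg, cluster_k, fine_rank)
    result = indval(agg.at(fine_rank), groups, n_perm=n_perm, seed=seed)
    best = result.best_groups()
    sig = best[best["p"] <= alpha]

    ref = agg.reference.df
    key = TAXA if fine_rank == TAXA else fine_rank
    parent_of = {}
    for name in sig["taxon"]:
        rows = ref[ref[key] == name]
        parents = rows[upper_rank].replace("", np.nan).dropna().unique()
        parent_of[name] = parents[0] if len(parents) else None

    table = agg.at(fine_rank).df
    total = float(table.to_numpy().sum())
    nodes: list[str] = []
    links: list[dict] = []

    def add_node(n: str) -> None:
        if n not in nodes:
            nodes.append(n)

    label_series = pd.Series(groups).reindex(table.columns)
    for _, row in sig.iterrows():
        taxon, group = row["taxon"], row["group"]
        parent = parent_of.get(taxon)
        share = float(table.loc[taxon].sum()) / total if total > 0 else 0.0
        add_node(taxon)
        if parent is not None:
            add_node(parent)
            links.append({"source": parent, "target": taxon, "weight": share})
        add_node(str(group))
        in_group = float(
            table.loc[taxon, label_series[label_series == group].index].sum()
        )
        gshare = in_group / total if total > 0 else 0.0
        links.append({"source": taxon, "target": str(group), "weight": gshare})
    data = SankeyData(nodes, links)
    data.validate()
    return data, result


def prevalence_data(
    agg: AggregatedCommunity, rank: str = "Family", upper_rank: str = "Order"
) -> pd.DataFrame:
    """Counts and shares of ``rank`` taxa within each ``upper_rank`` taxon
    present in the community (shares sum to 1 over upper taxa)."""
    table = agg.at(rank).df
    present = table.index[(table > 0).any(axis=1)]
    if len(present) == 0:
        return pd.DataFrame(columns=["upper", "count", "share"])
    ref = agg.reference.df
    key = TAXA if rank == TAXA else rank
    parents = []
    for name in present:
        rows = ref[ref[key] == name]
        vals = rows[upper_rank].replace("", np.nan).dropna().unique()
        if len(vals):
            parents.append((vals[0], name))
    counts = pd.Series([p for p, _ in parents]).value_counts().sort_index()
    out = pd.DataFrame(
        {"upper": counts.index, "count": counts.to_numpy()}
    )
    out["share"] = out["count"] / out["count"].sum()
    return out


def composition_barplot_data(
    agg: AggregatedCommunity,
    rank: str = TAXA,
    cluster: bool = True,
) -> pd.DataFrame:
    """Per-sample taxon proportions (columns sum to 1) with samples ordered
    by the leaf order of a Bray-Curtis average-linkage dendrogram."""
    table = agg.at(rank).df
    totals = table.sum(axis=0)
    props = table.div(totals.where(totals > 0), axis=1)
    order = list(table.columns)
    if cluster and len(order) > 1:
        z = _sample_linkage(table)
        order = [table.columns[i] for i in leaves_list(z)]
    return props[order]
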