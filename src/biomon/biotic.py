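"""Sensitivity-score biomonitoring indices.

All indices share one machinery: a :class:`ScoreTable` assigns per-taxon
information (scalar scores, abundance-class score vectors, group labels,
weights, ...), the community is read at the score table's rank, and every
present taxon is either *used* (contributing a numerator ``score`` and
optionally a denominator ``weight``) or *excluded* with a reason.  The
index value is ``scale * transform(sum score, sum weight)``, which makes
every value recomputable from its trace alone
(:func:`recompute_from_trace`).
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ranks import TAXA
from .taxonomy import (
    AggregatedCommunity,
    ArgumentError,
    get_taxa_richness,
)

#: default pollution-sensitive insect orders for EPT-type metrics
EPT_ORDERS = ("Ephemeroptera", "Plecoptera", "Trichoptera")

#: default tolerant groups for the 1-GOLD metric (name -> rank it lives at)
GOLD_GROUPS = {"Gastropoda": "Class", "Oligochaeta": "Subclass", "Diptera": "Order"}

#: default ordinal biocontamination class thresholds (applied to ACI and RCI)
SBCI_THRESHOLDS = (0.0, 0.01, 0.1, 0.2, 0.5)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceClassRule:
    """Log-10 style abundance classes: class(n) for n in class k iff
    breakpoints[k-2] <= n < breakpoints[k-1] (1-based); 0 -> absent."""

    breakpoints: tuple[float, ...] = (10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        bp = tuple(self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or (bp and bp[0] <= 0):
            raise ArgumentError("breakpoints must be strictly ascending and positive")

    @property
    def n_classes(self) -> int:
        return len(self.breakpoints) + 1

    def class_of(self, n: float) -> int:
        """1-based abundance class; 0 for absent (n <= 0)."""
        if n <= 0:
            return 0
        return 1 + bisect.bisect_right(list(self.breakpoints), n)


@dataclass
class ScoreTable:
    """Taxon -> score information for one biotic index.

    ``kind`` selects the payload stored per taxon in ``entries``:

    - ``scalar``  : float score (BMWP/ASPT/DEHLI)
    - ``classes`` : tuple of per-abundance-class scores (WHPT)
    - ``group``   : group label, scored via ``group_scores`` (LIFE/PSI)
    - ``weight``  : float weight, with ``sensitive_taxa`` (EPSI)
    - ``cs_e``    : (sensitivity score, stenoecy coefficient) (IBMR)
    - ``members`` : membership only (EPTD family list, alien lists)
    """

    index: str
    rank: str
    kind: str
    entries: dict[str, object]
    class_rule: AbundanceClassRule | None = None
    group_scores: pd.DataFrame | None = None  # groups x classes
    presence_scores: dict[str, float] = field(default_factory=dict)
    sensitive_groups: tuple[str, ...] = ()
    sensitive_taxa: tuple[str, ...] = ()
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    origin: str = "synthetic"

    def validate(self) -> list[str]:
        problems = []
        for name, val in self.entries.items():
            if self.kind in {"scalar", "weight"} and not np.isfinite(float(val)):
                problems.append(f"non-finite score for {name!r}")
            if self.kind == "classes":
                if self.class_rule is None:
                    problems.append("classes kind requires a class_rule")
                    break
                if len(val) != self.class_rule.n_classes:
                    problems.append(
                        f"class-score vector length mismatch for {name!r}"
                    )
        if self.kind == "group" and self.group_scores is None:
            problems.append("group kind requires group_scores")
        for comp, members in self.composites.items():
            for m in members:
                if m not in self.entries and comp not in self.entries:
                    problems.append(f"composite member {m!r} unresolvable")
        return problems

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, val in self.entries.items():
            row: dict[str, object] = {"taxon": name, "rank": self.rank}
            if self.kind == "scalar":
                row["score"] = float(val)
            elif self.kind == "classes":
                for k, v in enumerate(val, 1):
                    row[f"score_class{k}"] = float(v)
                if name in self.presence_scores:
                    row["score_presence"] = self.presence_scores[name]
            elif self.kind == "group":
                row["group"] = val
            elif self.kind == "weight":
                row["weight"] = float(val)
                row["sensitive"] = int(name in self.sensitive_taxa)
            elif self.kind == "cs_e":
                row["cs"], row["e"] = float(val[0]), float(val[1])
            elif self.kind == "members":
                row["member"] = 1
            rows.append(row)
        return pd.DataFrame(rows)

    def meta_dict(self) -> dict:
        return {
            "index": self.index,
            "rank": self.rank,
            "kind": self.kind,
            "origin": self.origin,
            "class_rule": list(self.class_rule.breakpoints)
            if self.class_rule
            else None,
            "group_scores": (
                {
                    "groups": list(self.group_scores.index),
                    "classes": [str(c) for c in self.group_scores.columns],
                    "values": self.group_scores.to_numpy().tolist(),
                }
                if self.group_scores is not None
                else None
            ),
            "sensitive_groups": list(self.sensitive_groups),
            "composites": {k: list(v) for k, v in self.composites.items()},
        }

    def to_csv(self, path: str | Path) -> None:
        """Write the table CSV plus a ``.json`` metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps(self.meta_dict(), indent=2, sort_keys=True)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict) -> "ScoreTable":
        kind = meta["kind"]
        entries: dict[str, object] = {}
        presence: dict[str, float] = {}
        sensitive: list[str] = []
        for _, row in df.iterrows():
            name = row["taxon"]
            if kind == "scalar":
                entries[name] = float(row["score"])
            elif kind == "classes":
                cols = sorted(
                    (c for c in df.columns if c.startswith("score_class")),
                    key=lambda c: int(c.removeprefix("score_class")),
                )
                entries[name] = tuple(float(row[c]) for c in cols)
                if "score_presence" in row and pd.notna(row["score_presence"]):
                    presence[name] = float(row["score_presence"])
            elif kind == "group":
                entries[name] = str(row["group"])
            elif kind == "weight":
                entries[name] = float(row["weight"])
                if int(row["sensitive"]):
                    sensitive.append(name)
            elif kind == "cs_e":
                entries[name] = (float(row["cs"]), float(row["e"]))
            elif kind == "members":
                entries[name] = 1
            else:
                raise ArgumentError(f"unknown score-table kind {kind!r}")
        gs = meta.get("group_scores")
        group_scores = (
            pd.DataFrame(
                gs["values"], index=gs["groups"], columns=gs["classes"]
            )
            if gs
            else None
        )
        return cls(
            index=meta["index"],
            rank=meta["rank"],
            kind=kind,
            entries=entries,
            class_rule=AbundanceClassRule(tuple(meta["class_rule"]))
            if meta.get("class_rule")
            else None,
            group_scores=group_scores,
            presence_scores=presence,
            sensitive_groups=tuple(meta.get("sensitive_groups", ())),
            sensitive_taxa=tuple(sensitive),
            composites={
                k: tuple(v) for k, v in meta.get("composites", {}).items()
            },
            origin=meta.get("origin", "user"),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls.from_frame(pd.read_csv(path), meta)


# ---------------------------------------------------------------------------
# Index result + trace machinery
# ---------------------------------------------------------------------------


@dataclass
class IndexResult:
    values: pd.Series | pd.DataFrame
    index_name: str
    tax_lev: str
    flags: dict[str, str] = field(default_factory=dict)
    trace: dict[str, dict] | None = None
    aggregation: dict = field(default_factory=lambda: {"transform": "sum", "scale": 1.0})
    origin: str = ""


def recompute_from_trace(result: IndexResult) -> pd.Series:
    """Rebuild per-sample values using only the trace records."""
    if result.trace is None:
        raise ArgumentError("result has no trace; rerun with trace_b=True")
    transform = result.aggregation.get("transform", "sum")
    scale = result.aggregation.get("scale", 1.0)
    out = {}
    for sample, rec in result.trace.items():
        s = sum(u["score"] for u in rec["used"])
        s += sum(c["score"] for c in rec.get("composites", []))
        w = sum(u.get("weight", 0.0) for u in rec["used"])
        w += sum(c.get("weight", 0.0) for c in rec.get("composites", []))
        if transform == "sum":
            v = s
        elif transform == "ratio":
            v = s / w if w else math.nan
        elif transform == "log10p1":
            v = math.log10(1.0 + s)
        elif transform == "one_minus_ratio":
            v = 1.0 - s / w if w else math.nan
        else:  # pragma: no cover
            raise ArgumentError(f"unknown transform {transform!r}")
        out[sample] = scale * v if not math.isnan(v) else math.nan
    return pd.Series(out, dtype=float)


def _resolve_rank(scores: ScoreTable, tax_lev: str | None) -> str:
    if tax_lev is None:
        return scores.rank
    if tax_lev != scores.rank:
        raise ArgumentError(
            f"score table for {scores.index!r} applies at rank "
            f"{scores.rank!r}, not {tax_lev!r}"
        )
    return tax_lev


def _present(table: pd.DataFrame, sample: str) -> pd.Series:
    col = table[sample]
    return col[col > 0]


def _score_samples(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None,
    per_taxon,
    transform: str,
    scale: float = 1.0,
    trace_b: bool = False,
    composite: bool = False,
    index_name: str | None = None,
) -> IndexResult:
    """Shared scoring loop.

    ``per_taxon(name, abundance)`` returns ``(score, weight, extra)`` or a
    string exclusion reason.  Composite rules (when enabled) substitute a
    single entry for any present member set.
    """
    rank = _resolve_rank(scores, tax_lev)
    table = agg.at(rank).df
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    trace: dict[str, dict] = {}
    for sample in agg.samples:
        present = _present(table, sample)
        used, excluded, comps = [], [], []
        covered: set[str] = set()
        if composite:
            for comp_name, members in scores.composites.items():
                inter = [t for t in present.index if t in members]
                if not inter or comp_name not in scores.entries:
                    continue
                res = per_taxon(comp_name, float(present[inter].sum()))
                if isinstance(res, str):
                    continue
                score, weight, extra = res
                comps.append(
                    {
                        "name": comp_name,
                        "members_present": inter,
                        "score": score,
                        "weight": weight,
                        **extra,
                    }
                )
                covered.update(inter)
        for taxon, n in present.items():
            if taxon in covered:
                excluded.append(
                    {"taxon": taxon, "reason": "covered_by_composite"}
                )
                continue
            if taxon not in scores.entries:
                excluded.append({"taxon": taxon, "reason": "no_score"})
                continue
            res = per_taxon(taxon, float(n))
            if isinstance(res, str):
                excluded.append({"taxon": taxon, "reason": res})
                continue
            score, weight, extra = res
            used.append({"taxon": taxon, "score": score, "weight": weight, **extra})
        s = sum(u["score"] for u in used) + sum(c["score"] for c in comps)
        w = sum(u["weight"] for u in used) + sum(c["weight"] for c in comps)
        if transform == "sum":
            v = s
        elif transform == "ratio":
            v = s / w if w else math.nan
        elif transform == "log10p1":
            v = math.log10(1.0 + s)
        elif transform == "one_minus_ratio":
            v = 1.0 - s / w if w else math.nan
        else:  # pragma: no cover
            raise ArgumentError(f"unknown transform {transform!r}")
        if math.isnan(v):
            flags[sample] = "no_scored_taxa"
            values[sample] = math.nan
        else:
            values[sample] = scale * v
        trace[sample] = {"used": used, "excluded": excluded, "composites": comps}
    return IndexResult(
        values=pd.Series(values, dtype=float).reindex(agg.samples),
        index_name=index_name or scores.index,
        tax_lev=rank,
        flags=flags,
        trace=trace if trace_b else None,
        aggregation={"transform": transform, "scale": scale},
        origin=scores.origin,
    )


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------


def bmwp(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
    composite: bool = False,
) -> IndexResult:
    """Sum of sensitivity scores of present scoring taxa.

    With ``composite`` on, families belonging to one composite rule
    contribute the composite's score exactly once.
    """
    if scores.kind != "scalar":
        raise ArgumentError("bmwp requires a scalar-valued score table")

    def per_taxon(name, n):
        return float(scores.entries[name]), 0.0, {}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "sum",
        trace_b=trace_b, composite=composite, index_name="bmwp",
    )


def aspt(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
    composite: bool = False,
) -> IndexResult:
    """Average score per taxon: BMWP sum divided by the number of scoring
    units (composites counted once)."""
    if scores.kind != "scalar":
        raise ArgumentError("aspt requires a scalar-valued score table")

    def per_taxon(name, n):
        return float(scores.entries[name]), 1.0, {}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "ratio",
        trace_b=trace_b, composite=composite, index_name="aspt",
    )


def dehli(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """Mean drought-sensitivity score of present scored taxa (same
    averaging contract as aspt, its own score table)."""
    res = aspt(agg, scores, tax_lev, trace_b=trace_b)
    res.index_name = "dehli"
    return res


def whpt(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    metric: str = "aspt",
    occurrence_mode: bool = False,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """Abundance-class-weighted scores, summed (``bmwp``) or averaged
    (``aspt``); ``occurrence_mode`` uses the presence-only score column."""
    if metric not in {"aspt", "bmwp"}:
        raise ArgumentError("whpt metric must be 'aspt' or 'bmwp'")
    if scores.kind != "classes" or scores.class_rule is None:
        raise ArgumentError("whpt requires a class-valued score table")
    rule = scores.class_rule

    def per_taxon(name, n):
        if occurrence_mode:
            if name not in scores.presence_scores:
                return "no_presence_score"
            return scores.presence_scores[name], 1.0, {"class": 0}
        k = rule.class_of(n)
        return float(scores.entries[name][k - 1]), 1.0, {"class": k}

    return _score_samples(
        agg, scores, tax_lev, per_taxon,
        "ratio" if metric == "aspt" else "sum",
        trace_b=trace_b, index_name=f"whpt_{metric}",
    )


def life(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """Mean flow score: each present taxon contributes the
    (flow group x abundance class) cell of the flow-score matrix."""
    if scores.kind != "group" or scores.group_scores is None:
        raise ArgumentError("life requires a group score table with a matrix")
    rule = scores.class_rule or AbundanceClassRule()
    mat = scores.group_scores

    def per_taxon(name, n):
        group = scores.entries[name]
        k = min(rule.class_of(n), mat.shape[1])
        return float(mat.loc[group].iloc[k - 1]), 1.0, {"group": group, "class": k}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "ratio",
        trace_b=trace_b, index_name="life",
    )


def psi(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """100 x (weight of sediment-sensitive groups) / (weight of all scored
    groups); weights from the (group x abundance class) matrix."""
    if scores.kind != "group" or scores.group_scores is None:
        raise ArgumentError("psi requires a group score table with a matrix")
    rule = scores.class_rule or AbundanceClassRule()
    mat = scores.group_scores
    sensitive = set(scores.sensitive_groups)

    def per_taxon(name, n):
        group = scores.entries[name]
        k = min(rule.class_of(n), mat.shape[1])
        fs = float(mat.loc[group].iloc[k - 1])
        num = fs if group in sensitive else 0.0
        return num, fs, {"group": group, "class": k, "fs": fs}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "ratio", scale=100.0,
        trace_b=trace_b, index_name="psi",
    )


def epsi(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """Empirically weighted PSI: 100 x (weights of sensitive taxa present)
    / (weights of all scored taxa present)."""
    if scores.kind != "weight":
        raise ArgumentError("epsi requires a weight-valued score table")
    sensitive = set(scores.sensitive_taxa)

    def per_taxon(name, n):
        w = float(scores.entries[name])
        return (w if name in sensitive else 0.0), w, {"sensitive": name in sensitive}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "ratio", scale=100.0,
        trace_b=trace_b, index_name="epsi",
    )


def ibmr(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """Cover-weighted macrophyte index: sum(CS*E*K)/sum(E*K) with K the
    abundance class of cover."""
    if scores.kind != "cs_e":
        raise ArgumentError("ibmr requires a cs/e score table")
    rule = scores.class_rule or AbundanceClassRule()

    def per_taxon(name, n):
        cs, e = scores.entries[name]
        k = rule.class_of(n)
        return cs * e * k, e * k, {"cs": cs, "e": e, "class": k}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "ratio",
        trace_b=trace_b, index_name="ibmr",
    )


def ept(
    agg: AggregatedCommunity,
    metric: str = "richness",
    tax_lev: str = "Family",
    orders: Sequence[str] = EPT_ORDERS,
) -> IndexResult:
    """Richness (or abundance) of Ephemeroptera + Plecoptera + Trichoptera
    at the stated rank."""
    if metric not in {"richness", "abundance"}:
        raise ArgumentError("ept metric must be 'richness' or 'abundance'")
    if metric == "richness":
        vals = get_taxa_richness(agg, orders, "Order", tax_lev)
    else:
        ref = agg.reference.df
        members = set(
            ref.loc[ref["Order"].isin(orders), tax_lev].replace("", np.nan).dropna()
        )
        table = agg.at(tax_lev).df
        vals = table.loc[table.index.isin(members)].sum(axis=0).reindex(
            agg.samples, fill_value=0.0
        )
    return IndexResult(
        values=vals.astype(float),
        index_name=f"ept_{metric}",
        tax_lev=tax_lev,
        aggregation={"transform": "sum", "scale": 1.0},
    )


def eptd(
    agg: AggregatedCommunity,
    scores: ScoreTable,
    tax_lev: str | None = None,
    trace_b: bool = False,
) -> IndexResult:
    """log10(1 + summed abundance of the selected EPTD families)."""
    if scores.kind != "members":
        raise ArgumentError("eptd requires a members score table")

    def per_taxon(name, n):
        return n, 0.0, {}

    return _score_samples(
        agg, scores, tax_lev, per_taxon, "log10p1",
        trace_b=trace_b, index_name="eptd",
    )


def igold(
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
    groups: dict[str, str] = GOLD_GROUPS,
    trace_b: bool = False,
) -> IndexResult:
    """1 - relative abundance of Gastropoda + Oligochaeta + Diptera.

    ``groups`` maps each tolerant group name to the rank it occupies in the
    reference; membership is resolved through lineages.
    """
    ref = agg.reference.df
    gold: set[str] = set()
    key = TAXA if tax_lev == TAXA else tax_lev
    for name, rank in groups.items():
        rows = ref[ref[rank] == name]
        gold.update(rows[key].replace("", np.nan).dropna())
    table = agg.at(tax_lev).df
    values, flags, trace = {}, {}, {}
    for sample in agg.samples:
        present = _present(table, sample)
        total = float(present.sum())
        if total == 0:
            values[sample] = math.nan
            flags[sample] = "empty_sample"
            trace[sample] = {"used": [], "excluded": [], "composites": []}
            continue
        used = [
            {"taxon": t, "score": float(n) if t in gold else 0.0,
             "weight": float(n), "gold": t in gold}
            for t, n in present.items()
        ]
        gsum = sum(u["score"] for u in used)
        values[sample] = 1.0 - gsum / total
        trace[sample] = {"used": used, "excluded": [], "composites": []}
    return IndexResult(
        values=pd.Series(values, dtype=float).reindex(agg.samples),
        index_name="igold",
        tax_lev=tax_lev,
        flags=flags,
        trace=trace if trace_b else None,
        aggregation={"transform": "one_minus_ratio", "scale": 1.0},
    )


def bioco(
    agg: AggregatedCommunity,
    aliens: Iterable[str],
    tax_lev: str = TAXA,
    thresholds: Sequence[float] = SBCI_THRESHOLDS,
    trace_b: bool = False,
) -> IndexResult:
    """Biocontamination: ACI (alien abundance share), RCI (alien richness
    share) and the ordinal SBCI class.

    SBCI = max(class(ACI), class(RCI)) where class(x) counts thresholds
    strictly exceeded, capped at the number of classes - 1 (default 5
    classes, 0-4).  The class table is configurable.
    """
    alien_set = set(aliens)
    table = agg.at(tax_lev).df
    n_classes = len(thresholds)

    def cls(x: float) -> int:
        return min(sum(x > t for t in thresholds), n_classes - 1)

    rows, flags, trace = {}, {}, {}
    for sample in agg.samples:
        present = _present(table, sample)
        total_n = float(present.sum())
        total_s = int(len(present))
        if total_s == 0:
            rows[sample] = (math.nan, math.nan, math.nan)
            flags[sample] = "empty_sample"
            trace[sample] = {"used": [], "excluded": [], "composites": []}
            continue
        is_alien = present.index.isin(alien_set)
        aci = float(present[is_alien].sum()) / total_n
        rci = float(is_alien.sum()) / total_s
        sbci = max(cls(aci), cls(rci))
        rows[sample] = (aci, rci, sbci)
        trace[sample] = {
            "used": [
                {"taxon": t, "score": float(n), "weight": 0.0, "alien": bool(a)}
                for (t, n), a in zip(present.items(), is_alien)
            ],
            "excluded": [],
            "composites": [],
        }
    df = pd.DataFrame(rows, index=["aci", "rci", "sbci"]).T.reindex(agg.samples)
    return IndexResult(
        values=df,
        index_name="bioco",
        tax_lev=tax_lev,
        flags=flags,
        trace=trace if trace_b else None,
        aggregation={"transform": "sum", "scale": 1.0},
    )
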