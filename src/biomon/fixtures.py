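"""Synthetic generators for reference datasets, communities, trait tables
and score tables.

Everything downstream is testable offline: generation is deterministic per
seed, every artifact satisfies its type invariants, and the community
abundance model is a log-series so Fisher's alpha has a known ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biotic import AbundanceClassRule, ScoreTable
from .ranks import RANKS, TAXA
from .taxonomy import CommunityMatrix, ReferenceDataset

_CONS = "bdfglmnprstvz"
_VOW = "aeiou"


def _name(rng: np.random.Generator, syllables: int = 3, suffix: str = "") -> str:
    s = "".join(
        _CONS[rng.integers(len(_CONS))] + _VOW[rng.integers(len(_VOW))]
        for _ in range(syllables)
    )
    return s.capitalize() + suffix


def _unique_name(rng, used: set[str], syllables: int = 3, suffix: str = "") -> str:
    for _ in range(1000):
        n = _name(rng, syllables, suffix)
        if n not in used:
            used.add(n)
            return n
    raise RuntimeError("name space exhausted")  # pragma: no cover


def generate_reference(
    n_orders: int = 4,
    n_families_per_order: int = 3,
    n_genera_per_family: int = 2,
    n_species_per_genus: int = 2,
    seed: int = 0,
    order_names: list[str] | None = None,
    phylum: str = "Arthropoda",
    class_name: str = "Insecta",
) -> ReferenceDataset:
    """Nested synthetic lineages (Phylum/Class/Order/Family/Genus/Species).

    Every internal taxon (order, family, genus) also gets its own terminal
    row so mixed-resolution communities can reference it directly.  Real
    order names (e.g. the EPT orders) can be injected via ``order_names``.
    """
    rng = np.random.default_rng(seed)
    used: set[str] = {phylum, class_name}
    rows: list[dict[str, str]] = []

    def add(lineage: dict[str, str]) -> None:
        row = {r: lineage.get(r, "") for r in RANKS}
        finest = [v for v in (lineage.get(r) for r in RANKS) if v][-1]
        row[TAXA] = finest
        rows.append(row)

    base = {"Phylum": phylum, "Class": class_name}
    add(base)
    for oi in range(n_orders):
        if order_names is not None and oi < len(order_names):
            order = order_names[oi]
            used.add(order)
        else:
            order = _unique_name(rng, used, 4, "ptera")
        olin = dict(base, Order=order)
        add(olin)
        for _ in range(n_families_per_order):
            family = _unique_name(rng, used, 3, "idae")
            flin = dict(olin, Family=family)
            add(flin)
            for _ in range(n_genera_per_family):
                genus = _unique_name(rng, used, 3, "us")
                glin = dict(flin, Genus=genus)
                add(glin)
                for _ in range(n_species_per_genus):
                    epithet = _name(rng, 3).lower()
                    species = f"{genus} {epithet}"
                    if species in used:
                        continue
                    used.add(species)
                    add(dict(glin, Species=species))
    df = pd.DataFrame(rows, columns=list(RANKS) + [TAXA])
    return ReferenceDataset(df)


def generate_community(
    ref: ReferenceDataset,
    n_samples: int = 5,
    n_taxa: int | None = None,
    resolution_mix: tuple[float, float, float] = (0.6, 0.25, 0.15),
    logseries_x: float = 0.9,
    occurrence: bool = False,
    seed: int = 0,
) -> CommunityMatrix:
    """Mixed-resolution community drawn from the reference.

    ``resolution_mix`` gives the fractions of taxa identified at species,
    genus and family level.  Abundances of occupied cells are iid
    log-series(x) counts, so a sample's (S, N) pair is consistent with a
    Fisher log-series community of parameter x.
    """
    rng = np.random.default_rng(seed)
    df = ref.df
    pools = {
        "Species": sorted(df.loc[df["Species"] != "", TAXA]),
        "Genus": sorted(
            set(df.loc[df["Genus"] != "", "Genus"]) & set(df[TAXA])
        ),
        "Family": sorted(
            set(df.loc[df["Family"] != "", "Family"]) & set(df[TAXA])
        ),
    }
    weights = np.asarray(resolution_mix, dtype=float)
    weights = weights / weights.sum()
    if n_taxa is None:
        n_taxa = max(3, int(0.6 * len(pools["Species"])))
    chosen: list[str] = []
    for rank, w in zip(("Species", "Genus", "Family"), weights):
        k = min(int(round(w * n_taxa)), len(pools[rank]))
        if k > 0:
            picks = rng.choice(pools[rank], size=k, replace=False)
            chosen.extend(p for p in picks if p not in chosen)
    if not chosen:
        chosen = pools["Species"][:n_taxa]
    mat = np.zeros((len(chosen), n_samples))
    for j in range(n_samples):
        occupied = rng.random(len(chosen)) < 0.8
        if not occupied.any():
            occupied[rng.integers(len(chosen))] = True
        counts = rng.logseries(logseries_x, size=int(occupied.sum()))
        mat[occupied, j] = counts
    if occurrence:
        mat = (mat > 0).astype(float)
    cm = pd.DataFrame(
        mat, index=chosen, columns=[f"sample_{j + 1}" for j in range(n_samples)]
    )
    return CommunityMatrix(cm, occurrence)


def generate_logseries_sample(
    alpha: float, target_n: float, seed: int = 0
) -> CommunityMatrix:
    """Single-sample community drawn from a Fisher log-series with known
    alpha: S ~ Poisson(alpha * ln(1 + N/alpha)) species, counts iid
    log-series(x) with x = N/(N + alpha)."""
    rng = np.random.default_rng(seed)
    x = target_n / (target_n + alpha)
    s_expected = alpha * np.log1p(target_n / alpha)
    s = max(2, int(rng.poisson(s_expected)))
    counts = rng.logseries(x, size=s)
    df = pd.DataFrame(
        {"sample_1": counts.astype(float)},
        index=[f"Taxon{i + 1}" for i in range(s)],
    )
    return CommunityMatrix(df)


def generate_traits(
    ref: ReferenceDataset,
    blocks: dict[str, int] | None = None,
    trait_ranks: tuple[str, ...] = ("Family", "Genus", "Species"),
    specialization: float = 2.0,
    seed: int = 0,
):
    """Fuzzy-coded trait rows for reference taxa at the given ranks.

    Affinities are Dirichlet within each block; larger ``specialization``
    concentrates affinity in fewer modalities.  Block sums are 1.
    """
    from .traits import TraitDataset

    if blocks is None:
        blocks = {"feeding": 4, "flow": 3, "size": 3}
    rng = np.random.default_rng(seed)
    df = ref.df
    taxa: list[str] = []
    ranks: list[str] = []
    for rank in trait_ranks:
        if rank == TAXA:
            continue
        members = df.loc[(df[rank] != "") & (df[TAXA] == df[rank]), TAXA]
        if rank == "Species":
            members = df.loc[df["Species"] != "", TAXA]
        for t in sorted(members):
            if t not in taxa:
                taxa.append(t)
                ranks.append(rank)
    cols: list[str] = []
    block_map: dict[str, list[str]] = {}
    for trait, k in blocks.items():
        mods = [f"{trait}_{i + 1}" for i in range(k)]
        block_map[trait] = mods
        cols.extend(mods)
    data = np.zeros((len(taxa), len(cols)))
    c0 = 0
    for trait, k in blocks.items():
        conc = np.full(k, 1.0 / specialization)
        data[:, c0 : c0 + k] = rng.dirichlet(conc, size=len(taxa))
        c0 += k
    frame = pd.DataFrame(np.round(data, 6), index=taxa, columns=cols)
    # re-normalize blocks after rounding
    td = TraitDataset(frame, pd.Series(ranks, index=taxa, dtype=object), block_map)
    td.data = td.block_normalized()
    return td


def _family_pool(ref: ReferenceDataset) -> list[str]:
    df = ref.df
    return sorted(set(df.loc[df["Family"] != "", "Family"]))


def generate_scores(
    ref: ReferenceDataset, kind: str = "bmwp", seed: int = 0
) -> ScoreTable:
    """Synthetic score tables per index family.

    Kinds: ``bmwp`` (scalar family scores 1..10, plus one composite rule),
    ``whpt`` (4-class vectors + presence score), ``life`` (flow groups with
    a group x class matrix), ``psi`` (A-D groups, A/B sensitive), ``epsi``
    (weights + sensitive flags), ``ibmr`` (CS/E pairs), ``eptd`` and
    ``aliens`` (member lists), ``dehli`` (scalar drought scores).
    """
    rng = np.random.default_rng(seed)
    families = _family_pool(ref)
    rule = AbundanceClassRule()
    if kind in {"bmwp", "dehli"}:
        entries = {f: float(rng.integers(1, 11)) for f in families}
        composites = {}
        if kind == "bmwp" and len(families) >= 2:
            members = tuple(sorted(rng.choice(families, 2, replace=False)))
            comp = f"{members[0]} (composite)"
            entries[comp] = float(max(entries[m] for m in members))
            composites = {comp: members}
        return ScoreTable(
            index=kind, rank="Family", kind="scalar", entries=entries,
            composites=composites, origin=f"synthetic-{seed}",
        )
    if kind == "whpt":
        entries = {}
        presence = {}
        for f in families:
            base = float(rng.uniform(1, 9))
            vec = tuple(
                round(base + drift, 1)
                for drift in np.cumsum(rng.uniform(-1.0, 0.4, rule.n_classes))
            )
            entries[f] = vec
            presence[f] = round(base, 1)
        return ScoreTable(
            index="whpt", rank="Family", kind="classes", entries=entries,
            class_rule=rule, presence_scores=presence,
            origin=f"synthetic-{seed}",
        )
    if kind in {"life", "psi"}:
        if kind == "life":
            groups = [f"group{i}" for i in range(1, 7)]
            mat = pd.DataFrame(
                [
                    [9 - gi + drift for drift in (0, -1, -2, -3)]
                    for gi in range(len(groups))
                ],
                index=groups,
                columns=[f"class{k}" for k in range(1, rule.n_classes + 1)],
                dtype=float,
            ).clip(lower=1.0)
            sensitive: tuple[str, ...] = ()
        else:
            groups = ["A", "B", "C", "D"]
            mat = pd.DataFrame(
                [[2.0, 3.0, 4.0, 5.0]] * 2 + [[1.0, 2.0, 3.0, 4.0]] * 2,
                index=groups,
                columns=[f"class{k}" for k in range(1, rule.n_classes + 1)],
            )
            sensitive = ("A", "B")
        entries = {f: groups[rng.integers(len(groups))] for f in families}
        return ScoreTable(
            index=kind, rank="Family", kind="group", entries=entries,
            class_rule=rule, group_scores=mat, sensitive_groups=sensitive,
            origin=f"synthetic-{seed}",
        )
    if kind == "epsi":
        entries = {f: float(np.round(rng.uniform(0.1, 1.0), 3)) for f in families}
        sens = tuple(sorted(rng.choice(families, len(families) // 2, replace=False)))
        return ScoreTable(
            index="epsi", rank="Family", kind="weight", entries=entries,
            sensitive_taxa=sens, origin=f"synthetic-{seed}",
        )
    if kind == "ibmr":
        genera = sorted(
            set(ref.df.loc[ref.df["Genus"] != "", "Genus"]) & set(ref.df[TAXA])
        )
        entries = {
            g: (float(rng.integers(0, 21)) / 2.0, float(rng.integers(1, 4)))
            for g in genera
        }
        return ScoreTable(
            index="ibmr", rank="Genus", kind="cs_e", entries=entries,
            class_rule=AbundanceClassRule((5.0, 25.0, 75.0)),
            origin=f"synthetic-{seed}",
        )
    if kind == "eptd":
        k = max(1, len(families) // 3)
        members = sorted(rng.choice(families, k, replace=False))
        return ScoreTable(
            index="eptd", rank="Family", kind="members",
            entries={m: 1 for m in members}, origin=f"synthetic-{seed}",
        )
    if kind == "aliens":
        taxa = sorted(ref.df.loc[ref.df["Species"] != "", TAXA])
        k = max(1, len(taxa) // 5)
        members = sorted(rng.choice(taxa, k, replace=False))
        return ScoreTable(
            index="aliens", rank=TAXA, kind="members",
            entries={m: 1 for m in members}, origin=f"synthetic-{seed}",
        )
    raise ValueError(f"unknown score kind {kind!r}")


SCORE_KINDS = ("bmwp", "dehli", "whpt", "life", "psi", "epsi", "ibmr", "eptd", "aliens")


def demo_workspace(seed: int = 0) -> dict:
    """A complete in-memory demo: reference, community, traits, scores."""
    ref = generate_reference(
        seed=seed, order_names=["Ephemeroptera", "Plecoptera", "Trichoptera"]
    )
    community = generate_community(ref, seed=seed)
    traits = generate_traits(ref, seed=seed)
    scores = {kind: generate_scores(ref, kind, seed=seed) for kind in SCORE_KINDS}
    return {
        "reference": ref,
        "community": community,
        "traits": traits,
        "scores": scores,
    }
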