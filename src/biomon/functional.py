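"""Trait spaces and functional diversity indices.

Builds Gower/Euclidean distance matrices from fuzzy-coded traits, embeds
them by principal coordinates analysis (with the Cailliez, Lingoes, square
root and quasi-Euclidean corrections), evaluates trait-space quality
(distance correlation, cumulative-eigenvalue r-squared, mean squared
deviation), and computes functional richness/dispersion/evenness, Rao's
quadratic entropy, redundancy, community weighted means, specialization
and fuzzy trait ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform

from .ranks import TAXA
from .taxonomy import AggregatedCommunity, ArgumentError, ValidationError
from .traits import TraitDataset

PCOA_CORRECTIONS = ("none", "cailliez", "lingoes", "sqrt", "quasi")
AXIS_CRITERIA = ("corr", "r2", "msd")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    metric: str = "gower"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def sub(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(t) for t in labels]
        return DistanceMatrix(labels, self.d[np.ix_(idx, idx)], self.metric)


def gower_distance(traits: TraitDataset) -> DistanceMatrix:
    """Gower dissimilarity on fuzzy-coded blocks.

    Each block contributes one component: the mean over its modalities of
    range-scaled absolute differences of block-normalized affinities;
    the distance is the mean over blocks informative in both rows (a block
    with zero affinity sum counts as missing for that row).
    """
    norm = traits.block_normalized()
    taxa = list(norm.index)
    n = len(taxa)
    raw = traits.data
    has_any = np.zeros(n, dtype=bool)
    comp = []  # per block: (component matrix, availability vector)
    for mods in traits.blocks.values():
        x = norm[mods].to_numpy(dtype=float)
        has = raw[mods].sum(axis=1).to_numpy() > 0
        has_any |= has
        rng = x.max(axis=0) - x.min(axis=0)
        diffs = np.zeros((n, n))
        used = 0
        for j, r in enumerate(rng):
            if r <= 0:
                continue
            col = x[:, j]
            diffs += np.abs(col[:, None] - col[None, :]) / r
            used += 1
        if used == 0:
            continue  # constant block carries no information
        comp.append((diffs / used, has))
    if not has_any.all():
        bad = [t for t, e in zip(taxa, has_any) if not e]
        raise ArgumentError(f"all trait blocks missing for taxa: {bad}")
    total = np.zeros((n, n))
    counts = np.zeros((n, n))
    for diffs, has in comp:
        both = np.outer(has, has)
        total += np.where(both, diffs, 0.0)
        counts += both
    with np.errstate(invalid="ignore"):
        d = np.where(counts > 0, total / np.where(counts > 0, counts, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa, (d + d.T) / 2.0, "gower")


def euclidean_distance(traits: TraitDataset) -> DistanceMatrix:
    x = traits.data.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(list(traits.data.index), d, "euclidean")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class TraitSpace:
    labels: list[str]
    coordinates: np.ndarray  # taxa x m axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    correction: str = "none"
    correction_constant: float = 0.0
    quality: pd.DataFrame | None = None

    def coords(self, m: int | None = None) -> np.ndarray:
        if m is None:
            return self.coordinates
        if m > self.coordinates.shape[1]:
            raise ArgumentError(
                f"requested {m} axes but only {self.coordinates.shape[1]} available"
            )
        return self.coordinates[:, :m]


def _double_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _eig_desc(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest c making d + c (off-diagonal) Euclidean: largest real
    # eigenvalue of the classical 2n x 2n companion problem
    n = d.shape[0]
    delta1 = _double_center(d)
    delta2_a = -0.5 * d
    row = delta2_a.mean(axis=1, keepdims=True)
    col = delta2_a.mean(axis=0, keepdims=True)
    delta2 = delta2_a - row - col + delta2_a.mean()
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    big = np.vstack([upper, lower])
    ev = np.linalg.eigvals(big)
    c = float(np.max(ev.real))
    return max(c, 0.0)


def _lingoes_constant(d: np.ndarray) -> float:
    w, _ = _eig_desc(_double_center(d))
    lam_min = float(w.min())
    return max(-lam_min, 0.0)


def pcoa(dist: DistanceMatrix, correction: str = "none") -> TraitSpace:
    """Principal coordinates of a distance matrix.

    Corrections: ``sqrt`` takes element-wise square roots; ``lingoes`` uses
    sqrt(d^2 + 2*c2) off-diagonal with the minimal c2; ``cailliez`` adds the
    minimal c1 off-diagonal; ``quasi`` simply drops negative-eigenvalue
    axes (which every variant does for the returned coordinates).
    """
    if correction not in PCOA_CORRECTIONS:
        raise ArgumentError(
            f"unknown correction {correction!r}; choose from {PCOA_CORRECTIONS}"
        )
    d = dist.d.copy()
    const = 0.0
    off = ~np.eye(d.shape[0], dtype=bool)
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "lingoes":
        const = _lingoes_constant(d)
        if const > 0:
            d2 = d**2
            d2[off] += 2.0 * const
            d = np.sqrt(d2)
    elif correction == "cailliez":
        const = _cailliez_constant(d)
        if const > 0:
            d[off] += const
    w, v = _eig_desc(_double_center(d))
    tol = max(1e-10, 1e-10 * abs(w).max(initial=1.0))
    pos = w > tol
    coords = v[:, pos] * np.sqrt(w[pos])
    return TraitSpace(
        labels=list(dist.labels),
        coordinates=coords,
        eigenvalues=w,
        correction=correction,
        correction_constant=const,
    )


def _pairwise(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def select_pcoa_axes(
    dist: DistanceMatrix,
    correction: str = "none",
    criterion: str = "msd",
    threshold: float = 0.95,
    m_max: int | None = None,
) -> tuple[pd.DataFrame, int, TraitSpace]:
    """Trait-space quality for m = 1..m_max retained axes.

    Per m: ``corr`` is the Pearson correlation between m-axis Euclidean
    distances and the original distances; ``r2`` the cumulative share of
    positive eigenvalues; ``msd`` the mean squared deviation between
    max-scaled m-axis and original distances.  The recommended m minimizes
    mSD, or is the smallest m reaching ``threshold`` for corr/r2.
    """
    if criterion not in AXIS_CRITERIA:
        raise ArgumentError(
            f"unknown criterion {criterion!r}; choose from {AXIS_CRITERIA}"
        )
    space = pcoa(dist, correction)
    n_axes = space.coordinates.shape[1]
    if n_axes == 0:
        raise ArgumentError("no positive-eigenvalue axis available")
    m_top = n_axes if m_max is None else min(m_max, n_axes)
    orig = squareform(dist.d, checks=False)
    pos = space.eigenvalues[space.eigenvalues > 0]
    rows = []
    for m in range(1, m_top + 1):
        dm = squareform(_pairwise(space.coords(m)), checks=False)
        if orig.std() == 0 or dm.std() == 0:
            corr = math.nan
        else:
            corr = float(np.corrcoef(dm, orig)[0, 1])
        r2 = float(pos[:m].sum() / pos.sum())
        s_orig = orig / orig.max() if orig.max() > 0 else orig
        s_dm = dm / dm.max() if dm.max() > 0 else dm
        msd = float(((s_dm - s_orig) ** 2).mean())
        rows.append({"m": m, "corr": corr, "r2": r2, "msd": msd})
    quality = pd.DataFrame(rows)
    if criterion == "msd":
        recommended = int(quality.loc[quality["msd"].idxmin(), "m"])
    else:
        ok = quality[quality[criterion] >= threshold]
        recommended = int(ok["m"].iloc[0]) if not ok.empty else m_top
    space.quality = quality
    return quality, recommended, space


# ---------------------------------------------------------------------------
# Community helpers
# ---------------------------------------------------------------------------


@dataclass
class FunctionalResult:
    values: pd.Series
    index_name: str
    tax_lev: str
    flags: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _sample_weights(
    agg: AggregatedCommunity, tax_lev: str, labels: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Relative abundances restricted to taxa covered by the trait object."""
    table = agg.at(tax_lev).df
    covered = [t for t in table.index if t in labels]
    flags = {}
    sub = table.loc[covered]
    return sub, flags


def f_rich(
    space: TraitSpace,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
    m: int = 2,
    max_m: int = 6,
) -> FunctionalResult:
    """Functional richness: convex-hull volume of present taxa in m axes.

    Samples with at most m present (covered) taxa, or degenerate point
    sets, get NaN with a flag.  ``m > max_m`` is refused (hull cost grows
    combinatorially); raise ``max_m`` explicitly to override.
    """
    if m > max_m:
        raise ArgumentError(f"m={m} exceeds max_m={max_m}")
    coords = space.coords(m)
    sub, flags = _sample_weights(agg, tax_lev, space.labels)
    pos = {t: space.labels.index(t) for t in sub.index}
    values = {}
    for s in agg.samples:
        present = sub.index[sub[s] > 0]
        if len(present) <= m:
            values[s] = math.nan
            flags[s] = "too_few_taxa"
            continue
        pts = coords[[pos[t] for t in present]]
        try:
            values[s] = float(ConvexHull(pts).volume)
        except QhullError:
            values[s] = math.nan
            flags[s] = "degenerate_hull"
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "f_rich", tax_lev, flags, {"m": m},
    )


def f_disp(
    space: TraitSpace,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
    m: int | None = None,
) -> FunctionalResult:
    """Functional dispersion: abundance-weighted mean distance of present
    taxa to their abundance-weighted centroid in m axes."""
    coords = space.coords(m)
    sub, flags = _sample_weights(agg, tax_lev, space.labels)
    pos = {t: space.labels.index(t) for t in sub.index}
    values = {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            values[s] = math.nan
            flags[s] = "empty_sample"
            continue
        p = present.to_numpy() / present.sum()
        pts = coords[[pos[t] for t in present.index]]
        centroid = (p[:, None] * pts).sum(axis=0)
        dists = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
        values[s] = float((p * dists).sum())
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "f_disp", tax_lev, flags, {"m": m},
    )


def f_eve(
    space: TraitSpace,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
    m: int | None = None,
) -> FunctionalResult:
    """Villeger functional evenness from the minimum spanning tree of the
    present taxa in trait space; undefined for fewer than 3 taxa."""
    coords = space.coords(m)
    sub, flags = _sample_weights(agg, tax_lev, space.labels)
    pos = {t: space.labels.index(t) for t in sub.index}
    values = {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        S = len(present)
        if S < 3:
            values[s] = math.nan
            flags[s] = "fewer_than_3_taxa"
            continue
        p = present.to_numpy() / present.sum()
        pts = coords[[pos[t] for t in present.index]]
        dmat = _pairwise(pts)
        mst = minimum_spanning_tree(dmat).tocoo()
        ew = []
        for i, j, length in zip(mst.row, mst.col, mst.data):
            ew.append(length / (p[i] + p[j]))
        ew = np.asarray(ew)
        if ew.sum() == 0:
            values[s] = math.nan
            flags[s] = "degenerate_mst"
            continue
        pew = ew / ew.sum()
        thr = 1.0 / (S - 1)
        values[s] = float(
            (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)
        )
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "f_eve", tax_lev, flags, {"m": m},
    )


def f_divs(
    dist: DistanceMatrix,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
) -> FunctionalResult:
    """Rao quadratic entropy Q = sum_ij p_i p_j d_ij."""
    sub, flags = _sample_weights(agg, tax_lev, dist.labels)
    idx = {t: dist.labels.index(t) for t in sub.index}
    values = {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            values[s] = math.nan
            flags[s] = "empty_sample"
            continue
        p = present.to_numpy() / present.sum()
        ii = [idx[t] for t in present.index]
        d = dist.d[np.ix_(ii, ii)]
        values[s] = float(p @ d @ p)
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "f_divs", tax_lev, flags, {"metric": dist.metric},
    )


def f_red(
    dist: DistanceMatrix,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
) -> FunctionalResult:
    """Functional redundancy: Gini-Simpson diversity minus Rao's Q computed
    on distances rescaled to [0, 1]."""
    dmax = dist.d.max()
    scaled = DistanceMatrix(
        dist.labels, dist.d / dmax if dmax > 0 else dist.d, dist.metric
    )
    rao = f_divs(scaled, agg, tax_lev)
    sub, _ = _sample_weights(agg, tax_lev, dist.labels)
    values = {}
    flags = dict(rao.flags)
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            values[s] = math.nan
            continue
        p = present.to_numpy() / present.sum()
        gs = 1.0 - float((p**2).sum())
        values[s] = gs - rao.values[s]
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "f_red", tax_lev, flags, {"scaled_to_unit": dmax > 0},
    )


def cwm(
    traits: TraitDataset,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
) -> pd.DataFrame:
    """Community weighted mean: per sample and modality, sum p_i * trait_i
    over covered present taxa (block-normalized affinities)."""
    norm = traits.block_normalized()
    table = agg.at(tax_lev).df
    covered = [t for t in table.index if t in norm.index]
    sub = table.loc[covered]
    out = {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            out[s] = pd.Series(np.nan, index=norm.columns)
            continue
        p = present / present.sum()
        out[s] = norm.loc[present.index].mul(p, axis=0).sum(axis=0)
    return pd.DataFrame(out).T.reindex(agg.samples)


def tsi(traits: TraitDataset) -> pd.Series:
    """Taxon specialization index in [0, 1].

    Per block with >1 modality: generalism = (1/C - 1)/(K - 1), C the
    Simpson concentration of block-normalized affinities; TSI = 1 - mean
    generalism over informative blocks, so single-modality profiles score 1
    and uniform profiles score 0.
    """
    norm = traits.block_normalized()
    out = {}
    for taxon in norm.index:
        gens = []
        for mods in traits.blocks.values():
            if len(mods) < 2:
                continue
            a = norm.loc[taxon, mods].to_numpy(dtype=float)
            if a.sum() <= 0:
                continue
            c = float((a**2).sum())
            gens.append((1.0 / c - 1.0) / (len(mods) - 1.0))
        out[taxon] = 1.0 - float(np.mean(gens)) if gens else math.nan
    return pd.Series(out, dtype=float)


def csi(
    traits: TraitDataset,
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
) -> FunctionalResult:
    """Community specialization: abundance-weighted mean TSI."""
    t = tsi(traits).dropna()
    table = agg.at(tax_lev).df
    covered = [x for x in table.index if x in t.index]
    sub = table.loc[covered]
    values, flags = {}, {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            values[s] = math.nan
            flags[s] = "empty_sample"
            continue
        p = present / present.sum()
        values[s] = float((p * t.loc[present.index]).sum())
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "csi", tax_lev, flags,
    )


def fuzzy_trait_ratio(
    traits: TraitDataset,
    agg: AggregatedCommunity,
    numerator: list[str],
    denominator: list[str],
    tax_lev: str = TAXA,
) -> FunctionalResult:
    """Ratio of community-weighted affinity sums:
    sum_i p_i a_i(numerator) / sum_i p_i a_i(denominator), with a the
    block-normalized affinities.  Zero denominator -> NaN + flag."""
    norm = traits.block_normalized()
    for mod in list(numerator) + list(denominator):
        if mod not in norm.columns:
            raise ArgumentError(f"unknown trait modality {mod!r}")
    table = agg.at(tax_lev).df
    covered = [t for t in table.index if t in norm.index]
    sub = table.loc[covered]
    values, flags = {}, {}
    for s in agg.samples:
        col = sub[s]
        present = col[col > 0]
        if len(present) == 0:
            values[s] = math.nan
            flags[s] = "empty_sample"
            continue
        p = present / present.sum()
        num = float((p * norm.loc[present.index, numerator].sum(axis=1)).sum())
        den = float((p * norm.loc[present.index, denominator].sum(axis=1)).sum())
        if den == 0:
            values[s] = math.nan
            flags[s] = "zero_denominator"
        else:
            values[s] = num / den
    return FunctionalResult(
        pd.Series(values, dtype=float).reindex(agg.samples),
        "fuzzy_trait_ratio", tax_lev, flags,
        {"numerator": list(numerator), "denominator": list(denominator)},
    )


def flow_t(
    traits: TraitDataset,
    agg: AggregatedCommunity,
    flow_block: str = "flow",
    intermittency_modalities: list[str] | None = None,
    tax_lev: str = TAXA,
) -> FunctionalResult:
    """Flow-intermittency affinity ratio (Flow-T): a fuzzy trait ratio with
    the intermittency modalities as numerator and the whole flow block as
    denominator."""
    if flow_block not in traits.blocks:
        raise ArgumentError(f"trait block {flow_block!r} not found")
    block = traits.blocks[flow_block]
    num = intermittency_modalities or [block[-1]]
    res = fuzzy_trait_ratio(traits, agg, num, list(block), tax_lev)
    res.index_name = "flow_t"
    return res
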