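"""Richness, diversity, dominance and evenness indices.

Every operation takes ``(agg, tax_lev)`` and returns a
:class:`DiversityResult` with one value per sample.  Undefined cases yield
NaN plus a machine-readable flag, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .ranks import TAXA
from .taxonomy import AggregatedCommunity, ArgumentError


@dataclass
class DiversityResult:
    values: pd.Series
    index_name: str
    tax_lev: str
    flags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sample": self.values.index,
                "value": self.values.to_numpy(),
                "index": self.index_name,
                "tax_lev": self.tax_lev,
            }
        )
        out["flag"] = [self.flags.get(s, "") for s in self.values.index]
        return out


def _matrix(agg: AggregatedCommunity, tax_lev: str) -> pd.DataFrame:
    return agg.at(tax_lev).df


def _require_abundance(agg: AggregatedCommunity, name: str) -> None:
    if agg.occurrence:
        raise ArgumentError(
            f"{name} requires abundance data; community is presence/absence"
        )


def _result(name, tax_lev, samples, values, flags=None) -> DiversityResult:
    return DiversityResult(
        pd.Series(values, index=samples, dtype=float), name, tax_lev, flags or {}
    )


def richness(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """S: count of taxa with abundance > 0 per sample."""
    m = _matrix(agg, tax_lev)
    return _result("richness", tax_lev, agg.samples, (m > 0).sum(axis=0))


def shannon(
    agg: AggregatedCommunity, tax_lev: str = TAXA, base: float = np.e
) -> DiversityResult:
    """H = -sum p_i log_base p_i."""
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy() if s in m else np.array([])
        n = n[n > 0]
        if n.sum() == 0:
            vals.append(np.nan)
            flags[s] = "empty_sample"
            continue
        p = n / n.sum()
        vals.append(float(-(p * np.log(p)).sum() / np.log(base)))
    return _result("shannon", tax_lev, agg.samples, vals, flags)


def _simpson_concentration(n: np.ndarray) -> float:
    p = n / n.sum()
    return float((p**2).sum())


def simpson(
    agg: AggregatedCommunity,
    tax_lev: str = TAXA,
    variant: str = "simpson",
) -> DiversityResult:
    """Simpson family: ``simpson`` = 1-D (Gini-Simpson), ``invsimpson`` =
    1/D, ``esimpson`` = (1/D)/S, ``concentration`` = D, D = sum p_i^2."""
    if variant not in {"simpson", "invsimpson", "esimpson", "concentration"}:
        raise ArgumentError(f"unknown simpson variant {variant!r}")
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        if n.sum() == 0:
            vals.append(np.nan)
            flags[s] = "empty_sample"
            continue
        d = _simpson_concentration(n)
        if variant == "simpson":
            vals.append(1.0 - d)
        elif variant == "invsimpson":
            vals.append(1.0 / d)
        elif variant == "esimpson":
            vals.append(1.0 / d / len(n))
        else:
            vals.append(d)
    return _result(variant, tax_lev, agg.samples, vals, flags)


def pielou(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """J = H / ln S (base-consistent; undefined for S <= 1)."""
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        if len(n) <= 1:
            vals.append(np.nan)
            flags[s] = "richness_leq_1"
            continue
        p = n / n.sum()
        vals.append(float(-(p * np.log(p)).sum() / np.log(len(n))))
    return _result("pielou", tax_lev, agg.samples, vals, flags)


def berger_parker(
    agg: AggregatedCommunity, tax_lev: str = TAXA, variant: str = "berpar"
) -> DiversityResult:
    """d = max n_i / N (``berpar``) or its inverse (``invberpar``)."""
    if variant not in {"berpar", "invberpar"}:
        raise ArgumentError(f"unknown berger-parker variant {variant!r}")
    _require_abundance(agg, variant)
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        if n.sum() == 0:
            vals.append(np.nan)
            flags[s] = "empty_sample"
            continue
        d = n.max() / n.sum()
        vals.append(d if variant == "berpar" else 1.0 / d)
    return _result(variant, tax_lev, agg.samples, vals, flags)


def margalef(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """(S - 1)/ln N; undefined for N <= 1."""
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        N = n.sum()
        if N <= 1:
            vals.append(np.nan)
            flags[s] = "total_leq_1"
            continue
        vals.append((len(n) - 1) / np.log(N))
    return _result("margalef", tax_lev, agg.samples, vals, flags)


def menhinick(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """S / sqrt(N)."""
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        N = n.sum()
        if N == 0:
            vals.append(np.nan)
            flags[s] = "empty_sample"
            continue
        vals.append(len(n) / np.sqrt(N))
    return _result("menhinick", tax_lev, agg.samples, vals, flags)


def brillouin(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """HB = (ln N! - sum ln n_i!)/N; integer abundances required."""
    _require_abundance(agg, "brillouin")
    m = _matrix(agg, tax_lev)
    vals_arr = m.to_numpy()
    if not np.allclose(vals_arr, np.round(vals_arr)):
        raise ArgumentError("brillouin requires integer abundances")
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = np.round(m[s].to_numpy()).astype(np.int64)
        n = n[n > 0]
        N = n.sum()
        if N == 0:
            vals.append(np.nan)
            flags[s] = "empty_sample"
            continue
        hb = (gammaln(N + 1) - gammaln(n + 1).sum()) / N
        vals.append(float(hb))
    return _result("brillouin", tax_lev, agg.samples, vals, flags)


def mcintosh(agg: AggregatedCommunity, tax_lev: str = TAXA) -> DiversityResult:
    """(N - U)/(N - sqrt(N)), U = sqrt(sum n_i^2); undefined for N <= 1."""
    _require_abundance(agg, "mcintosh")
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        N = n.sum()
        if N <= 1:
            vals.append(np.nan)
            flags[s] = "total_leq_1"
            continue
        u = np.sqrt((n**2).sum())
        vals.append(float((N - u) / (N - np.sqrt(N))))
    return _result("mcintosh", tax_lev, agg.samples, vals, flags)


def fisher_alpha(
    agg: AggregatedCommunity, tax_lev: str = TAXA, tol: float = 1e-9
) -> DiversityResult:
    """alpha solving S = alpha * ln(1 + N/alpha), by bracketed root finding.

    Undefined (NaN + flag) when S = N (all singletons leave the equation
    without a finite root) or S = 0.
    """
    _require_abundance(agg, "fisher_alpha")
    m = _matrix(agg, tax_lev)
    flags: dict[str, str] = {}
    vals = []
    for s in agg.samples:
        n = m[s].to_numpy()
        n = n[n > 0]
        S, N = len(n), float(n.sum())
        if S == 0 or S >= N:
            vals.append(np.nan)
            flags[s] = "undefined_fisher"
            continue
        f = lambda a: a * np.log1p(N / a) - S  # noqa: E731
        lo, hi = 1e-12, 1.0
        while f(hi) < 0:
            hi *= 2
            if hi > 1e12:  # pragma: no cover - numeric guard
                break
        vals.append(float(brentq(f, lo, hi, xtol=tol)))
    return _result("fisher_alpha", tax_lev, agg.samples, vals, flags)


#: diversity index registry fragment: name -> callable(agg, tax_lev) -> result
DIVERSITY_INDICES = {
    "richness": richness,
    "shannon": shannon,
    "simpson": simpson,
    "invsimpson": lambda agg, tax_lev=TAXA: simpson(agg, tax_lev, "invsimpson"),
    "esimpson": lambda agg, tax_lev=TAXA: simpson(agg, tax_lev, "esimpson"),
    "pielou": pielou,
    "berpar": berger_parker,
    "invberpar": lambda agg, tax_lev=TAXA: berger_parker(agg, tax_lev, "invberpar"),
    "margalef": margalef,
    "menhinick": menhinick,
    "brillouin": brillouin,
    "mcintosh": mcintosh,
    "fisher": fisher_alpha,
}


def allrich(agg: AggregatedCommunity) -> pd.DataFrame:
    """Richness at every available rank: rows (rank, sample, value)."""
    rows = []
    for rank in agg.available_ranks:
        res = richness(agg, rank)
        for s, v in res.values.items():
            rows.append({"tax_lev": rank, "sample": s, "value": v})
    return pd.DataFrame(rows, columns=["tax_lev", "sample", "value"])


def allindices(agg: AggregatedCommunity, tax_lev: str = TAXA) -> pd.DataFrame:
    """All applicable diversity indices at one rank (long table).

    Indices that refuse the data type (e.g. brillouin on occurrences) are
    skipped; NaN cells keep their flags.
    """
    frames = []
    for name, fn in DIVERSITY_INDICES.items():
        try:
            frames.append(fn(agg, tax_lev).to_frame())
        except ArgumentError:
            continue
    return pd.concat(frames, ignore_index=True)
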