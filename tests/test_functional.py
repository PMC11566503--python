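"""Trait spaces and functional indices: brute-force and geometric oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import biomon
from biomon.functional import DistanceMatrix, TraitSpace, pcoa, select_pcoa_axes
from biomon.taxonomy import ArgumentError
from biomon.traits import TraitDataset

from conftest import make_agg


def simple_traits(rows, blocks=None):
    cols = sorted({c for r in rows.values() for c in r})
    data = pd.DataFrame(
        {t: [r.get(c, 0.0) for c in cols] for t, r in rows.items()}, index=cols
    ).T
    blocks = blocks or {"t": cols}
    return TraitDataset(data, pd.Series({t: "Genus" for t in rows}), blocks)


def gower_oracle(traits: TraitDataset) -> np.ndarray:
    """Independent double-loop Gower on block-normalized fuzzy data."""
    norm = traits.block_normalized()
    raw = traits.data
    taxa = list(norm.index)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            comps = []
            for mods in traits.blocks.values():
                if raw.loc[taxa[i], mods].sum() == 0 or raw.loc[taxa[j], mods].sum() == 0:
                    continue
                diffs = []
                for m in mods:
                    col = norm[m]
                    rng = col.max() - col.min()
                    if rng <= 0:
                        continue
                    diffs.append(abs(norm.loc[taxa[i], m] - norm.loc[taxa[j], m]) / rng)
                if diffs:
                    comps.append(np.mean(diffs))
            out[i, j] = np.mean(comps) if comps else 0.0
    return out


class TestGower:
    def test_identical_profiles_zero(self):
        t = simple_traits({"A": {"x1": 0.5, "x2": 0.5}, "B": {"x1": 0.5, "x2": 0.5},
                           "C": {"x1": 1.0, "x2": 0.0}})
        d = biomon.gower_distance(t)
        assert d.d[0, 1] == 0.0

    def test_opposite_binary_one(self):
        t = simple_traits({"A": {"x1": 1.0, "x2": 0.0}, "B": {"x1": 0.0, "x2": 1.0}})
        assert biomon.gower_distance(t).d[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, traits):
        sub = TraitDataset(
            traits.data.iloc[:10], traits.ranks.iloc[:10], traits.blocks
        )
        d = biomon.gower_distance(sub).d
        assert np.allclose(d, gower_oracle(sub), atol=1e-12)

    def test_all_missing_row_errors(self):
        t = simple_traits({"A": {"x1": 1.0, "x2": 0.0}, "B": {"x1": 0.0, "x2": 0.0}})
        with pytest.raises(ArgumentError, match="B"):
            biomon.gower_distance(t)


class TestPcoa:
    def line_dist(self):
        # points at 0, 1, 3 on a line
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        return DistanceMatrix(["A", "B", "C"], d, "euclidean")

    def test_line_reconstructs_exactly(self):
        space = pcoa(self.line_dist())
        got = np.sqrt(
            ((space.coordinates[:, None, :] - space.coordinates[None, :, :]) ** 2).sum(-1)
        )
        assert np.allclose(got, self.line_dist().d, atol=1e-8)

    def test_line_correction_constants_zero(self):
        for corr in ("cailliez", "lingoes"):
            space = pcoa(self.line_dist(), corr)
            assert space.correction_constant == pytest.approx(0.0, abs=1e-8)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        space = pcoa(DistanceMatrix(["A", "B", "C"], d))
        assert space.coordinates.shape[1] == 2
        got = np.sqrt(
            ((space.coordinates[:, None, :] - space.coordinates[None, :, :]) ** 2).sum(-1)
        )
        assert np.allclose(got[~np.eye(3, dtype=bool)], 1.0, atol=1e-8)

    def _non_euclidean(self):
        # violates the triangle inequality -> negative eigenvalues
        d = np.array([
            [0.0, 1.0, 1.0, 1.9],
            [1.0, 0.0, 1.0, 0.2],
            [1.0, 1.0, 0.0, 1.0],
            [1.9, 0.2, 1.0, 0.0],
        ])
        return DistanceMatrix(list("ABCD"), d)

    @pytest.mark.parametrize("corr", ["cailliez", "lingoes", "sqrt"])
    def test_corrections_remove_negative_eigenvalues(self, corr):
        dist = self._non_euclidean()
        raw = pcoa(dist)
        assert raw.eigenvalues.min() < -1e-8  # fixture really is non-Euclidean
        fixed = pcoa(dist, corr)
        tol = 1e-8 * max(1.0, abs(fixed.eigenvalues).max())
        if corr == "sqrt":
            # sqrt is a heuristic; only check it helps here
            assert fixed.eigenvalues.min() >= raw.eigenvalues.min() - tol
        else:
            assert fixed.eigenvalues.min() >= -tol

    def test_quasi_drops_negative_axes(self):
        space = pcoa(self._non_euclidean(), "quasi")
        assert space.coordinates.shape[1] == int((space.eigenvalues > 1e-10).sum())

    def test_non_symmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(Exception):
            DistanceMatrix(["A", "B"], d)


class TestSelectAxes:
    def euclidean_dist(self, seed=0, n=8, k=4):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, k))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix([f"t{i}" for i in range(n)], d, "euclidean")

    def test_full_rank_perfect(self):
        dist = self.euclidean_dist()
        quality, _, _ = select_pcoa_axes(dist)
        last = quality.iloc[-1]
        assert last["corr"] == pytest.approx(1.0, abs=1e-8)
        assert last["r2"] == pytest.approx(1.0, abs=1e-12)
        assert last["msd"] == pytest.approx(0.0, abs=1e-12)

    def test_r2_eigenvalue_ratio(self):
        space = TraitSpace(["a", "b"], np.zeros((2, 1)), np.array([3.0, 1.0]))
        # r2 at m=1 for eigenvalues (3,1) is 0.75; check through the API
        dist = self.euclidean_dist()
        quality, _, space = select_pcoa_axes(dist)
        pos = space.eigenvalues[space.eigenvalues > 0]
        for _, row in quality.iterrows():
            assert row["r2"] == pytest.approx(
                pos[: int(row["m"])].sum() / pos.sum(), abs=1e-12
            )

    def test_msd_monotone_on_euclidean(self):
        quality, _, _ = select_pcoa_axes(self.euclidean_dist(3))
        msd = quality["msd"].to_numpy()
        assert (np.diff(msd) <= 1e-10).all()

    def test_threshold_recommendation(self):
        quality, m, _ = select_pcoa_axes(self.euclidean_dist(), criterion="r2",
                                         threshold=0.5)
        assert quality.loc[quality["m"] == m, "r2"].iloc[0] >= 0.5
        assert (quality.loc[quality["m"] < m, "r2"] < 0.5).all()


def space_from_points(labels, pts):
    pts = np.asarray(pts, dtype=float)
    return TraitSpace(list(labels), pts, np.ones(pts.shape[1]))


class TestFRich:
    def test_triangle_shoelace(self, tiny_ref):
        space = space_from_points(
            ["Baetis", "Cloeon", "Baetidae"], [[0, 0], [1, 0], [0, 1]]
        )
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0], "Baetidae": [1.0]})
        res = biomon.f_rich(space, agg, m=2)
        # shoelace oracle
        x, y = zip(*[[0, 0], [1, 0], [0, 1]])
        area = 0.5 * abs(
            sum(x[i] * y[(i + 1) % 3] - x[(i + 1) % 3] * y[i] for i in range(3))
        )
        assert res.values["s1"] == pytest.approx(area, abs=1e-10)
        assert area == 0.5

    def test_collinear_flagged(self, tiny_ref):
        space = space_from_points(
            ["Baetis", "Cloeon", "Baetidae"], [[0, 0], [1, 0], [2, 0]]
        )
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0], "Baetidae": [1.0]})
        res = biomon.f_rich(space, agg, m=2)
        assert math.isnan(res.values["s1"])
        assert res.flags["s1"] in {"degenerate_hull", "too_few_taxa"}

    def test_interior_point_no_change(self, tiny_ref):
        pts = [[0, 0], [1, 0], [0, 1], [0.2, 0.2]]
        labels = ["Baetis", "Cloeon", "Baetidae", "Ephemeroptera"]
        space = space_from_points(labels, pts)
        agg3 = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0], "Baetidae": [1.0]})
        agg4 = make_agg(tiny_ref, {t: [1.0] for t in labels})
        v3 = biomon.f_rich(space, agg3, m=2).values["s1"]
        v4 = biomon.f_rich(space, agg4, m=2).values["s1"]
        assert v4 == pytest.approx(v3, abs=1e-10)

    def test_too_few_taxa_flag(self, tiny_ref):
        space = space_from_points(["Baetis", "Cloeon"], [[0, 0], [1, 1]])
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0]})
        res = biomon.f_rich(space, agg, m=2)
        assert math.isnan(res.values["s1"]) and res.flags["s1"] == "too_few_taxa"

    def test_monotone_under_superset(self, agg, traits):
        d = biomon.gower_distance(traits)
        space = pcoa(d, "cailliez")
        full = biomon.f_rich(space, agg, m=2)
        # removing taxa can only shrink the hull
        table = agg.taxa_table.df
        reduced = table.copy()
        drop = [t for t in reduced.index if t in space.labels][:3]
        reduced.loc[drop] = 0.0
        agg2 = biomon.AggregatedCommunity(
            dict(agg.per_rank), biomon.CommunityMatrix(reduced),
            agg.reference, agg.match_report, agg.samples,
        )
        sub = biomon.f_rich(space, agg2, m=2)
        for s in agg.samples:
            if not (math.isnan(full.values[s]) or math.isnan(sub.values[s])):
                assert sub.values[s] <= full.values[s] + 1e-10

    def test_m_cap(self, tiny_ref):
        space = space_from_points(["Baetis"], np.zeros((1, 8)))
        agg = make_agg(tiny_ref, {"Baetis": [1.0]})
        with pytest.raises(ArgumentError):
            biomon.f_rich(space, agg, m=7)


class TestFDisp:
    def test_single_taxon_zero(self, tiny_ref):
        space = space_from_points(["Baetis"], [[0.0, 0.0]])
        agg = make_agg(tiny_ref, {"Baetis": [5.0]})
        assert biomon.f_disp(space, agg).values["s1"] == 0.0

    def test_two_equal_taxa(self, tiny_ref):
        space = space_from_points(["Baetis", "Cloeon"], [[0.0], [1.0]])
        agg = make_agg(tiny_ref, {"Baetis": [2.0], "Cloeon": [2.0]})
        assert biomon.f_disp(space, agg).values["s1"] == pytest.approx(0.5)

    def test_rotation_invariance(self, tiny_ref):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [0.3, 2.0]])
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        labels = ["Baetis", "Cloeon", "Baetidae"]
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [2.0], "Baetidae": [3.0]})
        v1 = biomon.f_disp(space_from_points(labels, pts), agg).values["s1"]
        v2 = biomon.f_disp(space_from_points(labels, pts @ rot.T), agg).values["s1"]
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestFEve:
    def test_perfectly_even_chain(self, tiny_ref):
        labels = ["Baetis", "Cloeon", "Baetidae", "Ephemeroptera"]
        space = space_from_points(labels, [[0.0], [1.0], [2.0], [3.0]])
        agg = make_agg(tiny_ref, {t: [1.0] for t in labels})
        assert biomon.f_eve(space, agg).values["s1"] == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_three_nan(self, tiny_ref):
        space = space_from_points(["Baetis", "Cloeon"], [[0.0], [1.0]])
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0]})
        res = biomon.f_eve(space, agg)
        assert math.isnan(res.values["s1"]) and res.flags["s1"] == "fewer_than_3_taxa"

    def test_in_unit_interval_random(self, agg, traits):
        space = pcoa(biomon.gower_distance(traits), "cailliez")
        res = biomon.f_eve(space, agg, m=3)
        for v in res.values:
            if not math.isnan(v):
                assert 0.0 - 1e-12 <= v <= 1.0 + 1e-12


def rao_oracle(d, p):
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * d[i, j]
    return q


class TestRaoRedundancy:
    def test_single_taxon_zero(self, tiny_ref):
        dist = DistanceMatrix(["Baetis"], np.zeros((1, 1)))
        agg = make_agg(tiny_ref, {"Baetis": [4.0]})
        assert biomon.f_divs(dist, agg).values["s1"] == 0.0

    def test_two_taxa_half(self, tiny_ref):
        dist = DistanceMatrix(["Baetis", "Cloeon"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [1.0]})
        assert biomon.f_divs(dist, agg).values["s1"] == pytest.approx(0.5)

    def test_matches_double_loop(self, agg, traits):
        dist = biomon.gower_distance(traits)
        res = biomon.f_divs(dist, agg)
        table = agg.taxa_table.df
        covered = [t for t in table.index if t in dist.labels]
        for s in agg.samples:
            col = table.loc[covered, s]
            present = col[col > 0]
            p = (present / present.sum()).to_numpy()
            ii = [dist.labels.index(t) for t in present.index]
            expected = rao_oracle(dist.d[np.ix_(ii, ii)], p)
            assert res.values[s] == pytest.approx(expected, abs=1e-10)

    def test_q_bounded_by_max_distance(self, agg, traits):
        dist = biomon.gower_distance(traits)
        res = biomon.f_divs(dist, agg)
        assert (res.values.dropna() <= dist.d.max() + 1e-12).all()

    def test_redundancy_zero_when_all_distinct(self, tiny_ref):
        d = np.ones((3, 3)) - np.eye(3)
        dist = DistanceMatrix(["Baetis", "Cloeon", "Baetidae"], d)
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [2.0], "Baetidae": [3.0]})
        assert biomon.f_red(dist, agg).values["s1"] == pytest.approx(0.0, abs=1e-12)

    def test_redundancy_equals_ginisimpson_when_identical(self, tiny_ref):
        dist = DistanceMatrix(["Baetis", "Cloeon"], np.zeros((2, 2)))
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [3.0]})
        gs = 1 - (0.25**2 + 0.75**2)
        assert biomon.f_red(dist, agg).values["s1"] == pytest.approx(gs)

    def test_redundancy_non_negative(self, agg, traits):
        res = biomon.f_red(biomon.gower_distance(traits), agg)
        assert (res.values.dropna() >= -1e-10).all()


class TestCwmCsi:
    def test_single_taxon_profile(self, tiny_ref):
        t = simple_traits({"Baetis": {"x1": 0.25, "x2": 0.75}})
        agg = make_agg(tiny_ref, {"Baetis": [9.0]})
        out = biomon.cwm(t, agg)
        assert np.allclose(out.loc["s1"], [0.25, 0.75])

    def test_weighted_mean_frozen(self, tiny_ref):
        # modality values (2,4)/6 vs (4,2)/6 weighted 1:3
        t = simple_traits({"Baetis": {"x1": 1.0, "x2": 0.0},
                           "Cloeon": {"x1": 0.0, "x2": 1.0}})
        agg = make_agg(tiny_ref, {"Baetis": [1.0], "Cloeon": [3.0]})
        out = biomon.cwm(t, agg)
        assert out.loc["s1", "x1"] == pytest.approx(0.25)
        assert out.loc["s1", "x2"] == pytest.approx(0.75)

    def test_block_sums_preserved(self, agg, traits):
        out = biomon.cwm(traits, agg)
        for mods in traits.blocks.values():
            sums = out[mods].sum(axis=1).dropna()
            assert np.allclose(sums, 1.0)

    def test_tsi_extremes(self):
        t = simple_traits(
            {"Spec": {"x1": 1.0, "x2": 0.0, "x3": 0.0},
             "Gen": {"x1": 1.0, "x2": 1.0, "x3": 1.0}},
            blocks={"t": ["x1", "x2", "x3"]},
        )
        scores = biomon.tsi(t)
        assert scores["Spec"] == pytest.approx(1.0)
        assert scores["Gen"] == pytest.approx(0.0)

    def test_csi_within_tsi_bounds(self, agg, traits):
        scores = biomon.tsi(traits).dropna()
        res = biomon.csi(traits, agg)
        for v in res.values.dropna():
            assert scores.min() - 1e-9 <= v <= scores.max() + 1e-9


class TestFuzzyTraitRatio:
    def test_num_equals_den_one(self, tiny_ref, traits):
        agg = make_agg(tiny_ref, {"Baetis": [1.0]})
        t = simple_traits({"Baetis": {"x1": 0.3, "x2": 0.7}})
        res = biomon.fuzzy_trait_ratio(t, agg, ["x1", "x2"], ["x1", "x2"])
        assert res.values["s1"] == pytest.approx(1.0)

    def test_single_taxon_quarter(self, tiny_ref):
        t = simple_traits({"Baetis": {"x1": 0.25, "x2": 0.75}})
        agg = make_agg(tiny_ref, {"Baetis": [1.0]})
        res = biomon.fuzzy_trait_ratio(t, agg, ["x1"], ["x1", "x2"])
        assert res.values["s1"] == pytest.approx(0.25)

    def test_zero_denominator_nan(self, tiny_ref):
        t = simple_traits(
            {"Baetis": {"x1": 1.0, "x2": 0.0, "y1": 1.0}},
            blocks={"x": ["x1", "x2"], "y": ["y1"]},
        )
        agg = make_agg(tiny_ref, {"Baetis": [1.0]})
        res = biomon.fuzzy_trait_ratio(t, agg, ["x1"], ["x2"])
        assert math.isnan(res.values["s1"]) and res.flags["s1"] == "zero_denominator"

    def test_flow_t_dispatches(self, agg, traits):
        res = biomon.flow_t(traits, agg, flow_block="flow")
        assert res.index_name == "flow_t"
        assert (res.values.dropna() <= 1.0 + 1e-12).all()


class TestAbundanceRescalingInvariance:
    def test_weighted_indices_invariant(self, agg, traits):
        dist = biomon.gower_distance(traits)
        space = pcoa(dist, "cailliez")
        scaled = biomon.AggregatedCommunity(
            {r: biomon.CommunityMatrix(cm.df * 11.0) for r, cm in agg.per_rank.items()},
            biomon.CommunityMatrix(agg.taxa_table.df * 11.0),
            agg.reference, agg.match_report, agg.samples,
        )
        pairs = [
            (biomon.f_disp(space, agg, m=2), biomon.f_disp(space, scaled, m=2)),
            (biomon.f_divs(dist, agg), biomon.f_divs(dist, scaled)),
            (biomon.csi(traits, agg), biomon.csi(traits, scaled)),
        ]
        for a, b in pairs:
            assert np.allclose(a.values, b.values, atol=1e-12, equal_nan=True)
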