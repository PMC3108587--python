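import math

import numpy as np
import pandas as pd
import pytest

from parvapop.errors import InputError, ParameterError
from parvapop.popio import PopulationMap
from parvapop.spatial import (
    classical_mds,
    geo_distance_matrix,
    ibd_regressions,
    mantel_test,
)


def popmap_from(coords):
    rows = []
    for i, (pop, lat, lon) in enumerate(coords):
        rows.append({"id": f"i{i}", "population": pop, "group": "invasive", "lat": lat, "lon": lon})
    return PopulationMap(table=pd.DataFrame(rows).set_index("id"))


class TestGeoDistances:
    def test_identical_coordinates_zero(self):
        pm = popmap_from([("A", 10, 20), ("B", 10, 20)])
        assert geo_distance_matrix(pm).loc["A", "B"] == 0.0

    def test_axis_aligned_euclidean_degrees(self):
        pm = popmap_from([("A", 0, 0), ("B", 0, 3)])
        assert geo_distance_matrix(pm).loc["A", "B"] == pytest.approx(3.0)

    def test_haversine_quarter_circle(self):
        pm = popmap_from([("A", 0, 0), ("B", 0, 90)])
        d = geo_distance_matrix(pm, mode="haversine_km").loc["A", "B"]
        assert d == pytest.approx(6371.0 * math.pi / 2, rel=1e-6)

    def test_missing_coordinates_named(self):
        pm = popmap_from([("A", 0, 0), ("B", float("nan"), 1)])
        with pytest.raises(InputError, match="B"):
            geo_distance_matrix(pm)


def random_distance_frames(rng, n=6):
    labels = [f"P{i}" for i in range(n)]
    def rand():
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        return pd.DataFrame(m + m.T, index=labels, columns=labels)
    return rand(), rand()


class TestMantel:
    def test_self_correlation_maximal(self, rng):
        g, _ = random_distance_frames(rng)
        res = mantel_test(g, g, transform="none", nperm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_r_matches_offdiagonal_pearson(self, rng):
        g, e = random_distance_frames(rng, n=4)
        res = mantel_test(g, e, transform="none", nperm=99, seed=2)
        iu = np.triu_indices(4, 1)
        expected = np.corrcoef(g.to_numpy()[iu], e.to_numpy()[iu])[0, 1]
        assert res.r == pytest.approx(expected)

    def test_agrees_with_reference_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        _, e = random_distance_frames(rng, n=8)
        noise, _ = random_distance_frames(rng, n=8)
        g = e + 0.3 * noise  # genuine correlation: stable small p
        res = mantel_test(g, e, transform="none", nperm=999, seed=3)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(g.to_numpy(), ids=list(g.index)),
            DistanceMatrix(e.to_numpy(), ids=list(e.index)),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)
        assert abs(res.p - float(p_ref)) < 0.02  # same null up to permutation noise

    def test_constant_matrix_rejected(self, rng):
        labels = list("ABCD")
        g = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=labels, columns=labels)
        _, e = random_distance_frames(rng, n=4)
        e.index = e.columns = labels
        with pytest.raises(InputError):
            mantel_test(g, e, transform="none", nperm=99, seed=4)

    def test_too_few_populations_rejected(self, rng):
        g, e = random_distance_frames(rng, n=3)
        with pytest.raises(ParameterError):
            mantel_test(g, e, transform="none")

    def test_log_transform_handles_zero_fst(self, rng):
        g, e = random_distance_frames(rng, n=5)
        g.iloc[0, 1] = g.iloc[1, 0] = 0.0
        res = mantel_test(g, e, transform="log10_fst", nperm=99, seed=5)
        assert np.isfinite(res.r)


class TestIbdRegressions:
    def _inputs(self, rng, slope=0.0):
        pops = [f"P{i}" for i in range(6)]
        coords = [(p, 45.0, float(i * 2)) for i, p in enumerate(pops)]
        pm = popmap_from(coords)
        geo = geo_distance_matrix(pm)
        fst = geo * slope + 0.01
        np.fill_diagonal(fst.values, 0.0)
        records = pd.DataFrame(
            {
                "H": rng.uniform(0, 1, 6),
                "pi": rng.uniform(0, 0.01, 6),
            },
            index=pops,
        )
        return pm, fst, records, geo

    def test_perfectly_linear_response(self, rng):
        _, fst, records, geo = self._inputs(rng, slope=0.02)
        regs = ibd_regressions("P0", fst, records, geo)
        fst_reg = next(r for r in regs if r.response == "fst_from_source")
        assert fst_reg.r_squared == pytest.approx(1.0)
        assert fst_reg.slope == pytest.approx(0.02)

    def test_closed_form_three_points(self):
        from scipy import stats as ss

        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 4.0])
        # normal equations by hand
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        res = ss.linregress(x, y)
        assert res.slope == pytest.approx(slope)

    def test_exclusions_change_sample_size(self, rng):
        _, fst, records, geo = self._inputs(rng)
        full = ibd_regressions("P0", fst, records, geo)
        part = ibd_regressions("P0", fst, records, geo, exclude=["P5"])
        assert part[0].n == full[0].n - 1

    def test_missing_source_rejected(self, rng):
        _, fst, records, geo = self._inputs(rng)
        with pytest.raises(InputError):
            ibd_regressions("XX", fst, records, geo)


class TestClassicalMds:
    def test_all_zero_matrix_maps_to_origin(self):
        labels = list("ABC")
        d = pd.DataFrame(np.zeros((3, 3)), index=labels, columns=labels)
        with pytest.warns(UserWarning):
            coords = classical_mds(d)
        assert np.allclose(coords.to_numpy(), 0)

    def test_collinear_points_recovered_in_1d(self):
        labels = list("abc")
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=labels, columns=labels, dtype=float
        )
        coords = classical_mds(d, dims=1)
        x = coords["dim1"].to_numpy()
        assert np.allclose(np.abs(np.diff(np.sort(x))), [1.0, 1.0])

    def test_euclidean_round_trip_after_procrustes(self, rng):
        from scipy.spatial import procrustes

        X = rng.normal(size=(7, 2))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = [f"P{i}" for i in range(7)]
        Y = classical_mds(pd.DataFrame(D, index=labels, columns=labels)).to_numpy()
        _, _, disparity = procrustes(X, Y)
        assert disparity < 1e-8

    def test_permutation_invariance_after_procrustes(self, rng):
        from scipy.spatial import procrustes

        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = [f"P{i}" for i in range(6)]
        a = classical_mds(pd.DataFrame(D, index=labels, columns=labels)).to_numpy()
        order = rng.permutation(6)
        b = classical_mds(
            pd.DataFrame(D[np.ix_(order, order)], index=[labels[i] for i in order],
                         columns=[labels[i] for i in order])
        ).to_numpy()
        inv = np.argsort(order)
        _, _, disparity = procrustes(a, b[inv])
        assert disparity < 1e-12
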