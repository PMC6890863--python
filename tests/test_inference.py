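import numpy as np
import pandas as pd
import pytest

from tonguefan.inference import (
    DiffCurve,
    IntervalSet,
    difference_curve,
    enumerate_comparisons,
    group_average_spline,
    interval_coverage,
    significant_regions,
)
from tonguefan.smoothing import ModelSpec, fit
from tests.conftest import two_condition_frame


def make_curve(theta, est, se):
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    return DiffCurve(
        theta=np.asarray(theta, dtype=float),
        estimate=est,
        se=se,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
    )


class TestDifferenceCurve:
    @pytest.fixture(scope="class")
    def bump_fit(self):
        df = two_condition_frame(n_contours=30, diff_amplitude=10.0, seed=21)
        return fit(ModelSpec(factor="cond", factor_levels=("A", "B")), df)

    def test_identity_contrast(self, bump_fit):
        c = difference_curve(bump_fit, "A", "A")
        assert np.all(c.estimate == 0) and np.all(c.se == 0)

    def test_recovers_injected_difference(self, bump_fit):
        c = difference_curve(bump_fit, "B", "A")
        truth = 10.0 * np.exp(-0.5 * ((c.theta + 2.3) / 0.18) ** 2)
        inside = (c.ci_low <= truth) & (truth <= c.ci_high)
        assert inside.mean() >= 0.90

    def test_se_matches_dense_oracle(self, bump_fit):
        grid = np.linspace(-2.5, -1.0, 20)
        c = difference_curve(bump_fit, "B", "A", grid=grid)
        info = bump_fit.design
        rows_a = info.rows(pd.DataFrame({"theta": grid, "cond": "B"}), include_random=False)
        rows_b = info.rows(pd.DataFrame({"theta": grid, "cond": "A"}), include_random=False)
        Cm = rows_a - rows_b
        expect = np.sqrt(np.diag(Cm @ bump_fit.Vb @ Cm.T))
        assert np.abs(c.se - expect).max() < 1e-8

    def test_simultaneous_wider_than_pointwise(self, bump_fit):
        cp = difference_curve(bump_fit, "B", "A", seed=1)
        cs = difference_curve(bump_fit, "B", "A", simultaneous=True, seed=1)
        assert np.all(cs.ci_high - cs.ci_low >= cp.ci_high - cp.ci_low)

    def test_unknown_level_error(self, bump_fit):
        with pytest.raises(ValueError, match="unknown"):
            difference_curve(bump_fit, "A", "Z")


class TestSignificantRegions:
    def test_straddling_zero_everywhere(self):
        th = np.linspace(-2.5, -0.5, 50)
        c = make_curve(th, np.zeros(50), np.ones(50))
        assert len(significant_regions(c)) == 0

    def test_single_localized_excursion(self):
        th = np.linspace(-2.5, -0.5, 201)
        est = np.where((th >= -2.5) & (th <= -2.0), 5.0, 0.0)
        c = make_curve(th, est, np.full(201, 0.01))
        regions = significant_regions(c)
        assert len(regions) == 1
        (lo, hi), = regions
        assert lo == pytest.approx(-2.5, abs=0.02)
        assert hi == pytest.approx(-2.0, abs=0.02)

    def test_two_disjoint_excursions(self):
        th = np.linspace(-2.5, -0.5, 201)
        est = np.zeros(201)
        est[(th >= -2.4) & (th <= -2.1)] = 5.0
        est[(th >= -1.0) & (th <= -0.8)] = -5.0
        c = make_curve(th, est, np.full(201, 0.01))
        regions = significant_regions(c)
        assert len(regions) == 2
        assert regions.intervals[0][1] < regions.intervals[1][0]


class TestIntervalSet:
    def test_invariants(self):
        with pytest.raises(ValueError):
            IntervalSet(((1.0, 1.0),))
        with pytest.raises(ValueError):
            IntervalSet(((0.0, 2.0), (1.0, 3.0)))

    def test_jaccard(self):
        a = IntervalSet(((0.0, 1.0),))
        b = IntervalSet(((0.5, 1.5),))
        assert a.jaccard(b) == pytest.approx(0.5 / 1.5)
        assert a.jaccard(a) == 1.0


class TestIntervalCoverage:
    def test_single_interval(self):
        s = IntervalSet(((-2.0, -1.0),))
        out = interval_coverage([s], 1)
        assert out.intervals == ((-2.0, -1.0),)

    def test_none_entries_ignored(self):
        s = IntervalSet(((-2.0, -1.0),))
        out = interval_coverage([s, None, None], 1)
        assert out.intervals == ((-2.0, -1.0),)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(33)
        for trial in range(100):
            sets = []
            for _ in range(rng.integers(1, 6)):
                ivs = []
                last = 0.0
                for _ in range(rng.integers(1, 4)):
                    lo = last + rng.uniform(0.01, 0.3)
                    hi = lo + rng.uniform(0.01, 0.3)
                    ivs.append((round(lo, 3), round(hi, 3)))
                    last = hi + 0.001
                sets.append(IntervalSet(tuple(ivs)))
            mc = int(rng.integers(1, len(sets) + 1))
            out = interval_coverage(sets, mc)
            # brute-force oracle on a fine grid
            grid = np.arange(0.0, 2.5, 1e-4)
            cov = np.zeros(grid.size, dtype=int)
            for s in sets:
                for a, b in s:
                    cov += (grid >= a) & (grid <= b)
            hits = cov >= mc
            for x, h in zip(grid[::7], hits[::7]):
                assert out.contains(round(float(x), 10)) == bool(h) or (
                    # grid points within 1e-4 of an endpoint may disagree
                    min(
                        [abs(x - e) for s in sets for iv in s for e in iv],
                        default=1.0,
                    )
                    < 2e-4
                )

    def test_monotone_in_min_count(self):
        rng = np.random.default_rng(7)
        sets = []
        for _ in range(6):
            lo = rng.uniform(0, 1)
            sets.append(IntervalSet(((lo, lo + rng.uniform(0.1, 1.0)),)))
        prev = None
        for mc in range(1, 7):
            out = interval_coverage(sets, mc)
            if prev is not None:
                assert out.total_length() <= prev.total_length() + 1e-12
            prev = out


class TestGroupAverage:
    def test_constant_predictions(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "theta": rng.uniform(-2.8, -0.5, 1000),
                "rho": 7.0 + 0.001 * rng.standard_normal(1000),
                "contour_id": np.repeat(np.arange(20), 50),
                "grp": np.tile(["x", "y"], 500),
            }
        )
        f = fit(ModelSpec(factor=None), df)
        out = group_average_spline(f, df, "grp")
        for _, (grid, vals) in out.items():
            assert np.abs(vals - 7.0).max() < 0.01

    def test_balanced_average_of_condition_smooths(self):
        df = two_condition_frame(n_contours=25, diff_amplitude=8.0, seed=40)
        df["grp"] = "all"
        f = fit(ModelSpec(factor="cond", factor_levels=("A", "B")), df)
        # n_points=50 makes the output grid coincide with the shared data grid
        out = group_average_spline(f, df, "grp", include_random=False, n_points=50)
        grid, vals = out["all"]
        nd_a = pd.DataFrame({"theta": grid, "cond": "A"})
        nd_b = pd.DataFrame({"theta": grid, "cond": "B"})
        from tonguefan.smoothing import predict

        mean_cond = 0.5 * (predict(f, nd_a)[0] + predict(f, nd_b)[0])
        assert np.abs(vals - mean_cond).max() < 1e-3

    def test_disjoint_ranges_keep_own_support(self):
        rng = np.random.default_rng(3)
        th1 = np.linspace(-2.8, -1.8, 50)
        th2 = np.linspace(-1.5, -0.5, 50)
        rows = []
        for c in range(10):
            rows.append(pd.DataFrame({"theta": th1, "rho": 5 + 0.1 * rng.standard_normal(50),
                                      "contour_id": c, "grp": "post"}))
            rows.append(pd.DataFrame({"theta": th2, "rho": 5 + 0.1 * rng.standard_normal(50),
                                      "contour_id": 10 + c, "grp": "ant"}))
        df = pd.concat(rows, ignore_index=True)
        f = fit(ModelSpec(factor=None), df)
        out = group_average_spline(f, df, "grp")
        assert out["post"][0].max() <= -1.8 + 1e-9
        assert out["ant"][0].min() >= -1.5 - 1e-9


class TestEnumerateComparisons:
    @staticmethod
    def full_manifest(missing=(("NZE", "F4", "mezzopiano"),)):
        rows = []
        for lang in ("NZE", "Tongan"):
            for note in ("Bb2", "F3", "Bb3", "D4", "F4"):
                for inten in ("piano", "mezzopiano", "mezzoforte", "forte"):
                    if (lang, note, inten) in missing:
                        continue
                    rows.append({"language": lang, "category": note, "intensity": inten})
        return pd.DataFrame(rows)

    def test_study_design_counts(self):
        comps = enumerate_comparisons(self.full_manifest())
        assert len(comps) == 76
        assert (comps.language == "Tongan").sum() == 40
        assert (comps.language == "NZE").sum() == 36

    def test_minimal_case(self):
        m = pd.DataFrame(
            [
                {"language": "NZE", "category": "Bb2", "intensity": "piano"},
                {"language": "NZE", "category": "F3", "intensity": "piano"},
            ]
        )
        comps = enumerate_comparisons(m)
        assert len(comps) == 1
        assert comps.iloc[0][["note_a", "note_b"]].tolist() == ["Bb2", "F3"]

    def test_random_manifests_match_brute_force(self):
        rng = np.random.default_rng(55)
        notes = ["Bb2", "F3", "Bb3", "D4", "F4"]
        intens = ["piano", "mezzopiano", "mezzoforte", "forte"]
        for _ in range(30):
            rows = [
                {"language": lang, "category": n, "intensity": i}
                for lang in ("NZE", "Tongan")
                for n in notes
                for i in intens
                if rng.random() < 0.7
            ]
            m = pd.DataFrame(rows, columns=["language", "category", "intensity"])
            comps = enumerate_comparisons(m)
            cells = set(map(tuple, rows and m.values.tolist() or []))
            brute = 0
            for lang in ("NZE", "Tongan"):
                for i in intens:
                    avail = [n for n in notes if (lang, n, i) in cells]
                    brute += len(avail) * (len(avail) - 1) // 2
            assert len(comps) == brute

    def test_deterministic_ordering(self):
        comps = enumerate_comparisons(self.full_manifest())
        again = enumerate_comparisons(self.full_manifest().sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(comps, again)
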