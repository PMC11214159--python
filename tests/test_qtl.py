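"""BC1 QTL machinery: filtering, genoprobs, scans, permutations, intervals."""

import math

import numpy as np
import pandas as pd
import pytest

from sweepfoot.errors import (
    ConfigError, DegenerateModelError, EstimationError, InputError,
)
from sweepfoot.qtl import (
    CrossData, LodCurve, bayes_interval, filter_markers,
    genotype_probabilities, haldane_r, kosambi_d, kosambi_r, map_density,
    permutation_threshold, scan_lod, variance_explained,
)
from sweepfoot.simulate import BC1Config, gen_bc1


def tiny_cross(geno_rows, positions, phenos=None, lg=1):
    n, m = np.shape(geno_rows)
    ind = pd.Index([f"i{k}" for k in range(n)])
    markers = pd.Index([f"mk{j}" for j in range(m)], name="marker")
    cmap = pd.DataFrame({"lg": [lg] * m, "cM": positions}, index=markers)
    pheno = pd.DataFrame(phenos if phenos is not None else
                         {"y": np.zeros(n)}, index=ind)
    return CrossData(pd.DataFrame(geno_rows, index=ind, columns=markers),
                     cmap, pheno)


class TestFilterMarkers:
    def _cross_with_counts(self, nb, nh):
        col = np.array([0.0] * nb + [1.0] * nh)
        balanced = np.tile([0.0, 1.0], len(col) // 2 + 1)[:len(col)]
        return tiny_cross(np.column_stack([col, balanced]), [0.0, 10.0])

    def test_balanced_retained(self):
        out = filter_markers(self._cross_with_counts(66, 66))
        assert "mk0" in out.genotypes.columns

    def test_skewed_removed(self):
        # 90 b / 42 h: chi-square = 2*(24^2/66) ~ 17.45 > 3.841
        out = filter_markers(self._cross_with_counts(90, 42))
        assert "mk0" not in out.genotypes.columns

    def test_mildly_skewed_retained(self):
        # 76 b / 56 h: chi-square ~ 3.03 < 3.841
        out = filter_markers(self._cross_with_counts(76, 56))
        assert "mk0" in out.genotypes.columns

    def test_all_removed_raises(self):
        geno = np.zeros((40, 1))
        with pytest.raises(InputError):
            filter_markers(tiny_cross(geno, [0.0]))


class TestMapFunctions:
    def test_kosambi_round_trip(self):
        for d in (0.1, 5.0, 20.0, 80.0):
            assert kosambi_d(kosambi_r(d)) == pytest.approx(d)

    def test_r_bounded(self):
        assert kosambi_r(1e9) == pytest.approx(0.5)
        assert haldane_r(1e9) == pytest.approx(0.5)


class TestGenotypeProbabilities:
    def test_typed_marker_is_indicator(self):
        cross = tiny_cross([[1.0, 0.0], [0.0, 1.0]], [0.0, 20.0])
        glg, gpos, P = genotype_probabilities(cross, grid_step=1.0)
        at0 = np.flatnonzero(gpos == 0.0)[0]
        at20 = np.flatnonzero(gpos == 20.0)[0]
        assert P[0, at0] == 1.0 and P[0, at20] == 0.0
        assert P[1, at0] == 0.0 and P[1, at20] == 1.0

    def test_midpoint_matches_enumeration_oracle(self):
        cross = tiny_cross([[0.0, 1.0]], [0.0, 20.0])
        glg, gpos, P = genotype_probabilities(cross, grid_step=10.0)
        mid = np.flatnonzero(gpos == 10.0)[0]
        r = float(kosambi_r(10.0))
        # enumerate hidden genotype g with chain P(A=0)*t(0,g)*t(g,1)
        w_h = (1 - 0) * r * (1 - r)
        w_b = (1 - r) * r
        oracle = w_h / (w_h + w_b)
        assert P[0, mid] == pytest.approx(oracle)

    def test_missing_genotype_skipped_to_next_informative(self):
        cross = tiny_cross([[1.0, np.nan, 1.0]], [0.0, 10.0, 20.0])
        _, gpos, P = genotype_probabilities(cross, grid_step=10.0)
        # between two h markers with the middle one missing: still near 1
        assert P[0, np.flatnonzero(gpos == 10.0)[0]] > 0.9

    def test_zero_distance_flanks(self):
        cross = tiny_cross([[1.0, 1.0]], [5.0, 5.0])
        _, gpos, P = genotype_probabilities(cross, grid_step=1.0)
        assert np.allclose(P[0, gpos == 5.0], 1.0)

    def test_untyped_individual_gets_half(self):
        cross = tiny_cross([[np.nan, np.nan]], [0.0, 10.0])
        _, _, P = genotype_probabilities(cross, grid_step=5.0)
        assert np.allclose(P, 0.5)


class TestScanLod:
    def _fully_typed_cross(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        geno = (rng.random((n, 3)) < 0.5).astype(float)
        y = 0.8 * geno[:, 1] + rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)
        return tiny_cross(geno, [0.0, 10.0, 20.0],
                          phenos={"y": y + 0.5 * cov, "cov": cov})

    def test_matches_direct_regression_oracle(self):
        cross = self._fully_typed_cross()
        curve = scan_lod(cross, "y", "cov", grid_step=10.0)
        y = cross.phenotypes["y"].to_numpy()
        cov = cross.phenotypes["cov"].to_numpy()
        n = y.size
        for j, pos in enumerate([0.0, 10.0, 20.0]):
            g = cross.genotypes.iloc[:, j].to_numpy()
            X0 = np.column_stack([np.ones(n), cov])
            X1 = np.column_stack([X0, g])
            rss0 = np.linalg.lstsq(X0, y, rcond=None)[1][0]
            rss1 = np.linalg.lstsq(X1, y, rcond=None)[1][0]
            ref = n / 2 * math.log10(rss0 / rss1)
            at = np.flatnonzero(curve.cM == pos)[0]
            assert curve.lod[at] == pytest.approx(ref, abs=1e-8)

    def test_affine_invariance(self):
        cross = self._fully_typed_cross(1)
        base = scan_lod(cross, "y", "cov", grid_step=5.0).lod
        ph = cross.phenotypes.copy()
        ph["y"] = 3.0 * ph["y"] - 7.0
        ph["cov"] = -0.5 * ph["cov"] + 2.0
        scaled = CrossData(cross.genotypes, cross.map, ph)
        assert np.allclose(scan_lod(scaled, "y", "cov", grid_step=5.0).lod,
                           base, atol=1e-8)

    def test_constant_covariate_equals_no_covariate(self):
        cross = self._fully_typed_cross(2)
        ph = cross.phenotypes.copy()
        ph["const"] = 1.0
        cross2 = CrossData(cross.genotypes, cross.map, ph)
        with pytest.raises(DegenerateModelError):
            # constant covariate duplicates the intercept: flagged, not fit
            scan_lod(cross2, "y", "const", grid_step=5.0)
        a = scan_lod(cross, "y", None, grid_step=5.0).lod
        assert np.all(a >= 0)

    def test_duplicate_trait_covariate_degenerate(self):
        cross = self._fully_typed_cross(3)
        with pytest.raises(DegenerateModelError):
            scan_lod(cross, "y", "y", grid_step=5.0)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self):
        res = gen_bc1(BC1Config(seed=4, n_markers=56, n_lg=4,
                                total_cM=200.0, n_individuals=40))
        gp = genotype_probabilities(res.cross, grid_step=5.0)
        thr_min = permutation_threshold(res.cross, "head_width",
                                        "thorax_width", n_perm=50,
                                        alpha=1.0, seed=0, genoprob=gp)
        thr_05 = permutation_threshold(res.cross, "head_width",
                                       "thorax_width", n_perm=50,
                                       alpha=0.05, seed=0, genoprob=gp)
        assert thr_min <= thr_05

    def test_seed_determinism(self):
        res = gen_bc1(BC1Config(seed=5, n_markers=56, n_lg=4,
                                total_cM=200.0, n_individuals=40))
        args = dict(n_perm=60, seed=123,
                    genoprob=genotype_probabilities(res.cross, grid_step=5.0))
        a = permutation_threshold(res.cross, "head_width", "thorax_width", **args)
        b = permutation_threshold(res.cross, "head_width", "thorax_width", **args)
        assert a == b

    def test_bad_perm_count(self):
        res = gen_bc1(BC1Config(seed=6, n_markers=14, n_lg=2,
                                total_cM=100.0, n_individuals=30))
        with pytest.raises(ConfigError):
            permutation_threshold(res.cross, "head_width", None, n_perm=0)


class TestBayesInterval:
    def _curve(self, lod, lg=1):
        m = len(lod)
        return LodCurve(np.full(m, lg, dtype=object),
                        np.arange(m, dtype=float), np.asarray(lod, float))

    def test_delta_peak_single_cell(self):
        lod = np.zeros(11)
        lod[5] = 10.0
        lg, lo, hi = bayes_interval(self._curve(lod))
        assert (lo, hi) == (5.0, 5.0)

    def test_uniform_curve_covers_group(self):
        lg, lo, hi = bayes_interval(self._curve(np.ones(11)), prob=0.95)
        assert hi - lo >= 9.0

    def test_triangular_profile_matches_mass_enumeration(self):
        lod = np.array([0, .5, 1.5, 2.2, 4.8, 3.9, 2.1, 1.2, .3, .1, 0.])
        lg, lo, hi = bayes_interval(self._curve(lod), prob=0.9)
        w = 10.0 ** (lod - lod.max())
        w = w / w.sum()
        peak = int(np.argmax(lod))
        best = None
        for i in range(peak + 1):
            for j in range(peak, 11):
                if w[i:j + 1].sum() >= 0.9 and (
                        best is None or j - i < best[1] - best[0]):
                    best = (i, j)
        assert (lo, hi) == (float(best[0]), float(best[1]))

    def test_interval_widens_with_prob(self):
        lod = np.array([0, .5, 1.5, 2.2, 4.8, 3.9, 2.1, 1.2, .3, .1, 0.])
        widths = []
        for prob in (0.5, 0.8, 0.95, 0.99):
            _, lo, hi = bayes_interval(self._curve(lod), prob=prob)
            widths.append(hi - lo)
        assert widths == sorted(widths)

    def test_flat_zero_curve_undefined(self):
        with pytest.raises(EstimationError):
            bayes_interval(self._curve(np.zeros(5)))

    def test_multi_group_rejected(self):
        curve = LodCurve(np.array([1, 2], dtype=object),
                         np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(InputError):
            bayes_interval(curve)


class TestEffectSize:
    def test_zero_lod(self):
        assert variance_explained(0.0, 82) == 0.0

    def test_half_n(self):
        assert variance_explained(41.0, 82) == pytest.approx(0.9)

    def test_map_density(self):
        assert round(map_density(1533, 1790.0), 1) == 0.9
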