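"""Dimension spaces: complete-case filtering, PCA contracts, trophic indices."""

import numpy as np
import pandas as pd
import pytest

import isoniche as iso
from isoniche.dimensions import APPROACH_AXES, DimensionError
from isoniche.io import AA_C_COLUMNS


class TestCompleteCaseFilter:
    def test_identity_on_complete_data(self, community):
        assert len(iso.complete_case_filter(community)) == 63

    def test_single_missing_cell_drops_row(self, community):
        frame = community.frame.head(5).copy()
        frame.loc[2, "lys_n"] = np.nan
        out = iso.complete_case_filter(iso.IsotopeDataset(frame))
        assert len(out) == 4
        assert community.frame.loc[2, "sample_id"] not in set(out.sample_ids)

    def test_randomized_missingness_matches_row_scan(self):
        ds = iso.generate_community(
            [iso.SpeciesSpec("sp", 100, np.zeros(5), np.eye(5))],
            iso.default_tracer_map(), seed=2)
        frame = ds.frame.copy()
        rng = np.random.default_rng(0)
        rows = rng.choice(100, size=11, replace=False)
        cols = list(AA_C_COLUMNS) + ["bulk_s"]
        # one hole in each of the 11 rows, then 6 extra holes among them
        holes = {(int(r), str(rng.choice(cols))) for r in rows}
        while len(holes) < 17:
            holes.add((int(rng.choice(rows)), str(rng.choice(cols))))
        for r, c in holes:
            frame.loc[r, c] = np.nan
        # independent brute-force row scan
        expected = sum(
            1 for i in range(100)
            if not any((i, c) in holes for c in cols))
        out = iso.complete_case_filter(iso.IsotopeDataset(frame))
        assert len(out) == expected == 89

    def test_all_missing_raises(self, community):
        frame = community.frame.copy()
        frame["bulk_s"] = np.nan
        with pytest.raises(DimensionError, match="no complete-case"):
            iso.complete_case_filter(iso.IsotopeDataset(frame))


class TestFitPca:
    def test_isotropic_data_splits_variance_evenly(self):
        x = np.random.default_rng(1).standard_normal((50_000, 10))
        model = iso.fit_pca(x)
        assert np.all(np.abs(model.explained_fraction - 0.1) < 0.02)

    def test_rank_one_two_column_case(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(200)
        model = iso.fit_pca(np.column_stack([a, 2 * a + 1]))
        assert model.explained_fraction[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.contributions_pct[:, 0], [50, 50], atol=1e-8)

    def test_orthonormal_loadings_and_contribution_sums(self, filtered):
        model = iso.fit_pca(filtered.aa_d13c.to_numpy(), AA_C_COLUMNS)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(10), atol=1e-8)
        assert np.all(np.diff(model.explained_fraction) <= 1e-12)
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.contributions_pct.sum(axis=0), 100.0, atol=1e-6)

    def test_reconstruction_and_scale_invariance(self, filtered):
        x = filtered.aa_d13c.to_numpy()
        model = iso.fit_pca(x)
        z = (x - model.center) / model.scale
        scores = model.transform(x)
        assert np.allclose(scores @ model.loadings.T, z, atol=1e-8)
        scaled = x.copy()
        scaled[:, 3] *= 7.5
        assert np.allclose(iso.fit_pca(scaled).transform(scaled), scores, atol=1e-8)

    def test_row_permutation_leaves_loadings_unchanged(self, filtered):
        x = filtered.aa_d15n.to_numpy()
        perm = np.random.default_rng(5).permutation(len(x))
        m1, m2 = iso.fit_pca(x), iso.fit_pca(x[perm])
        assert np.allclose(m1.loadings, m2.loadings, atol=1e-8)

    def test_zero_variance_column_names_the_amino_acid(self, filtered):
        x = filtered.aa_d13c.to_numpy().copy()
        x[:, 5] = -24.0
        with pytest.raises(DimensionError, match="pro_c"):
            iso.fit_pca(x, AA_C_COLUMNS)


class TestBuildDimensionSpace:
    @pytest.mark.parametrize("approach,axes", list(APPROACH_AXES.items()))
    def test_axis_sets_match_the_approach_exactly(self, filtered, approach, axes):
        space, _, _ = iso.build_dimension_space(filtered, approach)
        assert space.axis_names == axes
        assert space.coords.shape == (63, len(axes))

    def test_std_sulphur_is_standardized(self, space_5d):
        col = space_5d.coords[:, space_5d.axis_names.index("stdDeltaS")]
        assert abs(col.mean()) < 1e-8
        assert col.var(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_unknown_approach_lists_valid_labels(self, filtered):
        with pytest.raises(DimensionError, match="1D.*2D.*3D.*5D"):
            iso.build_dimension_space(filtered, "4D")


class TestTrophicIndices:
    def test_formula_algebra(self, community):
        frame = community.frame.head(3).copy()
        frame.loc[0, "glx_n"] = frame.loc[0, "phe_n"] = 12.0
        frame.loc[1, "glx_n"] = 15.0
        frame.loc[1, "lys_n"] = 9.0
        # glx - phe = beta + tdf  =>  TP exactly 2
        frame.loc[2, "phe_n"] = frame.loc[2, "glx_n"] - (3.4 + 7.6)
        out = iso.trophic_indices(iso.IsotopeDataset(frame), beta=3.4, tdf=7.6)
        assert out.loc[0, "glx_minus_phe"] == 0.0
        assert out.loc[0, "tp_single"] == pytest.approx(1 - 3.4 / 7.6)
        assert out.loc[1, "glx_minus_lys"] == pytest.approx(6.0)
        assert out.loc[2, "tp_single"] == pytest.approx(2.0)

    def test_zero_tdf_rejected(self, community):
        with pytest.raises(DimensionError, match="tdf"):
            iso.trophic_indices(community, tdf=0.0)


class TestValidateProxies:
    def test_self_and_anti_correlation(self, space_5d, filtered):
        report = iso.validate_proxies(space_5d, filtered)
        pc1c = space_5d.coords[:, 0]
        bulk_c = filtered.frame["bulk_c"].to_numpy()
        r = np.corrcoef(pc1c, bulk_c)[0, 1]
        got = report.query("axis == 'PC1-Css' and target == 'bulk_c'")["r"].iloc[0]
        assert got == pytest.approx(r, abs=1e-12)
        assert got == pytest.approx(-np.corrcoef(-pc1c, bulk_c)[0, 1], abs=1e-12)

    def test_planted_bulk_proxy_correlation(self):
        # bulk values are exact uniform AA means: PC1 must be a near-perfect proxy
        tm = iso.default_tracer_map()
        tm.bulk_c_noise_sd = tm.bulk_n_noise_sd = 0.0
        specs = [
            iso.SpeciesSpec("lo", 50, [-2, 0, -2, 0, 0], 0.3 * np.eye(5)),
            iso.SpeciesSpec("hi", 50, [2, 0, 2, 0, 0], 0.3 * np.eye(5)),
        ]
        ds = iso.generate_community(specs, tm, seed=17)
        space, _, _ = iso.build_dimension_space(iso.complete_case_filter(ds), "2D")
        report = iso.validate_proxies(space, ds)
        r_c = report.query("axis == 'PC1-Css' and target == 'bulk_c'")["abs_r"].iloc[0]
        r_n = report.query("axis == 'PC1-Nss' and target == 'bulk_n'")["abs_r"].iloc[0]
        assert r_c > 0.95 and r_n > 0.95

    def test_too_few_samples_rejected(self, community):
        tiny = community.subset(np.arange(63) < 2)
        space, _, _ = iso.build_dimension_space(
            iso.complete_case_filter(community), "2D")
        with pytest.raises(DimensionError):
            iso.validate_proxies(space, tiny)
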