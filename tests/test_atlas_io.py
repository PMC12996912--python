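"""Atlas/connectome/cohort I-O: parsing, validation, and region-order law."""

import numpy as np
import pandas as pd
import pytest

import corticov as cv


def _write_atlas_csv(path, rows):
    pd.DataFrame(rows, columns=["region_name", "hemisphere", "x", "y", "z"]).to_csv(
        path, index=False
    )


class TestReadAtlas:
    def test_four_region_file(self, tmp_path):
        p = tmp_path / "atlas.csv"
        _write_atlas_csv(
            p,
            [
                ("l1", "L", -2.0, 0.0, 0.0),   # non-unit: must be renormalized
                ("l2", "L", -1.0, 1.0, 0.0),
                ("r1", "R", 2.0, 0.0, 0.0),
                ("r2", "R", 1.0, 1.0, 0.0),
            ],
        )
        atlas = cv.read_atlas(p)
        assert atlas.n_regions == 4
        assert np.allclose(np.linalg.norm(atlas.centroids, axis=1), 1.0)
        assert atlas.region_names == ("l1", "l2", "r1", "r2")

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "atlas.csv"
        _write_atlas_csv(
            p,
            [("a", "L", -1, 0, 0), ("a", "L", -1, 1, 0),
             ("b", "R", 1, 0, 0), ("c", "R", 1, 1, 0)],
        )
        with pytest.raises(ValueError, match="duplicate"):
            cv.read_atlas(p)

    def test_unbalanced_hemispheres_rejected(self, tmp_path):
        p = tmp_path / "atlas.csv"
        _write_atlas_csv(
            p,
            [("a", "L", -1, 0, 0), ("b", "L", -1, 1, 0),
             ("c", "L", -1, 0, 1), ("d", "R", 1, 0, 0)],
        )
        with pytest.raises(ValueError, match="hemisphere"):
            cv.read_atlas(p)

    def test_nonfinite_coordinates_rejected(self, tmp_path):
        p = tmp_path / "atlas.csv"
        _write_atlas_csv(
            p,
            [("a", "L", np.nan, 0, 0), ("b", "L", -1, 1, 0),
             ("c", "R", 1, 0, 0), ("d", "R", 1, 1, 0)],
        )
        with pytest.raises(ValueError, match="finite"):
            cv.read_atlas(p)

    def test_roundtrip_68_regions(self, tmp_path, atlas68):
        p = tmp_path / "atlas.csv"
        cv.write_atlas(atlas68, p)
        back = cv.read_atlas(p)
        assert back.region_names == atlas68.region_names
        assert back.hemispheres == atlas68.hemispheres
        assert np.max(np.abs(back.centroids - atlas68.centroids)) < 1e-12


class TestReadConnectome:
    def test_identity_labelled_matrix_unchanged(self, tmp_path, atlas4):
        w = np.array(
            [[0, 0.5, 0.2, 0.1], [0.5, 0, 0.3, 0.2],
             [0.2, 0.3, 0, 0.4], [0.1, 0.2, 0.4, 0]]
        )
        p = tmp_path / "conn.csv"
        names = list(atlas4.region_names)
        pd.DataFrame(w, index=names, columns=names).to_csv(p)
        conn = cv.read_connectome(p, atlas4)
        assert np.allclose(conn.weights, w)

    def test_permuted_columns_reordered(self, tmp_path, atlas4):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        perm = [2, 0, 3, 1]
        names = list(atlas4.region_names)
        pnames = [names[i] for i in perm]
        p = tmp_path / "conn.csv"
        pd.DataFrame(w[np.ix_(perm, perm)], index=pnames, columns=pnames).to_csv(p)
        conn = cv.read_connectome(p, atlas4)
        assert np.allclose(conn.weights, w)   # manual-permutation oracle

    def test_unknown_region_rejected(self, tmp_path, atlas4):
        names = ["lA", "lB", "rA", "nope"]
        p = tmp_path / "conn.csv"
        pd.DataFrame(np.zeros((4, 4)), index=names, columns=names).to_csv(p)
        with pytest.raises(ValueError, match="labels"):
            cv.read_connectome(p, atlas4)

    def test_asymmetry_averaged_with_warning(self, tmp_path, atlas4, caplog):
        w = np.array(
            [[0, 0.5, 0.2, 0.1], [0.3, 0, 0.3, 0.2],
             [0.2, 0.3, 0, 0.4], [0.1, 0.2, 0.4, 0]]
        )
        names = list(atlas4.region_names)
        p = tmp_path / "conn.csv"
        pd.DataFrame(w, index=names, columns=names).to_csv(p)
        with caplog.at_level("WARNING", logger="corticov"):
            conn = cv.read_connectome(p, atlas4)
        assert "asymmetric" in caplog.text
        assert conn.weights[0, 1] == pytest.approx(0.4)

    def test_negative_structural_weight_rejected(self, tmp_path, atlas4):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = -0.2
        names = list(atlas4.region_names)
        p = tmp_path / "conn.csv"
        pd.DataFrame(w, index=names, columns=names).to_csv(p)
        with pytest.raises(ValueError, match="non-negative"):
            cv.read_connectome(p, atlas4, modality="structural")


class TestReadCohort:
    def test_toy_table(self, tmp_path, atlas4, toy_cohort_frame):
        tab = toy_cohort_frame(atlas4)
        p = tmp_path / "cohort.csv"
        tab.to_csv(p, index=False)
        cohort = cv.read_cohort(p, atlas4)
        assert cohort.n_subjects == 3

    def test_missing_thickness_column_lists_regions(self, tmp_path, atlas4, toy_cohort_frame):
        tab = toy_cohort_frame(atlas4).drop(columns=["lB"])
        p = tmp_path / "cohort.csv"
        tab.to_csv(p, index=False)
        with pytest.raises(ValueError, match="lB"):
            cv.read_cohort(p, atlas4)

    def test_roundtrip_preserves_values(self, tmp_path, atlas68, cohort98):
        cohort, _ = cohort98
        p = tmp_path / "cohort.csv"
        cv.write_cohort(cohort, p)
        back = cv.read_cohort(p, atlas68)
        assert np.max(np.abs(back.thickness() - cohort.thickness())) < 1e-12

    def test_missing_symptom_preserved(self, tmp_path, atlas4, toy_cohort_frame):
        tab = toy_cohort_frame(atlas4)
        tab.loc[1, "sans_alogia"] = np.nan
        p = tmp_path / "cohort.csv"
        tab.to_csv(p, index=False)
        cohort = cv.read_cohort(p, atlas4)
        assert cohort.table["sans_alogia"].isna().sum() == 1


def test_region_order_single_source_of_truth(tmp_path, atlas68, cohort98, connectome68):
    """Shuffling file row order must not change pipeline results (after
    mapping them back by region name)."""
    cohort, _ = cohort98
    rng = np.random.default_rng(3)
    perm = rng.permutation(atlas68.n_regions)
    # shuffled atlas file
    shuffled = cv.ParcelAtlas(
        region_names=tuple(atlas68.region_names[i] for i in perm),
        hemispheres=tuple(atlas68.hemispheres[i] for i in perm),
        centroids=atlas68.centroids[perm],
    )
    pa = tmp_path / "atlas.csv"
    cv.write_atlas(shuffled, pa)
    atlas_b = cv.read_atlas(pa)
    # connectome written in original order, read against shuffled atlas
    pc = tmp_path / "conn.csv"
    cv.write_connectome(connectome68, pc)
    conn_b = cv.read_connectome(pc, atlas_b)
    # cohort columns are matched by name, not position
    pco = tmp_path / "cohort.csv"
    cv.write_cohort(cohort, pco)
    cohort_b = cv.read_cohort(pco, atlas_b)

    res_a = cv.residualize(cohort)
    res_b = cv.residualize(cohort_b)
    em_a = cv.effect_map(res_a, cohort.table["amotivation"].to_numpy(float), "amotivation")
    em_b = cv.effect_map(res_b, cohort_b.table["amotivation"].to_numpy(float), "amotivation")
    assert np.allclose(em_b.coefficients, em_a.coefficients[perm])
    assert np.allclose(conn_b.weights, connectome68.weights[np.ix_(perm, perm)])
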