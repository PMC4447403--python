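"""Single-cell qPCR preprocessing, E-M projection, counting, MWU, PCA, correlation."""

import numpy as np
import pandas as pd
import pytest

from emstate import (
    CqPlate,
    SyntheticSpec,
    count_coexpressing,
    cq_to_expression,
    estimate_background,
    generate_cq_plate,
    mann_whitney_u,
    normalize_per_gene_max,
    pca_cells,
    process_plate,
    project_em_state,
)
from emstate.errors import (
    InvalidInputError,
    MissingAssayError,
    MissingBackgroundError,
)
from emstate.singlecell import correlation_matrix


def make_plate(cq_rows, ntc_rows=None, assays=("gX", "gY")):
    ntc_rows = ntc_rows or []
    rows = cq_rows + ntc_rows
    idx = [f"w{i}" for i in range(len(rows))]
    meta = pd.DataFrame(
        {
            "is_ntc": [False] * len(cq_rows) + [True] * len(ntc_rows),
            "n_cells": [1] * len(cq_rows) + [0] * len(ntc_rows),
        },
        index=idx,
    )
    return CqPlate(
        cq=pd.DataFrame(rows, index=idx, columns=list(assays)),
        well_meta=meta,
        assay_meta=pd.DataFrame({"panel": ["E"] * len(assays)}, index=list(assays)),
    )


class TestBackground:
    def test_min_of_ntc_cqs(self):
        plate = make_plate([[20.0, 20.0]], ntc_rows=[[26.0, 30.0], [28.0, 29.0]])
        bg = estimate_background(plate, fallback=24.0)
        assert bg["gX"] == 26.0 and bg["gY"] == 29.0

    def test_silent_ntc_falls_back(self):
        plate = make_plate([[20.0, 20.0]], ntc_rows=[[np.nan, 27.0]])
        bg = estimate_background(plate, fallback=24.0)
        assert bg["gX"] == 24.0 and bg["gY"] == 27.0

    def test_no_ntc_no_fallback_is_an_error(self):
        plate = make_plate([[20.0, 20.0]])
        with pytest.raises(MissingBackgroundError):
            estimate_background(plate, fallback=None)


class TestCqToExpression:
    def test_four_cycles_below_background_is_sixteen(self):
        plate = make_plate([[20.0, 24.0]])
        expr = cq_to_expression(plate, pd.Series({"gX": 24.0, "gY": 24.0}))
        assert expr.iloc[0, 0] == 16.0

    def test_at_or_past_background_is_exactly_zero(self):
        plate = make_plate([[24.0, 25.0]])
        expr = cq_to_expression(plate, pd.Series({"gX": 24.0, "gY": 24.0}))
        assert (expr.iloc[0] == 0.0).all()

    def test_missing_cq_is_zero(self):
        plate = make_plate([[np.nan, 20.0]])
        expr = cq_to_expression(plate, pd.Series({"gX": 24.0, "gY": 24.0}))
        assert expr.iloc[0, 0] == 0.0

    def test_negative_cq_rejected(self):
        with pytest.raises(InvalidInputError):
            make_plate([[-1.0, 20.0]])


class TestNormalization:
    def test_divide_by_single_cell_max(self):
        lin = pd.DataFrame({"g": [2.0, 8.0, 4.0]})
        out = normalize_per_gene_max(lin, np.array([True, True, True]))
        assert list(out["g"]) == [0.25, 1.0, 0.5]

    def test_all_zero_gene_stays_zero(self):
        lin = pd.DataFrame({"g": [0.0, 0.0]})
        out = normalize_per_gene_max(lin, np.array([True, True]))
        assert (out["g"] == 0).all()

    def test_pooled_wells_excluded_from_max_but_scaled(self):
        lin = pd.DataFrame({"g": [2.0, 4.0, 100.0]})
        mask = np.array([True, True, False])  # third is a 100-cell pool
        out = normalize_per_gene_max(lin, mask)
        assert list(out["g"]) == [0.5, 1.0, 25.0]

    def test_idempotent_on_normalized_profiles(self):
        rng = np.random.default_rng(0)
        lin = pd.DataFrame(rng.uniform(0, 9, (10, 4)))
        mask = np.ones(10, bool)
        once = normalize_per_gene_max(lin, mask)
        twice = normalize_per_gene_max(once, mask)
        pd.testing.assert_frame_equal(once, twice)


class TestProjection:
    def test_pure_and_hybrid_positions(self):
        norm = pd.DataFrame(
            [[1.0, 1.0, 0.0], [0.5, 0.5, 0.5]],
            columns=["e1", "e2", "m1"],
            index=["pure", "hybrid"],
        )
        pts = project_em_state(norm, ["e1", "e2"], ["m1"])
        assert tuple(pts.loc["pure"]) == (1.0, 0.0)
        assert tuple(pts.loc["hybrid"]) == (0.5, 0.5)

    def test_missing_panel_gene_listed_in_error(self):
        norm = pd.DataFrame([[1.0]], columns=["e1"])
        with pytest.raises(MissingAssayError, match="m1"):
            project_em_state(norm, ["e1"], ["m1"])

    def test_overlapping_panels_rejected(self):
        norm = pd.DataFrame([[1.0, 0.0]], columns=["a", "b"])
        with pytest.raises(InvalidInputError):
            project_em_state(norm, ["a"], ["a"])

    def test_group_means_invariant_to_cell_order(self, default_plate):
        plate, states = default_plate
        prof = process_plate(plate)
        sc = prof.single_cells()
        pts = project_em_state(sc, groups=states)
        shuffled = project_em_state(
            sc.sample(frac=1, random_state=1), groups=states
        )
        a = pts.groupby("group")[["mean_e", "mean_m"]].mean()
        b = shuffled.groupby("group")[["mean_e", "mean_m"]].mean()
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_hybrid_archetype_exceeds_opposite_state_means(self):
        spec = SyntheticSpec(
            seed=9, n_cells_per_state={"E": 20, "M": 20, "hybrid": 20}
        )
        plate, states = generate_cq_plate(spec)
        pts = project_em_state(process_plate(plate).single_cells(), groups=states)
        g = pts.groupby("group")[["mean_e", "mean_m"]].mean()
        assert g.loc["hybrid", "mean_e"] > g.loc["M", "mean_e"]
        assert g.loc["hybrid", "mean_m"] > g.loc["E", "mean_m"]


class TestCoexpression:
    def test_classes_from_constructed_profiles(self):
        norm = pd.DataFrame(
            [[1.0, 0.5], [1.0, 0.0], [0.0, 0.3], [0.0, 0.0]],
            columns=["e1", "m1"],
        )
        c = count_coexpressing(norm, ["e1"], ["m1"])
        assert (c["coexpressing"], c["exclusive_e"], c["exclusive_m"], c["silent"]) == (
            1, 1, 1, 1,
        )

    def test_synthetic_e_cells_are_promiscuous_m_cells_exclusive(self, default_plate):
        plate, states = default_plate
        sc = process_plate(plate).single_cells()
        e_mask = (states.loc[sc.index] == "E").to_numpy()
        ce = count_coexpressing(sc[e_mask])
        cm = count_coexpressing(sc[~e_mask])
        assert ce["coexpressing"] > ce["exclusive_e"] * 0  # some E cells co-express
        assert cm["exclusive_m"] >= 0.75 * cm["n_cells"]


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = mann_whitney_u([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_separated_em_aggregates_significant(self, default_plate):
        plate, states = default_plate
        pts = project_em_state(process_plate(plate).single_cells(),
                               groups=states)
        e = pts[pts["group"] == "E"]
        m = pts[pts["group"] == "M"]
        _, p_e = mann_whitney_u(e["mean_e"], m["mean_e"])
        _, p_m = mann_whitney_u(e["mean_m"], m["mean_m"])
        assert p_e < 0.004 and p_m < 0.004


class TestPcaAndCorrelation:
    def test_collinear_data_is_one_component(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"g1": x, "g2": 2 * x + 1})
        _, _, var = pca_cells(df)
        assert var[0] == pytest.approx(1.0)

    def test_loadings_separate_e_from_m_panel(self):
        spec = SyntheticSpec(seed=21, n_cells_per_state={"E": 20, "M": 20, "hybrid": 20})
        plate, _ = generate_cq_plate(spec)
        sc = process_plate(plate).single_cells()
        from emstate import E_PANEL, M_PANEL

        scores, loadings, _ = pca_cells(sc)
        # a component whose loadings have opposite signs for the two panels
        separated = False
        for pc in ("PC1", "PC2"):
            e_med = np.median(loadings.loc[[g for g in E_PANEL], pc])
            m_med = np.median(loadings.loc[[g for g in M_PANEL], pc])
            if e_med * m_med < 0:
                separated = True
        assert separated

    def test_scores_deterministic(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(15, 6)))
        s1, l1, v1 = pca_cells(df)
        s2, l2, v2 = pca_cells(df)
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_variance_genes_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [2.0, 1, 4]})
        with pytest.warns(UserWarning, match="zero-variance"):
            _, loadings, _ = pca_cells(df)
        assert "b" not in loadings.index

    def test_self_correlation_and_anticorrelation(self):
        x = np.arange(8.0)
        data = pd.DataFrame([x, -x, x + 3], index=["s1", "s2", "s3"])
        r = correlation_matrix(data)
        assert r.loc["s1", "s1"] == pytest.approx(1.0)
        assert r.loc["s1", "s2"] == pytest.approx(-1.0)
        assert r.loc["s1", "s3"] == pytest.approx(1.0)

    def test_block_average_signs_for_planted_blocks(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=40)
        e_like = np.vstack([base + rng.normal(0, 0.3, 40) for _ in range(4)])
        m_like = np.vstack([-base + rng.normal(0, 0.3, 40) for _ in range(4)])
        data = pd.DataFrame(np.vstack([e_like, m_like]))
        blocks = pd.Series(["E"] * 4 + ["M"] * 4, index=data.index)
        _, avg = correlation_matrix(data, blocks=blocks)
        assert avg.loc["E", "E"] > 0.5
        assert avg.loc["M", "M"] > 0.5
        assert avg.loc["E", "M"] < -0.5
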