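import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from opisthotraj import (
    CorrespondenceAnalysis,
    compositional_shift,
    correspondence_analysis,
    group_categories,
    normalize_for_ca,
    parse_species_tree,
)
from opisthotraj.content import CompositionMatrix
from opisthotraj.io import InputError


def rel(frame):
    sums = frame.sum(axis=1)
    return CompositionMatrix(frame.div(sums.replace(0.0, 1.0), axis=0), "relative",
                             frozenset(sums.index[sums == 0]))


def test_normalize_for_ca_hand_example():
    frame = pd.DataFrame([[1, 3], [3, 1]], index=["r1", "r2"], columns=["K", "T"],
                         dtype=float)
    out = normalize_for_ca(rel(frame))
    expected = np.array([[0.25, 0.75], [0.75, 0.25]])
    assert np.allclose(out.to_numpy(), expected)


def test_normalize_for_ca_output_is_row_stochastic():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.random((5, 4)) + 0.1, columns=list("KTWC"))
    out = normalize_for_ca(rel(frame))
    assert np.allclose(out.sum(axis=1), 1.0)


def test_doubly_stochastic_matrix_is_a_fixed_point():
    # circulant rows: every row and every column sums to 1
    frame = pd.DataFrame(
        [[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]], columns=list("KTW")
    )
    out = normalize_for_ca(CompositionMatrix(frame, "relative"))
    assert np.allclose(out.to_numpy(), frame.to_numpy() / 1.0)


def test_normalize_drops_unknown_category_and_dead_columns():
    frame = pd.DataFrame([[1, 1, 0], [1, 2, 0]], columns=["K", "S", "W"], dtype=float)
    with pytest.warns(UserWarning, match="all-zero"):
        out = normalize_for_ca(rel(frame))
    assert list(out.columns) == ["K"]


def test_identical_row_profiles_give_zero_inertia():
    frame = pd.DataFrame([[1, 2, 3], [2, 4, 6], [0.5, 1, 1.5]], columns=list("KTW"))
    model = correspondence_analysis(frame)
    assert model.total_inertia_ == pytest.approx(0.0, abs=1e-20)
    assert model.n_dimensions_ == 0


def test_diagonal_2x2_closed_form():
    """[[10,0],[0,10]]: one dimension, 100% inertia, symmetric rows."""
    frame = pd.DataFrame([[10, 0], [0, 10]], index=["r1", "r2"], columns=["K", "T"],
                         dtype=float)
    model = correspondence_analysis(frame)
    assert model.n_dimensions_ == 1
    assert model.inertia_shares_[0] == pytest.approx(1.0)
    # chi-square distance oracle: total inertia = chi2 / n = 1 for this table
    assert model.total_inertia_ == pytest.approx(1.0)
    coords = model.row_coords_["dim1"]
    assert coords["r1"] == pytest.approx(-coords["r2"])


def test_total_inertia_equals_chi2_over_n_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(20):
        shape = (int(rng.integers(3, 7)), int(rng.integers(3, 6)))
        table = rng.integers(1, 30, size=shape).astype(float)
        model = correspondence_analysis(pd.DataFrame(table))
        chi2 = chi2_contingency(table, correction=False)[0]
        assert model.total_inertia_ == pytest.approx(chi2 / table.sum(), rel=1e-9)


def test_masses_and_inertia_share_invariants():
    rng = np.random.default_rng(1)
    model = correspondence_analysis(pd.DataFrame(rng.integers(1, 20, (6, 5)).astype(float)))
    assert model.row_masses_.sum() == pytest.approx(1.0)
    assert model.col_masses_.sum() == pytest.approx(1.0)
    assert model.inertia_shares_.sum() == pytest.approx(1.0)
    assert model.n_dimensions_ <= min(6, 5) - 1


def test_supplementary_projection_reproduces_training_rows():
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(rng.integers(1, 20, (6, 5)).astype(float),
                         index=[f"n{i}" for i in range(6)])
    model = correspondence_analysis(frame)
    proj = model.transform(frame)
    assert np.allclose(proj.to_numpy(), model.row_coords_.to_numpy(), atol=1e-9)


def test_uniform_profile_projects_to_origin_under_uniform_masses():
    # symmetric table -> uniform column masses; a flat profile sits at the centroid
    frame = pd.DataFrame([[5, 1], [1, 5]], columns=["K", "T"], dtype=float)
    model = correspondence_analysis(frame)
    flat = pd.DataFrame([[1.0, 1.0]], columns=["K", "T"])
    assert np.allclose(model.transform(flat).to_numpy(), 0.0, atol=1e-12)


def test_column_mismatch_is_an_error():
    model = correspondence_analysis(pd.DataFrame([[1, 2], [2, 1]], columns=["K", "T"],
                                                 dtype=float))
    with pytest.raises(InputError, match="columns"):
        model.transform(pd.DataFrame([[1.0]], columns=["K"]))


def test_grouping_is_invariant_to_svd_sign_flip():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(rng.integers(1, 20, (6, 4)).astype(float),
                         index=[f"n{i}" for i in range(6)], columns=list("KTWC"))
    model = correspondence_analysis(frame)
    grouping = group_categories(model, {"n0", "n1"})
    model.row_coords_ *= -1  # global sign flip of every dimension
    model.col_coords_ *= -1
    model.col_standard_coords_ *= -1
    assert group_categories(model, {"n0", "n1"}) == grouping


def test_single_enriched_category_is_related_on_clean_fixture():
    rows = {"a1": [10, 1, 1], "a2": [9, 1, 1], "b1": [1, 5, 5], "b2": [1, 6, 4]}
    frame = pd.DataFrame(rows, index=list("KTW")).T.astype(float)
    model = correspondence_analysis(frame)
    grouping = group_categories(model, {"a1", "a2"})
    assert "K" in grouping["related"]
    assert grouping["related"].isdisjoint({"T"}) or "W" not in grouping["related"]


def test_compositional_shift_examples():
    tree = parse_species_tree("((a,b)M,(c,d)F)O;")
    frame = pd.DataFrame(
        {"K": [0.40, 0.435, 0.435], "T": [0.60, 0.565, 0.565]},
        index=["O", "M", "F"],
    )
    m = CompositionMatrix(frame, "relative")
    assert compositional_shift(m, tree, "M", {"K"}) == pytest.approx(3.5)
    assert compositional_shift(m, tree, "F", {"K"}) == pytest.approx(3.5)
    assert compositional_shift(m, tree, "F", {"T"}) == pytest.approx(-3.5)
    with pytest.raises(InputError, match="root"):
        compositional_shift(m, tree, "O", {"K"})


def test_shifts_telescope_along_paths(planted_sim):
    from opisthotraj import (build_profiles, node_category_counts,
                             relative_composition, simulate_annotations)
    cfg, events, truth = planted_sim
    cats, _ = build_profiles(simulate_annotations(truth, cfg))
    relm = relative_composition(node_category_counts(events, cats, truth.tree))
    letters = {"K", "T", "W"}
    group_root = truth.clade_roots["A"]
    path = truth.tree.path_to(group_root, "a1")
    total = sum(compositional_shift(relm, truth.tree, n, letters) for n in path)
    cols = [c for c in relm.frame.columns if c in letters]
    expected = 100 * (relm.frame.loc["a1", cols].sum()
                      - relm.frame.loc[group_root, cols].sum())
    assert total == pytest.approx(expected, abs=1e-9)
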