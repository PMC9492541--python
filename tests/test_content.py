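import numpy as np
import pandas as pd
import pytest

from opisthotraj import (
    build_profiles,
    category_net_changes,
    extant_contribution,
    mechanism_fractions,
    metabolic_fraction,
    node_category_counts,
    origination_decomposition,
    path_cumulative_changes,
    relative_composition,
    simulate_annotations,
)
from opisthotraj.io import EventTable, InputError
from opisthotraj.profiles import CategoryProfile, KOProfile


def make_events(rows, tree):
    frame = pd.DataFrame(
        rows, columns=["node", "og", "copies", "originations",
                       "duplications", "transfers", "losses"]
    )
    return EventTable(frame, tree=tree)


@pytest.fixture
def profiles():
    return {
        "og1": CategoryProfile("og1", {"K": 0.75, "B": 0.25}),
        "og2": CategoryProfile("og2", {"T": 1.0}),
    }


def test_node_counts_cross_copies_with_profiles(four_tip_tree, profiles):
    events = make_events(
        [("M", "og1", 2, 0, 0, 0, 0), ("M", "og2", 1, 0, 0, 0, 0)], four_tip_tree
    )
    mat = node_category_counts(events, profiles, four_tip_tree)
    assert mat.row("M").to_dict() == pytest.approx({"K": 1.5, "B": 0.5, "T": 1.0})
    assert mat.row("F").sum() == 0 and "F" in mat.zero_nodes


def test_relative_composition_rows(four_tip_tree, profiles):
    events = make_events(
        [("M", "og1", 2, 0, 0, 0, 0), ("M", "og2", 1, 0, 0, 0, 0)], four_tip_tree
    )
    rel = relative_composition(node_category_counts(events, profiles, four_tip_tree))
    assert rel.row("M").to_dict() == pytest.approx({"K": 0.5, "B": 1 / 6, "T": 1 / 3})
    sums = rel.frame.sum(axis=1)
    for node in rel.frame.index:
        if node not in rel.zero_nodes:
            assert sums[node] == pytest.approx(1.0, abs=1e-9)


def test_net_changes_are_parent_child_differences(four_tip_tree):
    profs = {"og1": CategoryProfile("og1", {"K": 1.0}),
             "og2": CategoryProfile("og2", {"T": 1.0})}
    events = make_events(
        [("O", "og1", 2, 0, 0, 0, 0), ("O", "og2", 1, 0, 0, 0, 0),
         ("M", "og1", 3, 0, 1, 0, 0), ("M", "og2", 0, 0, 0, 0, 1)],
        four_tip_tree,
    )
    mat = node_category_counts(events, profs, four_tip_tree)
    changes = category_net_changes(mat, four_tip_tree)
    assert changes.net.loc["M", "K"] == pytest.approx(1.0)
    assert changes.net.loc["M", "T"] == pytest.approx(-1.0)
    assert "O" not in changes.net.index  # the root has no preceding node


def test_net_changes_telescope_along_paths(planted_sim):
    cfg, events, truth = planted_sim
    anns = simulate_annotations(truth, cfg)
    cats, _ = build_profiles(anns)
    mat = node_category_counts(events, cats, truth.tree)
    changes = category_net_changes(mat, truth.tree)
    tip = "a1"
    group_root = truth.clade_roots["A"]
    cum = path_cumulative_changes(changes, truth.tree, group_root, tip)
    expected = mat.frame.loc[tip] - mat.frame.loc[group_root]
    assert np.allclose(cum.to_numpy(), expected.to_numpy(), atol=1e-9)
    # single-step path equals that node's own net change
    child_of_root = truth.tree.path_to(group_root, tip)[0]
    single = path_cumulative_changes(changes, truth.tree, group_root, child_of_root)
    assert np.allclose(single, changes.net.loc[child_of_root])


def test_metabolic_fraction_hand_example(four_tip_tree):
    events = make_events(
        [("M", "og1", 1, 0, 0, 0, 0), ("M", "og2", 3, 0, 0, 0, 0)], four_tip_tree
    )
    kos = {"og1": KOProfile("og1", {"K00001": 1.0}),
           "og2": KOProfile("og2", {"K00002": 1.0})}
    classes = {"K00001": "metabolic", "K00002": "other"}
    met = metabolic_fraction(events, kos, classes, four_tip_tree)
    assert met["M"] == pytest.approx(25.0)
    assert np.isnan(met["F"])  # zero-content node flagged
    all_met = metabolic_fraction(events, kos, {"K00001": "metabolic",
                                               "K00002": "membrane_transport"},
                                 four_tip_tree)
    assert all_met["M"] == pytest.approx(100.0)


def test_metabolic_fraction_unclassified_ko_is_an_error(four_tip_tree):
    events = make_events([("M", "og1", 1, 0, 0, 0, 0)], four_tip_tree)
    kos = {"og1": KOProfile("og1", {"K99999": 1.0})}
    with pytest.raises(InputError, match="K99999"):
        metabolic_fraction(events, kos, {}, four_tip_tree)


def test_mechanism_fractions_hand_example(four_tip_tree):
    events = make_events(
        [("M", "og1", 4, 2, 1, 1, 0), ("F", "og2", 1, 0, 0, 0, 0)], four_tip_tree
    )
    mech = mechanism_fractions(events)
    row = mech.loc["M"]
    assert row[["origination", "duplication", "transfer", "fusion"]].to_dict() == (
        pytest.approx({"origination": 50.0, "duplication": 25.0,
                       "transfer": 25.0, "fusion": 0.0})
    )
    assert row["origination"] + row["duplication"] + row["transfer"] == pytest.approx(100.0)
    assert bool(mech.loc["F", "flagged_zero_gains"]) is True


def test_fusion_fraction_is_reported_alongside(four_tip_tree):
    events = make_events([("M", "og1", 4, 2, 1, 1, 0)], four_tip_tree)
    mech = mechanism_fractions(events, fusion_flags={("M", "og1")})
    assert mech.loc["M", "fusion"] == pytest.approx(50.0)
    with pytest.raises(InputError, match="zero originations"):
        mechanism_fractions(
            make_events([("M", "og1", 1, 0, 1, 0, 0)], four_tip_tree),
            fusion_flags={("M", "og1")},
        )


def test_origination_decomposition_identities(four_tip_tree):
    profs = {f"og{i}": CategoryProfile(f"og{i}", {"K": 1.0}) for i in range(1, 4)}
    events = make_events(
        [("O", "og1", 1, 0, 0, 0, 0),          # pre-root family
         ("M", "og1", 2, 0, 1, 0, 0),          # expansion of ancestral family
         ("M", "og2", 1, 1, 0, 0, 0),          # origination at the focal node
         ("M", "og3", 1, 0, 0, 1, 0),          # transfer from elsewhere
         ("F", "og3", 1, 1, 0, 0, 0)],
        four_tip_tree,
    )
    out = origination_decomposition(events, four_tip_tree, "M", {"K"}, profs, {"O"})
    assert out["pct_originated_at_focal"] == pytest.approx(100 / 3)
    assert out["pct_originated_in_ancestors"] == pytest.approx(100 / 3)
    assert sum(out.values()) == pytest.approx(100.0)


def test_origination_decomposition_all_new_families(four_tip_tree):
    profs = {"og1": CategoryProfile("og1", {"K": 1.0})}
    events = make_events([("M", "og1", 1, 1, 0, 0, 0)], four_tip_tree)
    out = origination_decomposition(events, four_tip_tree, "M", {"K"}, profs, {"O"})
    assert out["pct_originated_at_focal"] == pytest.approx(100.0)
    assert out["pct_originated_in_ancestors"] == pytest.approx(0.0)


def test_extant_contribution_sums_to_100(four_tip_tree):
    profs = {"og1": CategoryProfile("og1", {"K": 1.0}),
             "og2": CategoryProfile("og2", {"T": 1.0})}
    events = make_events(
        [("O", "og1", 1, 0, 0, 0, 0), ("M", "og2", 1, 1, 0, 0, 0),
         ("a", "og1", 2, 0, 0, 0, 0), ("a", "og2", 2, 0, 0, 0, 0)],
        four_tip_tree,
    )
    contrib = extant_contribution(events, four_tip_tree, "a", profs)
    assert contrib.sum() == pytest.approx(100.0)
    assert contrib.to_dict() == pytest.approx({"O": 50.0, "M": 50.0})
    only_root = extant_contribution(
        events, four_tip_tree, "a", profs, category_set={"K"}
    )
    assert only_root.to_dict() == pytest.approx({"O": 100.0})


def test_extant_contribution_matches_truth(planted_sim):
    cfg, events, truth = planted_sim
    anns = simulate_annotations(truth, cfg)
    cats, _ = build_profiles(anns)
    contrib = extant_contribution(events, truth.tree, "a1", cats)
    meta = truth.og_table.set_index("og")
    f = events.frame
    at_tip = f[(f["node"] == "a1") & (f["copies"] > 0)]
    expected: dict[str, float] = {}
    for rec in at_tip.itertuples(index=False):
        if rec.og in cats and cats[rec.og].mass() > 0:
            node = meta.at[rec.og, "origin"]
            expected[node] = expected.get(node, 0.0) + rec.copies * cats[rec.og].mass()
    total = sum(expected.values())
    for node, val in expected.items():
        assert contrib[node] == pytest.approx(100 * val / total)


def test_event_and_content_bookkeeping_agree_per_og(planted_sim):
    """copies(child) - copies(parent) = orig + dup + trans - loss, exactly."""
    _, events, truth = planted_sim
    tree = truth.tree
    copies = events.copies_matrix(tree.nodes)
    f = events.frame
    for node in tree.nodes:
        if node == tree.root:
            continue
        sub = f[f["node"] == node]
        parent_row = copies.loc[tree.parent[node]]
        child_row = copies.loc[node]
        delta = (sub["originations"] + sub["duplications"]
                 + sub["transfers"] - sub["losses"]).to_numpy()
        got = child_row[sub["og"]].to_numpy() - parent_row[sub["og"]].to_numpy()
        assert np.allclose(got, delta, atol=1e-9)
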