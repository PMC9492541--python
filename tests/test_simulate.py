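import numpy as np
import pandas as pd
import pytest
import yaml

from opisthotraj import (
    build_profiles,
    node_category_counts,
    parse_species_tree,
    read_annotations,
    read_composites,
    read_event_table,
    read_hit_table,
    simulate_annotations,
    simulate_composites,
    simulate_gene_content,
)
from opisthotraj.simulate import (
    SimConfig,
    SimulationError,
    build_fixture,
    make_two_clade_tree,
    stage_seed,
)


def quiet_config(**kw):
    defaults = dict(seed=1, root_families=5, origination_rate=0.0,
                    duplication_rate=0.0, transfer_rate=0.0, loss_rate=0.0,
                    n_true_fusions=0, n_decoys=0)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_no_event_limit_propagates_root_content_unchanged():
    events, truth = simulate_gene_content(quiet_config())
    copies = events.copies_matrix(truth.tree.nodes)
    assert (copies.to_numpy() == 1).all() and copies.shape[1] == 5
    cols = ["originations", "duplications", "transfers", "losses"]
    assert (events.frame[cols].to_numpy() == 0).all()


def test_total_loss_limit_empties_the_clade():
    events, truth = simulate_gene_content(quiet_config(loss_rate=1e6))
    copies = events.copies_matrix(truth.tree.nodes)
    for node in truth.tree.nodes:
        if node == truth.tree.root:
            assert copies.loc[node].sum() == 5
        else:
            assert copies.loc[node].sum() == 0
    # losses on the branches out of the root equal the root copy count
    f = events.frame
    for child in truth.tree.children[truth.tree.root]:
        assert f[f["node"] == child]["losses"].sum() == 5


def test_origination_counts_match_poisson_mean():
    """Mean per-branch originations over 200 replicates vs sigma * length."""
    sigma, length = 0.5, 1.0
    totals = []
    n_branches = None
    for rep in range(200):
        cfg = SimConfig(seed=1000 + rep, root_families=3, origination_rate=sigma,
                        duplication_rate=0.3, transfer_rate=0.0, loss_rate=0.2,
                        n_true_fusions=0, n_decoys=0)
        events, truth = simulate_gene_content(cfg)
        n_branches = len(truth.tree.nodes) - 1
        totals.append(events.frame["originations"].sum() / n_branches)
    mean = np.mean(totals)
    se = np.std(totals, ddof=1) / np.sqrt(len(totals))
    assert abs(mean - sigma * length) <= 3 * se + 1e-9


def test_conservation_identity_exact(planted_sim):
    _, events, truth = planted_sim
    tree = truth.tree
    copies = events.copies_matrix(tree.nodes)
    for node in tree.nodes:
        if node == tree.root:
            continue
        sub = events.frame[events.frame["node"] == node]
        delta = (sub["originations"] + sub["duplications"] + sub["transfers"]
                 - sub["losses"]).to_numpy()
        got = (copies.loc[node, sub["og"]].to_numpy()
               - copies.loc[tree.parent[node], sub["og"]].to_numpy())
        assert np.array_equal(got, delta)


def test_noise_free_annotations_are_unit_vectors(planted_sim):
    cfg, events, truth = planted_sim
    anns = simulate_annotations(truth, cfg)  # default config: no noise
    cats, kos = build_profiles(anns)
    meta = truth.og_table.set_index("og")
    for og, prof in cats.items():
        assert prof.weights == pytest.approx({meta.at[og, "category"]: 1.0})
    for og, prof in kos.items():
        assert prof.weights == pytest.approx({meta.at[og, "ko"]: 1.0})


def test_fully_unannotated_gives_empty_profiles(neutral_sim):
    cfg, events, truth = neutral_sim
    blank = SimConfig(**{**cfg.__dict__, "p_unannotated": 1.0})
    anns = simulate_annotations(truth, blank)
    cats, _ = build_profiles(anns)
    assert all(not p.weights for p in cats.values())
    mat = node_category_counts(events, cats, truth.tree)
    assert (mat.frame.to_numpy() == 0).all()
    assert set(truth.tree.nodes) == set(mat.zero_nodes)


def test_multi_label_rate_within_binomial_interval(neutral_sim):
    cfg, events, truth = neutral_sim
    noisy = SimConfig(**{**cfg.__dict__, "p_multi": 0.5})
    anns = simulate_annotations(truth, noisy)
    n = len(anns)
    multi = sum(1 for a in anns if len(a.cog_letters) > 1)
    # the planted second letter is dropped when it collides with the first:
    # 11 noise letters, so the effective rate is 0.5 * 10/11
    p_eff = 0.5 * 10 / 11
    se = np.sqrt(p_eff * (1 - p_eff) / n)
    assert abs(multi / n - p_eff) <= 2.58 * se  # 99% interval


def test_zero_composites_requested(neutral_sim):
    cfg, events, truth = neutral_sim
    none_cfg = SimConfig(**{**cfg.__dict__, "n_true_fusions": 0, "n_decoys": 0})
    assert simulate_composites(truth, none_cfg) == []


def test_exact_half_member_fraction_fails_majority_rule(neutral_sim):
    from opisthotraj import call_composite_clusters
    cfg, events, truth = neutral_sim
    half = SimConfig(**{**cfg.__dict__, "member_composite_fraction": 0.5})
    recs = simulate_composites(truth, half)
    planted = truth.true_fusion_ogs | truth.decoy_ogs
    called = call_composite_clusters([r for r in recs if r.og_id in planted])
    assert called == set()


def test_infeasible_fusion_request_errors():
    cfg = quiet_config(n_true_fusions=3, n_decoys=0)
    _, truth = simulate_gene_content(cfg)
    with pytest.raises(SimulationError, match="deficit"):
        simulate_composites(truth, cfg)  # no non-root originations exist


def test_stage_seeds_are_stable_and_distinct():
    assert stage_seed(1, "annotations") == stage_seed(1, "annotations")
    assert stage_seed(1, "annotations") != stage_seed(1, "composites")
    assert stage_seed(1, "annotations") != stage_seed(2, "annotations")
    assert 0 <= stage_seed(123, "x") < 2**31


def test_null_multipliers_give_centred_shifts():
    """Without clade bias the mean planted shift is ~0 at every ancestor."""
    shifts = []
    for rep in range(30):
        cfg = SimConfig(seed=3000 + rep, root_families=300, origination_rate=50.0)
        _, truth = simulate_gene_content(cfg)
        for node in ("A1", "A2", "A3"):
            shifts.append(truth.true_shift(node, {"K", "T", "W"}))
    mean = np.mean(shifts)
    se = np.std(shifts, ddof=1) / np.sqrt(len(shifts))
    assert abs(mean) <= 3 * se + 1e-9


def test_planted_multiplier_tilts_shifts_positive(planted_sim):
    _, events, truth = planted_sim
    for node in ("A1", "A2", "A3"):
        assert truth.true_shift(node, {"K", "T", "W"}) > 0


def test_fixture_determinism_and_parseability(fixture_dir, tmp_path):
    fix, cfg = fixture_dir
    again = build_fixture(cfg, tmp_path / "again")
    for name in ("manifest.yaml", "events.tsv", "annotations.tsv",
                 "composites.tsv", "hits_forward.tsv", "tree.nwk"):
        assert (fix / name).read_bytes() == (again / name).read_bytes()
    tree = parse_species_tree((fix / "tree.nwk").read_text())
    events = read_event_table(fix / "events.tsv", tree)
    assert len(events) > 0
    anns = read_annotations(fix / "annotations.tsv")
    assert len(anns) > 0
    comps = read_composites(fix / "composites.tsv")
    assert any(r.is_composite for r in comps)
    fwd = read_hit_table(fix / "hits_forward.tsv")
    assert len(fwd) > 0
    manifest = yaml.safe_load((fix / "manifest.yaml").read_text())
    assert manifest["seed"] == cfg.seed and manifest["true_fusions"]
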