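"""Per-node functional compositions and their changes along the species tree.

The reconciliation gives an expected copy number for every orthogroup at
every node; the profiles give each orthogroup's fractional spread over
functional categories.  Crossing the two yields the absolute category
representation of every node, from which everything else follows:

* relative compositions (row-normalized),
* net category changes between a node and its immediate ancestor
  (content-difference definition),
* cumulative changes along ancestral paths,
* metabolic gene-content percentages from KO profiles,
* the mechanistic split of gene gains (origination / duplication /
  transfer, with fusion-mediated originations reported alongside), and
* decompositions of a node's gains or a tip's content by the origination
  node of the contributing families.

Two notions of "gain" coexist deliberately: category gains/losses are
content differences between neighbouring nodes, while mechanism fractions
count reconciliation events.  Per orthogroup the two agree
(copies_child - copies_parent = originations + duplications + transfers
- losses); per category they need not, because profiles spread fractional
mass over letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import EventTable, InputError
from .profiles import CategoryProfile, KOProfile
from .tree import SpeciesTree

GAIN_MECHANISMS = ("origination", "duplication", "transfer")


@dataclass
class CompositionMatrix:
    """Nodes x categories matrix, in absolute counts or relative fractions."""

    frame: pd.DataFrame
    mode: str  # "absolute" | "relative"
    zero_nodes: frozenset[str] = frozenset()

    def row(self, node: str) -> pd.Series:
        return self.frame.loc[node]


@dataclass
class NodeChangeTable:
    """Per-(node, category) net content change, with event-based components."""

    net: pd.DataFrame                       # non-root nodes x categories
    gains_by_mechanism: dict[str, pd.DataFrame] = field(default_factory=dict)
    losses: pd.DataFrame | None = None


def _profile_matrix(
    profiles: Mapping[str, CategoryProfile] | Mapping[str, KOProfile],
    og_ids: Iterable[str],
) -> pd.DataFrame:
    """Dense og x label weight matrix; missing/empty profiles give zero rows."""
    og_ids = sorted(og_ids)
    labels = sorted({lab for og in og_ids if og in profiles for lab in profiles[og].weights})
    mat = pd.DataFrame(0.0, index=og_ids, columns=labels)
    for og in og_ids:
        prof = profiles.get(og)
        if prof is not None:
            for lab, w in prof.weights.items():
                mat.at[og, lab] = w
    return mat


def node_category_counts(
    events: EventTable,
    profiles: Mapping[str, CategoryProfile],
    tree: SpeciesTree | None = None,
) -> CompositionMatrix:
    """Absolute category representation: copies x profile weight, summed."""
    tree = tree or events.tree
    nodes = tree.nodes if tree is not None else None
    copies = events.copies_matrix(nodes)
    weights = _profile_matrix(profiles, copies.columns)
    counts = copies.to_numpy() @ weights.loc[copies.columns].to_numpy()
    frame = pd.DataFrame(counts, index=copies.index, columns=weights.columns)
    zero = frozenset(frame.index[frame.sum(axis=1) == 0])
    return CompositionMatrix(frame, "absolute", zero)


def relative_composition(matrix: CompositionMatrix) -> CompositionMatrix:
    """Row-normalize an absolute composition; all-zero rows stay zero, flagged."""
    if matrix.mode != "absolute":
        raise InputError("relative_composition expects an absolute matrix")
    sums = matrix.frame.sum(axis=1)
    zero = frozenset(sums.index[sums == 0])
    safe = sums.replace(0.0, 1.0)
    return CompositionMatrix(matrix.frame.div(safe, axis=0), "relative", zero)


def category_net_changes(
    matrix: CompositionMatrix,
    tree: SpeciesTree,
    events: EventTable | None = None,
    profiles: Mapping[str, CategoryProfile] | None = None,
    fusion_flags: set[tuple[str, str]] | None = None,
) -> NodeChangeTable:
    """Net content change of every category between each node and its parent.

    When ``events`` and ``profiles`` are given, the event-based gain
    components (profile-weighted origination/duplication/transfer counts,
    plus fusion-flagged originations) and losses are attached as well.
    """
    if matrix.mode != "absolute":
        raise InputError("category_net_changes expects an absolute matrix")
    non_root = [n for n in tree.nodes if n != tree.root]
    parents = [tree.parent[n] for n in non_root]
    net = matrix.frame.loc[non_root].to_numpy() - matrix.frame.loc[parents].to_numpy()
    table = NodeChangeTable(pd.DataFrame(net, index=non_root, columns=matrix.frame.columns))

    if events is not None and profiles is not None:
        weights = _profile_matrix(profiles, events.frame["og"].unique())
        weights = weights.reindex(columns=matrix.frame.columns, fill_value=0.0)
        for mech, col in zip(GAIN_MECHANISMS, ("originations", "duplications", "transfers")):
            pivot = events.frame.pivot_table(index="node", columns="og", values=col,
                                             aggfunc="sum", fill_value=0.0)
            pivot = pivot.reindex(index=non_root, fill_value=0.0)
            vals = pivot.to_numpy() @ weights.loc[pivot.columns].to_numpy()
            table.gains_by_mechanism[mech] = pd.DataFrame(
                vals, index=non_root, columns=matrix.frame.columns
            )
        if fusion_flags:
            fus = events.frame[
                [(n, o) in fusion_flags for n, o in zip(events.frame["node"], events.frame["og"])]
            ]
            pivot = fus.pivot_table(index="node", columns="og", values="originations",
                                    aggfunc="sum", fill_value=0.0)
            pivot = pivot.reindex(index=non_root, columns=weights.index, fill_value=0.0)
            vals = pivot.to_numpy() @ weights.to_numpy()
            table.gains_by_mechanism["fusion_origination"] = pd.DataFrame(
                vals, index=non_root, columns=matrix.frame.columns
            )
        loss = events.frame.pivot_table(index="node", columns="og", values="losses",
                                        aggfunc="sum", fill_value=0.0)
        loss = loss.reindex(index=non_root, fill_value=0.0)
        table.losses = pd.DataFrame(
            loss.to_numpy() @ weights.loc[loss.columns].to_numpy(),
            index=non_root, columns=matrix.frame.columns,
        )
    return table


def path_cumulative_changes(
    changes: NodeChangeTable,
    tree: SpeciesTree,
    group_root: str,
    tip: str,
) -> pd.Series:
    """Cumulative net change per category along the path group_root -> tip.

    The sum runs over the nodes strictly below ``group_root`` down to and
    including ``tip``: changes on the branch *into* the group root belong
    to the group root's own row and are excluded, so the result telescopes
    to (tip content - group-root content).
    """
    path = tree.path_to(group_root, tip)
    return changes.net.loc[path].sum(axis=0)


def metabolic_fraction(
    events: EventTable,
    ko_profiles: Mapping[str, KOProfile],
    ko_classes: Mapping[str, str],
    tree: SpeciesTree | None = None,
) -> pd.Series:
    """Percent of each node's gene content that is metabolic.

    A gene counts as metabolic when its KO is classed ``metabolic`` or
    ``membrane_transport``.  The denominator is the node's total copy
    count over all orthogroups; nodes with zero content get NaN.
    """
    seen_kos = {ko for prof in ko_profiles.values() for ko in prof.weights}
    unclassified = sorted(seen_kos - set(ko_classes))
    if unclassified:
        raise InputError(f"KO ids without a class: {unclassified[:10]}")
    metabolic_kos = {ko for ko, cls in ko_classes.items()
                     if cls in ("metabolic", "membrane_transport")}
    tree = tree or events.tree
    copies = events.copies_matrix(tree.nodes if tree is not None else None)
    met_weight = pd.Series(
        {og: ko_profiles[og].mass(metabolic_kos) if og in ko_profiles else 0.0
         for og in copies.columns}
    )
    numer = copies.to_numpy() @ met_weight.loc[copies.columns].to_numpy()
    denom = copies.sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * numer / denom, np.nan)
    return pd.Series(pct, index=copies.index, name="metabolic_pct")


def mechanism_fractions(
    events: EventTable,
    fusion_flags: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Percent of each node's gene gains explained by each mechanism.

    Gains are origination + duplication + transfer event expectations.
    Fusion-mediated originations are a subset of originations and are
    reported alongside, not subtracted, so origination + duplication +
    transfer always sums to 100 on nodes with gains.  Zero-gain nodes are
    flagged and carry NaN percentages.
    """
    fusion_flags = fusion_flags or set()
    f = events.frame
    sums = f.groupby("node")[["originations", "duplications", "transfers"]].sum()
    if fusion_flags:
        flagged_rows = f[[(n, o) in fusion_flags for n, o in zip(f["node"], f["og"])]]
        zero_orig = flagged_rows[flagged_rows["originations"] <= 0]
        if len(zero_orig):
            pair = (zero_orig.iloc[0]["node"], zero_orig.iloc[0]["og"])
            raise InputError(f"fusion flag on {pair} with zero originations")
        fusion = flagged_rows.groupby("node")["originations"].sum()
    else:
        fusion = pd.Series(dtype=float)
    gains = sums.sum(axis=1)
    out = pd.DataFrame(index=sums.index)
    out["gains"] = gains
    with np.errstate(invalid="ignore", divide="ignore"):
        for mech, col in zip(GAIN_MECHANISMS, sums.columns):
            out[mech] = np.where(gains > 0, 100.0 * sums[col] / gains, np.nan)
        fus = fusion.reindex(sums.index, fill_value=0.0)
        out["fusion"] = np.where(gains > 0, 100.0 * fus / gains, np.nan)
    out["flagged_zero_gains"] = gains == 0
    return out


def origination_decomposition(
    events: EventTable,
    tree: SpeciesTree,
    focal_node: str,
    category_set: set[str],
    profiles: Mapping[str, CategoryProfile],
    ancestor_set: set[str],
) -> dict[str, float]:
    """Split a node's category-weighted gains by the origin of the families.

    Gains at ``focal_node`` (origination + duplication + transfer), weighted
    by each family's profile mass on ``category_set``, are partitioned into
    families that originated at the focal node itself, families that
    originated in the supplied ancestor set, and a residual.  Percentages
    sum to 100.
    """
    if not category_set:
        raise InputError("category_set must be non-empty")
    origin, _ = events.origination_nodes(tree)
    f = events.frame
    at_focal = f[f["node"] == focal_node]
    weighted = {}
    for rec in at_focal.itertuples(index=False):
        gain = rec.originations + rec.duplications + rec.transfers
        prof = profiles.get(rec.og)
        if gain <= 0 or prof is None:
            continue
        mass = prof.mass(category_set)
        if mass > 0:
            weighted[rec.og] = gain * mass
    total = sum(weighted.values())
    if total == 0:
        raise InputError(f"no category-weighted gains recorded at {focal_node!r}")
    here = sum(v for og, v in weighted.items() if origin.get(og) == focal_node)
    anc = sum(v for og, v in weighted.items() if origin.get(og) in ancestor_set)
    return {
        "pct_originated_at_focal": 100.0 * here / total,
        "pct_originated_in_ancestors": 100.0 * anc / total,
        "pct_residual": 100.0 * (total - here - anc) / total,
    }


def extant_contribution(
    events: EventTable,
    tree: SpeciesTree,
    tip: str,
    profiles: Mapping[str, CategoryProfile],
    category_set: set[str] | None = None,
) -> pd.Series:
    """Percent of a tip's (category-weighted) content by origination node.

    Each family's contribution is its copy count at the tip times its
    profile mass (restricted to ``category_set`` when given, otherwise the
    total profile mass); contributions are binned by the family's
    origination node and normalized to 100%.
    """
    if tip not in tree.nodes:
        raise InputError(f"unknown tip {tip!r}")
    origin, _ = events.origination_nodes(tree)
    f = events.frame
    at_tip = f[(f["node"] == tip) & (f["copies"] > 0)]
    bins: dict[str, float] = {}
    for rec in at_tip.itertuples(index=False):
        prof = profiles.get(rec.og)
        if prof is None:
            continue
        mass = prof.mass(category_set) if category_set else prof.mass()
        if mass > 0:
            node = origin[rec.og]
            bins[node] = bins.get(node, 0.0) + rec.copies * mass
    total = sum(bins.values())
    if total == 0:
        return pd.Series(dtype=float, name=tip)
    ordered = [n for n in tree.nodes if n in bins]
    return pd.Series({n: 100.0 * bins[n] / total for n in ordered}, name=tip)
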