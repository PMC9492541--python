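"""Composite-cluster calling and the ancestry-constrained fusion filter.

A sequence-level composite detector marks individual sequences as
composites of components drawn from other gene families.  At the family
level, a cluster counts as composite only when strictly more than half of
its members are composite sequences.  A composite family is then a *bona
fide* fusion only when every one of its component families originated at a
proper ancestor of the composite's own origination node: gene fissions and
same-node co-originations produce composite signatures without fusion, and
requiring strictly more ancestral components trades those false positives
for known false negatives (fusions whose parts arose in the same node).

"More ancestral" is formalized as proper ancestry on the species tree
(content is inherited along lineages in the reconciliation model); a
node-depth ordering that would also admit transfer-mediated acquisition is
available via ``ancestry="depth"``.  Families with a single sequence are
never accepted as components.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CompositeRecord, InputError
from .tree import SpeciesTree


@dataclass(frozen=True)
class FusionCall:
    og_id: str
    composite: bool
    components: tuple[str, ...]
    composite_origin: str | None
    component_origins: tuple[str, ...]
    bona_fide: bool
    reason: str  # none | member_fraction | same_node_component | non_ancestral_component


def call_composite_clusters(records: list[CompositeRecord]) -> set[str]:
    """Families in which >50% (strict) of members are composite sequences."""
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for rec in records:
        totals[rec.og_id] = totals.get(rec.og_id, 0) + 1
        if rec.is_composite:
            hits[rec.og_id] = hits.get(rec.og_id, 0) + 1
    return {og for og, n in totals.items() if hits.get(og, 0) * 2 > n}


def component_map(records: list[CompositeRecord]) -> dict[str, tuple[str, ...]]:
    """Union of component families named by any member, per family."""
    out: dict[str, set[str]] = {}
    for rec in records:
        if rec.is_composite:
            out.setdefault(rec.og_id, set()).update(rec.components)
    return {og: tuple(sorted(comps)) for og, comps in out.items()}


def bona_fide_fusions(
    composites: set[str],
    components: dict[str, tuple[str, ...]],
    origin: dict[str, str],
    tree: SpeciesTree,
    member_counts: dict[str, int] | None = None,
    ancestry: str = "lineage",
) -> list[FusionCall]:
    """Apply the ancestry filter to composite families.

    Parameters
    ----------
    composites :
        Families passing the >50%-composite-members rule.
    components :
        Map composite family -> its component families.
    origin :
        Map family -> origination node label (pre-root families resolve to
        the root).
    member_counts :
        Optional family sizes; single-sequence families are removed from
        component lists before the ancestry check.
    ancestry :
        ``"lineage"`` (default) requires components to originate at proper
        ancestors of the composite's origination node; ``"depth"`` only
        requires strictly smaller root distance.
    """
    if ancestry not in ("lineage", "depth"):
        raise InputError(f"unknown ancestry rule {ancestry!r}")
    calls = []
    for og in sorted(composites):
        comps = components.get(og, ())
        if member_counts is not None:
            comps = tuple(c for c in comps if member_counts.get(c, 0) > 1)
        if og not in origin:
            raise InputError(f"no origination node for composite {og!r}")
        unknown = [c for c in comps if c not in origin]
        if unknown:
            raise InputError(f"no origination node for components {unknown}")
        comp_origin = origin[og]
        comp_origins = tuple(origin[c] for c in comps)
        reason = "none"
        if not comps:
            reason = "non_ancestral_component"
        for c_origin in comp_origins:
            if c_origin == comp_origin:
                reason = "same_node_component"
                break
            if ancestry == "lineage":
                ok = tree.is_ancestor(c_origin, comp_origin)
            else:
                ok = tree.depth(c_origin) < tree.depth(comp_origin)
            if not ok:
                reason = "non_ancestral_component"
                break
        calls.append(
            FusionCall(
                og_id=og,
                composite=True,
                components=comps,
                composite_origin=comp_origin,
                component_origins=comp_origins,
                bona_fide=reason == "none",
                reason=reason,
            )
        )
    return calls


def fusion_origination_flags(
    calls: list[FusionCall],
) -> set[tuple[str, str]]:
    """(node, og) pairs whose origination is explained by a bona fide fusion."""
    return {(c.composite_origin, c.og_id) for c in calls if c.bona_fide}
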