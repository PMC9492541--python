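"""Fractional functional-category and KO profiles of orthogroups.

Each annotated sequence first distributes a unit of weight evenly over its
category letters (a sequence annotated {B, K} counts 0.5 B and 0.5 K); the
cluster profile is the average of these unit vectors over its members.  A
two-member cluster with one {K} member and one {B, K} member is therefore
0.75 K + 0.25 B.

By default the average runs over the *annotated* members only, so sparse
annotation coverage does not dilute profiles; set
``include_unannotated=True`` to divide by all members instead.  The
"unknown function" category S carries no functional information and is
removed (with renormalization) before any downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import InputError, SequenceAnnotation, UNKNOWN_CATEGORY


@dataclass(frozen=True)
class CategoryProfile:
    """Non-negative category weights of one orthogroup, summing to 1 (or empty)."""

    og_id: str
    weights: dict[str, float] = field(default_factory=dict)
    annotated_member_count: int = 0
    total_member_count: int = 0

    def mass(self, letters: Iterable[str] | None = None) -> float:
        """Total weight, optionally restricted to a letter set."""
        if letters is None:
            return sum(self.weights.values())
        wanted = set(letters)
        return sum(w for let, w in self.weights.items() if let in wanted)


@dataclass(frozen=True)
class KOProfile:
    og_id: str
    weights: dict[str, float] = field(default_factory=dict)
    annotated_member_count: int = 0
    total_member_count: int = 0

    def mass(self, ko_ids: Iterable[str] | None = None) -> float:
        if ko_ids is None:
            return sum(self.weights.values())
        wanted = set(ko_ids)
        return sum(w for ko, w in self.weights.items() if ko in wanted)


def sequence_weights(annotation: SequenceAnnotation) -> dict[str, float]:
    """Unit weight split evenly over a sequence's category letters."""
    letters = sorted(annotation.cog_letters)
    if not letters:
        return {}
    share = 1.0 / len(letters)
    return {letter: share for letter in letters}


def _averaged(
    members: list[SequenceAnnotation],
    attr: str,
    include_unannotated: bool,
) -> tuple[dict[str, float], int, int]:
    ogs = {m.og_id for m in members}
    if len(ogs) > 1:
        raise InputError(f"members span multiple orthogroups: {sorted(ogs)}")
    annotated = [m for m in members if getattr(m, attr)]
    denom = len(members) if include_unannotated else len(annotated)
    totals: dict[str, float] = {}
    for member in annotated:
        labels = sorted(getattr(member, attr))
        share = 1.0 / (len(labels) * denom)
        for label in labels:
            totals[label] = totals.get(label, 0.0) + share
    return totals, len(annotated), len(members)


def cluster_profile(
    members: list[SequenceAnnotation],
    include_unannotated: bool = False,
) -> CategoryProfile:
    """Average the members' per-sequence category weights into one profile."""
    if not members:
        raise InputError("cluster_profile requires at least one member")
    weights, n_annot, n_total = _averaged(members, "cog_letters", include_unannotated)
    return CategoryProfile(members[0].og_id, weights, n_annot, n_total)


def ko_profile(
    members: list[SequenceAnnotation],
    include_unannotated: bool = False,
) -> KOProfile:
    """Same averaging as :func:`cluster_profile`, over KO identifiers."""
    if not members:
        raise InputError("ko_profile requires at least one member")
    weights, n_annot, n_total = _averaged(members, "ko_ids", include_unannotated)
    return KOProfile(members[0].og_id, weights, n_annot, n_total)


def exclude_unknown(profile: CategoryProfile) -> CategoryProfile:
    """Drop the S (unknown function) category and renormalize to 1."""
    if UNKNOWN_CATEGORY not in profile.weights:
        return profile
    kept = {k: v for k, v in profile.weights.items() if k != UNKNOWN_CATEGORY}
    total = sum(kept.values())
    if total > 0:
        kept = {k: v / total for k, v in kept.items()}
    return CategoryProfile(
        profile.og_id, kept, profile.annotated_member_count, profile.total_member_count
    )


def build_profiles(
    annotations: list[SequenceAnnotation],
    include_unannotated: bool = False,
    drop_unknown: bool = True,
) -> tuple[dict[str, CategoryProfile], dict[str, KOProfile]]:
    """Group annotations by orthogroup and profile every cluster."""
    by_og: dict[str, list[SequenceAnnotation]] = {}
    for ann in annotations:
        by_og.setdefault(ann.og_id, []).append(ann)
    cats: dict[str, CategoryProfile] = {}
    kos: dict[str, KOProfile] = {}
    for og, members in sorted(by_og.items()):
        prof = cluster_profile(members, include_unannotated)
        cats[og] = exclude_unknown(prof) if drop_unknown else prof
        kos[og] = ko_profile(members, include_unannotated)
    return cats, kos


def write_profiles(
    profiles: Mapping[str, CategoryProfile] | Mapping[str, KOProfile],
    path: str | Path,
    label_col: str = "letter",
    include_unannotated: bool = False,
) -> None:
    rows = [
        {"og": og, label_col: label, "weight": weight}
        for og, prof in sorted(profiles.items())
        for label, weight in sorted(prof.weights.items())
    ]
    policy = "all-members" if include_unannotated else "annotated-members-only"
    with open(path, "w") as fh:
        fh.write(f"# averaging denominator: {policy}\n")
        pd.DataFrame(rows, columns=["og", label_col, "weight"]).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_profiles(path: str | Path, kind: str = "category") -> dict[str, CategoryProfile] | dict[str, KOProfile]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"og": str})
    label_col = frame.columns[1]
    cls = CategoryProfile if kind == "category" else KOProfile
    out: dict = {}
    for og, sub in frame.groupby("og"):
        out[og] = cls(og, dict(zip(sub[label_col], sub["weight"].astype(float))))
    return out
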