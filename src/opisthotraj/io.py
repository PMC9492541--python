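"""Readers, writers and validation for the pipeline's tabular inputs.

All tables are plain TSV with mandatory headers; labels are case-sensitive
and addressed by name, never by position.  Dialects:

=============  =======================================================
event table    ``node og copies originations duplications transfers losses``
annotations    ``seq og cog ko`` (cog = concatenated letters, ko =
               comma-separated ids; empty cells = unannotated)
hit tables     ``query target score qcov tcov``
composites     ``seq is_composite components`` (components comma-separated)
=============  =======================================================
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import SpeciesTree

#: Single-letter functional-category alphabet (COG-style); "S" (unknown
#: function) is legal on input but excluded from downstream compositions.
COG_LETTERS = frozenset(string.ascii_uppercase)
UNKNOWN_CATEGORY = "S"

EVENT_COLUMNS = ["node", "og", "copies", "originations", "duplications", "transfers", "losses"]
EVENT_VALUE_COLUMNS = EVENT_COLUMNS[2:]


class InputError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class SequenceAnnotation:
    """Functional annotation of one sequence: category letters and KO ids."""

    seq_id: str
    og_id: str
    cog_letters: frozenset[str] = frozenset()
    ko_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = self.cog_letters - COG_LETTERS
        if bad:
            raise InputError(f"{self.seq_id}: unrecognized category letters {sorted(bad)}")


@dataclass(frozen=True)
class CompositeRecord:
    seq_id: str
    og_id: str
    is_composite: bool
    components: tuple[str, ...] = ()


class EventTable:
    """Per-(node, orthogroup) reconciliation expectations.

    Values are non-negative reals, not integers: reconciliation programs
    report expectations over sampled histories, and every downstream
    accounting step is defined on reals.  Missing (node, og) pairs mean
    all-zero.
    """

    def __init__(self, frame: pd.DataFrame, tree: SpeciesTree | None = None):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"event table missing columns: {missing}")
        frame = frame[EVENT_COLUMNS].copy()
        frame[EVENT_VALUE_COLUMNS] = frame[EVENT_VALUE_COLUMNS].astype(float)
        neg = frame[EVENT_VALUE_COLUMNS].lt(0).any(axis=1)
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise InputError(f"negative event value at row {row + 1}")
        if tree is not None:
            known = set(tree.nodes)
            unknown = frame.loc[~frame["node"].isin(known), "node"]
            if len(unknown):
                row = int(unknown.index[0]) + 1
                raise InputError(f"unknown node label {unknown.iloc[0]!r} at row {row}")
        self.frame = frame.reset_index(drop=True)
        self.tree = tree

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def og_ids(self) -> list[str]:
        return sorted(self.frame["og"].unique())

    def copies_matrix(self, nodes: list[str] | None = None) -> pd.DataFrame:
        """Dense nodes x ogs matrix of expected copy numbers (zeros imputed)."""
        mat = self.frame.pivot_table(index="node", columns="og", values="copies",
                                     aggfunc="sum", fill_value=0.0)
        if nodes is not None:
            mat = mat.reindex(index=nodes, fill_value=0.0)
        return mat

    def origination_nodes(self, tree: SpeciesTree | None = None) -> tuple[dict[str, str], set[str]]:
        """Map og -> origination node, plus the set of pre-root families.

        The origination node is the node with recorded originations closest
        to the root (preorder order breaks depth ties).  Families with
        copies at the root but no originations anywhere ("pre-root") resolve
        to the root.
        """
        tree = tree or self.tree
        if tree is None:
            raise InputError("a species tree is required to resolve origination nodes")
        order = {label: i for i, label in enumerate(tree.preorder())}
        origin: dict[str, str] = {}
        pre_root: set[str] = set()
        f = self.frame
        with_orig = f[f["originations"] > 0]
        for og, sub in with_orig.groupby("og"):
            origin[og] = min(sub["node"], key=lambda n: (tree.depth(n), order[n]))
        rooted = f[(f["node"] == tree.root) & (f["copies"] > 0)]["og"]
        for og in rooted:
            if og not in origin:
                origin[og] = tree.root
                pre_root.add(og)
        orphans = set(f["og"]) - set(origin) - set(f.loc[f["copies"] > 0, "og"])
        # ogs with neither originations nor any copies are tolerated (all-zero)
        silent = sorted(set(f["og"]) - set(origin) - orphans)
        for og in silent:
            # copies somewhere but no origination and absent at root: treat the
            # shallowest node with copies as the origination point.
            sub = f[(f["og"] == og) & (f["copies"] > 0)]
            origin[og] = min(sub["node"], key=lambda n: (tree.depth(n), order[n]))
            pre_root.discard(og)
        return origin, pre_root


def read_event_table(path: str | Path, tree: SpeciesTree) -> EventTable:
    frame = pd.read_csv(path, sep="\t", dtype={"node": str, "og": str})
    return EventTable(frame, tree=tree)


def write_event_table(table: EventTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotations(path: str | Path) -> list[SequenceAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("seq", "og", "cog", "ko"):
        if col not in frame.columns:
            raise InputError(f"annotation table missing column {col!r}")
    out = []
    for rec in frame.itertuples(index=False):
        letters = frozenset(rec.cog) if rec.cog else frozenset()
        kos = frozenset(k for k in rec.ko.split(",") if k) if rec.ko else frozenset()
        out.append(SequenceAnnotation(rec.seq, rec.og, letters, kos))
    return out


def write_annotations(annotations: list[SequenceAnnotation], path: str | Path) -> None:
    rows = [
        {
            "seq": a.seq_id,
            "og": a.og_id,
            "cog": "".join(sorted(a.cog_letters)),
            "ko": ",".join(sorted(a.ko_ids)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["seq", "og", "cog", "ko"]).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path, deduplicate: bool = True) -> pd.DataFrame:
    """Read a homology hit table; keeps the best-scoring row per pair.

    Coverages are percentages in [0, 100].  Deduplication keeps the highest
    score for each (query, target) pair, breaking ties on row order.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    for col in ("query", "target", "score", "qcov", "tcov"):
        if col not in frame.columns:
            raise InputError(f"hit table missing column {col!r}")
    bad = frame[(frame["qcov"] < 0) | (frame["qcov"] > 100) | (frame["tcov"] < 0) | (frame["tcov"] > 100)]
    if len(bad):
        raise InputError(f"coverage outside [0, 100] at row {int(bad.index[0]) + 1}")
    if deduplicate:
        frame = (
            frame.sort_values("score", ascending=False, kind="stable")
            .drop_duplicates(["query", "target"])
            .sort_index()
            .reset_index(drop=True)
        )
    return frame


def write_hit_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_composites(path: str | Path) -> list[CompositeRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("seq", "og", "is_composite", "components"):
        if col not in frame.columns:
            raise InputError(f"composite table missing column {col!r}")
    out = []
    for rec in frame.itertuples(index=False):
        flag = rec.is_composite in ("1", "true", "True")
        comps = tuple(c for c in rec.components.split(",") if c) if rec.components else ()
        if flag and not comps:
            raise InputError(f"composite sequence {rec.seq!r} lists no components")
        out.append(CompositeRecord(rec.seq, rec.og, flag, comps))
    return out


def write_composites(records: list[CompositeRecord], path: str | Path) -> None:
    rows = [
        {
            "seq": r.seq_id,
            "og": r.og_id,
            "is_composite": int(r.is_composite),
            "components": ",".join(r.components),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["seq", "og", "is_composite", "components"]).to_csv(
        path, sep="\t", index=False
    )
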