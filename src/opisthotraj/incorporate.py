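"""Incorporation of external (prokaryotic/viral) homologues into orthogroups.

Candidate external sequences come from a forward search (internal queries
against the external database) and a reverse search (the matched external
sequences aligned back against the internal database).  Three filters are
applied, in order:

1. any hit, in either direction, with query or target coverage below the
   threshold (default 75%) is discarded — at-threshold coverage passes;
2. an external sequence is discarded when the best-scoring internal target
   of its reverse hits belongs to a different orthogroup than the
   best-scoring internal query that hit it in the forward direction
   (reciprocity at the cluster level);
3. each internal sequence contributes at most its single best-scoring
   surviving external query, and the per-orthogroup result is deduplicated —
   a cluster whose 300 members all best-hit the same external sequence
   gains exactly one external member.

Best-scoring ties break deterministically: higher score first, then the
lexicographically smaller sequence id.
"""

from __future__ import annotations

import pandas as pd

from .io import InputError


def _best_by_group(frame: pd.DataFrame, group_col: str, pick_col: str) -> pd.Series:
    """Best-scoring ``pick_col`` value per ``group_col`` (score desc, id asc)."""
    ordered = frame.sort_values(
        ["score", pick_col], ascending=[False, True], kind="stable"
    )
    return ordered.drop_duplicates(group_col).set_index(group_col)[pick_col]


def incorporate_external_homologues(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    membership: dict[str, str],
    coverage_threshold: float = 75.0,
) -> dict[str, set[str]]:
    """Return map orthogroup id -> set of incorporated external sequence ids.

    Parameters
    ----------
    forward :
        Hits with internal sequences as ``query`` and external sequences as
        ``target`` (columns ``query target score qcov tcov``), deduplicated
        to the best score per pair.
    reverse :
        Hits with external sequences as ``query`` and internal sequences as
        ``target``.
    membership :
        Map internal sequence id -> orthogroup id.
    coverage_threshold :
        Hits with query or target coverage strictly below this value are
        discarded (default 75, matching the published filter).
    """
    for frame, direction in ((forward, "forward"), (reverse, "reverse")):
        internal_col = "query" if direction == "forward" else "target"
        unknown = set(frame[internal_col]) - set(membership)
        if unknown:
            raise InputError(
                f"{direction} hits reference internal sequences without "
                f"orthogroup membership: {sorted(unknown)[:5]}"
            )

    def covered(frame: pd.DataFrame) -> pd.DataFrame:
        return frame[
            (frame["qcov"] >= coverage_threshold) & (frame["tcov"] >= coverage_threshold)
        ]

    fwd = covered(forward)
    rev = covered(reverse)
    if fwd.empty or rev.empty:
        return {}

    # rule 2: cluster-level reciprocity per external sequence
    best_fwd_internal = _best_by_group(fwd, "target", "query")   # external -> internal
    best_rev_internal = _best_by_group(rev, "query", "target")   # external -> internal
    reciprocal_externals = {
        ext
        for ext, rev_target in best_rev_internal.items()
        if ext in best_fwd_internal.index
        and membership[best_fwd_internal[ext]] == membership[rev_target]
    }
    rev = rev[rev["query"].isin(reciprocal_externals)]
    if rev.empty:
        return {}

    # rule 3: one external per internal sequence, deduplicated per orthogroup
    best_external = _best_by_group(rev, "target", "query")       # internal -> external
    incorporated: dict[str, set[str]] = {}
    for internal, external in best_external.items():
        incorporated.setdefault(membership[internal], set()).add(external)
    return incorporated
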