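"""Gene-content evolution simulator with full ground truth.

Families are born, duplicated, transferred and lost along a species tree
in a discrete branch walk (per branch, in order: losses, duplications,
transfers, originations), which conserves the bookkeeping identity

    copies(child) = copies(parent) + originations + duplications
                    + transfers - losses

exactly for every family.  Clade-specific gain biases are planted by
tilting the category distribution of new originations inside a focal
clade by per-category multipliers — the statistical structure that the
downstream compositional analyses are built to detect.  On top of the
event table the simulator emits per-sequence annotations (with optional
multi-label and missing-annotation noise), composite/component relations
with true fusions and planted decoys, and forward/reverse homology hit
tables with a known incorporation outcome, so every pipeline stage can be
checked against recorded truth without any external data.

All randomness flows from one master seed; each stage draws from its own
deterministically derived substream so stages can be regenerated
independently.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    CompositeRecord,
    EventTable,
    SequenceAnnotation,
    write_annotations,
    write_composites,
    write_event_table,
    write_hit_table,
)
from .tree import SpeciesTree, write_newick

DEFAULT_CATEGORIES = ("C", "E", "G", "K", "O", "P", "T", "U", "W", "Z")


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per unit branch length: ``origination_rate`` new families per
    branch (Poisson), ``duplication_rate`` per surviving copy,
    ``transfer_rate`` transfer-in events per branch, ``loss_rate`` the
    per-copy exponential loss intensity.  ``clade_multipliers`` maps a
    clade tag ("A"/"B") to per-category multipliers applied to the
    origination category distribution inside that clade.
    """

    seed: int
    n_tips_a: int = 4
    n_tips_b: int = 5
    branch_length: float = 1.0
    root_families: int = 1000
    origination_rate: float = 150.0
    duplication_rate: float = 0.02
    transfer_rate: float = 5.0
    loss_rate: float = 0.03
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    baseline: dict[str, float] | None = None
    clade_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    p_multi: float = 0.0
    p_unannotated: float = 0.0
    metabolic_fraction: float = 0.40
    membrane_transport_fraction: float = 0.05
    n_true_fusions: int = 10
    n_decoys: int = 10
    member_composite_fraction: float = 0.8
    n_external: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        if not self.categories:
            raise SimulationError("category alphabet must be non-empty")
        for rate in (self.origination_rate, self.duplication_rate,
                     self.transfer_rate, self.loss_rate):
            if rate < 0:
                raise SimulationError("rates must be non-negative")
        if self.branch_length <= 0:
            raise SimulationError("branch lengths must be positive")
        if self.baseline is None:
            p = 1.0 / len(self.categories)
            self.baseline = {c: p for c in self.categories}
        total = sum(self.baseline.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimulationError("baseline category distribution must sum to 1")
        for mults in self.clade_multipliers.values():
            if any(m <= 0 for m in mults.values()):
                raise SimulationError("clade multipliers must be positive")


@dataclass
class SimTruth:
    """Everything the generator knows about the dataset it emitted."""

    tree: SpeciesTree
    clade_roots: dict[str, str]
    og_table: pd.DataFrame               # og, category, origin, ko, ko_class
    copies: pd.DataFrame                 # nodes x ogs, true copy numbers
    composition: pd.DataFrame            # nodes x categories, true counts
    gains_by_mechanism: pd.DataFrame     # node x {originations,duplications,transfers}
    config: SimConfig
    composites: list[CompositeRecord] = field(default_factory=list)
    true_fusion_ogs: set[str] = field(default_factory=set)
    decoy_ogs: set[str] = field(default_factory=set)
    expected_incorporation: dict[str, set[str]] = field(default_factory=dict)
    member_counts: dict[str, int] = field(default_factory=dict)

    def relative_composition(self) -> pd.DataFrame:
        sums = self.composition.sum(axis=1).replace(0.0, 1.0)
        return self.composition.div(sums, axis=0)

    def observable_composition(self) -> pd.DataFrame:
        """True composition restricted to families with extant (tip) members.

        Families that died out before reaching any tip leave no sequences to
        annotate, so profile-based reconstructions cannot see them; this is
        the matrix a noise-free reconstruction recovers exactly.
        """
        extant = [og for og in self.copies.columns if og in self.member_counts]
        cats = self.og_table.set_index("og")["category"]
        sub = self.copies[extant]
        out = pd.DataFrame(0.0, index=self.composition.index,
                           columns=self.composition.columns)
        grouped = sub.T.groupby(cats.loc[extant]).sum().T
        for col in grouped.columns:
            out[col] = grouped[col]
        return out

    def true_shift(self, node: str, letters: set[str]) -> float:
        """Planted compositional shift (percentage points) at ``node``."""
        rel = self.relative_composition()
        cols = [c for c in rel.columns if c in letters]
        parent = self.tree.parent[node]
        return float(100.0 * (rel.loc[node, cols].sum() - rel.loc[parent, cols].sum()))


def stage_seed(master: int, stage: str) -> int:
    """Derive an independent 31-bit substream seed for a named stage."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_two_clade_tree(
    n_tips_a: int, n_tips_b: int, branch_length: float = 1.0
) -> tuple[SpeciesTree, dict[str, str]]:
    """Pectinate two-clade tree: root O, clade roots A1 and B1."""
    if n_tips_a < 2 or n_tips_b < 2:
        raise SimulationError("each clade needs at least two tips")
    parent: dict[str, str] = {}
    children: dict[str, tuple[str, ...]] = {}
    lengths: dict[str, float] = {}
    groups: dict[str, str] = {}

    def build(prefix: str, n: int) -> str:
        internals = [f"{prefix.upper()}{i}" for i in range(1, n)]
        tips = [f"{prefix}{i}" for i in range(1, n + 1)]
        for i, node in enumerate(internals):
            left_tip = tips[i]
            right = internals[i + 1] if i + 1 < len(internals) else tips[i + 1]
            children[node] = (left_tip, right)
            parent[left_tip] = node
            parent[right] = node
        last = internals[-1]
        children[last] = (tips[-2], tips[-1])
        parent[tips[-2]] = last
        parent[tips[-1]] = last
        for t in tips:
            children[t] = ()
            groups[t] = prefix.upper()
        groups[internals[0]] = prefix.upper()
        return internals[0]

    root_a = build("a", n_tips_a)
    root_b = build("b", n_tips_b)
    children["O"] = (root_a, root_b)
    parent[root_a] = "O"
    parent[root_b] = "O"
    for node in parent:
        lengths[node] = branch_length
    tree = SpeciesTree(parent=parent, root="O", children=children,
                       groups=groups, branch_lengths=lengths)
    return tree, {"A": root_a, "B": root_b}


def _clade_of(tree: SpeciesTree, clade_roots: dict[str, str], node: str) -> str | None:
    for tag, root in clade_roots.items():
        if node == root or tree.is_ancestor(root, node):
            return tag
    return None


def simulate_gene_content(
    config: SimConfig,
    tree: SpeciesTree | None = None,
    clade_roots: dict[str, str] | None = None,
) -> tuple[EventTable, SimTruth]:
    """Run the branch walk and return the event table plus ground truth."""
    if tree is None:
        tree, clade_roots = make_two_clade_tree(
            config.n_tips_a, config.n_tips_b, config.branch_length
        )
    clade_roots = clade_roots or {}
    rng = np.random.default_rng(stage_seed(config.seed, "gene_content"))
    cats = list(config.categories)
    baseline = np.array([config.baseline[c] for c in cats])

    def tilted(clade: str | None) -> np.ndarray:
        probs = baseline.copy()
        if clade and clade in config.clade_multipliers:
            for i, c in enumerate(cats):
                probs[i] *= config.clade_multipliers[clade].get(c, 1.0)
        return probs / probs.sum()

    family_category: list[str] = []
    family_origin: list[str] = []

    def new_families(n: int, node: str, clade: str | None) -> np.ndarray:
        idx = np.arange(len(family_category), len(family_category) + n)
        drawn = rng.choice(len(cats), size=n, p=tilted(clade))
        family_category.extend(cats[k] for k in drawn)
        family_origin.extend([node] * n)
        return idx

    copies_at: dict[str, np.ndarray] = {}
    rows: list[dict] = []

    # root content: pre-root families (no origination events recorded)
    root_idx = new_families(config.root_families, tree.root, None)
    copies_at[tree.root] = np.ones(len(root_idx), dtype=np.int64)
    gains_rows = {}

    for node in tree.preorder():
        if node == tree.root:
            continue
        par = tree.parent[node]
        length = tree.branch_lengths.get(node, config.branch_length)
        c_par = copies_at[par]
        F = len(family_category)
        c = np.zeros(F, dtype=np.int64)
        c[: len(c_par)] = c_par

        p_loss = 1.0 - math.exp(-config.loss_rate * length)
        losses = rng.binomial(c, p_loss)
        survivors = c - losses
        dups = rng.poisson(config.duplication_rate * length * survivors)

        transfers = np.zeros(F, dtype=np.int64)
        n_trans = rng.poisson(config.transfer_rate * length)
        depth_v = tree.depth(node)
        eligible = np.array(
            [i for i in range(F) if tree.depth(family_origin[i]) < depth_v],
            dtype=np.int64,
        )
        if len(eligible) and n_trans:
            chosen = rng.choice(eligible, size=n_trans, replace=True)
            np.add.at(transfers, chosen, 1)

        clade = _clade_of(tree, clade_roots, node)
        n_orig = rng.poisson(config.origination_rate * length)
        born = new_families(n_orig, node, clade)
        F_new = len(family_category)
        c_new = np.zeros(F_new, dtype=np.int64)
        c_new[:F] = survivors + dups + transfers
        c_new[born] = 1
        copies_at[node] = c_new

        originations = np.zeros(F_new, dtype=np.int64)
        originations[born] = 1
        losses_full = np.zeros(F_new, dtype=np.int64)
        losses_full[:F] = losses
        dups_full = np.zeros(F_new, dtype=np.int64)
        dups_full[:F] = dups
        trans_full = np.zeros(F_new, dtype=np.int64)
        trans_full[:F] = transfers

        active = np.flatnonzero(
            (c_new > 0) | (originations > 0) | (losses_full > 0)
            | (dups_full > 0) | (trans_full > 0)
        )
        for i in active:
            rows.append(
                {
                    "node": node,
                    "og": f"og{i:05d}",
                    "copies": float(c_new[i]),
                    "originations": float(originations[i]),
                    "duplications": float(dups_full[i]),
                    "transfers": float(trans_full[i]),
                    "losses": float(losses_full[i]),
                }
            )
        gains_rows[node] = {
            "originations": float(originations.sum()),
            "duplications": float(dups_full.sum()),
            "transfers": float(trans_full.sum()),
        }

    for i in root_idx:
        rows.append(
            {
                "node": tree.root,
                "og": f"og{i:05d}",
                "copies": 1.0,
                "originations": 0.0,
                "duplications": 0.0,
                "transfers": 0.0,
                "losses": 0.0,
            }
        )

    frame = pd.DataFrame(rows, columns=["node", "og", "copies", "originations",
                                        "duplications", "transfers", "losses"])
    frame = frame.sort_values(["node", "og"], kind="stable").reset_index(drop=True)
    events = EventTable(frame, tree=tree)

    og_ids = [f"og{i:05d}" for i in range(len(family_category))]
    ko_rng = np.random.default_rng(stage_seed(config.seed, "ko_classes"))
    draws = ko_rng.random(len(og_ids))
    ko_class = np.where(
        draws < config.metabolic_fraction,
        "metabolic",
        np.where(
            draws < config.metabolic_fraction + config.membrane_transport_fraction,
            "membrane_transport",
            "other",
        ),
    )
    og_table = pd.DataFrame(
        {
            "og": og_ids,
            "category": family_category,
            "origin": family_origin,
            "ko": [f"K{i:05d}" for i in range(len(og_ids))],
            "ko_class": ko_class,
        }
    )

    nodes = tree.nodes
    F_total = len(family_category)
    copy_mat = np.zeros((len(nodes), F_total), dtype=np.int64)
    for k, node in enumerate(nodes):
        arr = copies_at[node]
        copy_mat[k, : len(arr)] = arr
    copies_df = pd.DataFrame(copy_mat, index=nodes, columns=og_ids)
    cat_series = pd.Series(family_category, index=og_ids)
    comp = copies_df.T.groupby(cat_series).sum().T.reindex(columns=cats, fill_value=0).astype(float)
    gains = pd.DataFrame(gains_rows).T.reindex(
        [n for n in nodes if n != tree.root]
    )

    member_counts: dict[str, int] = {}
    for tip in tree.tips:
        arr = copies_at[tip]
        for i in np.flatnonzero(arr):
            og = og_ids[i]
            member_counts[og] = member_counts.get(og, 0) + int(arr[i])

    truth = SimTruth(
        tree=tree,
        clade_roots=clade_roots,
        og_table=og_table,
        copies=copies_df,
        composition=comp,
        gains_by_mechanism=gains,
        config=config,
        member_counts=member_counts,
    )
    return events, truth


def simulate_annotations(truth: SimTruth, config: SimConfig | None = None) -> list[SequenceAnnotation]:
    """One pseudo-sequence per extant (tip) copy, with configurable noise."""
    config = config or truth.config
    rng = np.random.default_rng(stage_seed(config.seed, "annotations"))
    cats = list(config.categories)
    noise_letters = cats + ["S"]
    meta = truth.og_table.set_index("og")
    out: list[SequenceAnnotation] = []
    events_needed = truth.member_counts  # og -> tip copy count
    # regenerate per-tip copies from the truth composition is not possible
    # per og, so we walk the member counts in a deterministic per-og order.
    per_tip: dict[str, list[str]] = {}
    # member ids are tip-agnostic: og-scoped numbering keeps them stable.
    for og in sorted(events_needed):
        n = events_needed[og]
        category = meta.at[og, "category"]
        ko = meta.at[og, "ko"]
        for j in range(n):
            seq_id = f"{og}|m{j:03d}"
            if rng.random() < config.p_unannotated:
                out.append(SequenceAnnotation(seq_id, og))
                continue
            letters = {category}
            if rng.random() < config.p_multi:
                extra = noise_letters[rng.integers(len(noise_letters))]
                if extra != category:
                    letters.add(extra)
            out.append(SequenceAnnotation(seq_id, og, frozenset(letters), frozenset({ko})))
    return out


def simulate_composites(truth: SimTruth, config: SimConfig | None = None) -> list[CompositeRecord]:
    """Plant true fusions and decoy composites over the simulated families.

    True fusions get two components that originated at proper ancestors of
    the composite's origination node; decoys get at least one component
    that originated at the same node (or, alternating, in a non-ancestral
    lineage).  Per family, ``floor(member_composite_fraction * members)``
    member sequences carry the composite flag.
    """
    config = config or truth.config
    rng = np.random.default_rng(stage_seed(config.seed, "composites"))
    tree = truth.tree
    meta = truth.og_table.set_index("og")
    counts = truth.member_counts

    n_wanted = config.n_true_fusions + config.n_decoys
    if n_wanted == 0:
        truth.composites = []
        return []

    origin = meta["origin"]
    eligible_components = {
        og for og, n in counts.items() if n > 1  # singletons are never components
    }
    candidates = []
    for og in sorted(counts):
        if counts[og] < 3:
            continue
        node = origin[og]
        if node == tree.root:
            continue
        ancestral = [
            c for c in eligible_components
            if c != og and tree.is_ancestor(origin[c], node)
        ]
        same_node = [c for c in eligible_components if c != og and origin[c] == node]
        non_anc = [
            c for c in eligible_components
            if c != og and origin[c] != node and not tree.is_ancestor(origin[c], node)
        ]
        candidates.append((og, ancestral, same_node, non_anc))

    true_ok = [c for c in candidates if len(c[1]) >= 2]
    if len(true_ok) < config.n_true_fusions:
        raise SimulationError(
            f"cannot plant {config.n_true_fusions} true fusions: only "
            f"{len(true_ok)} families have two ancestrally originated components "
            f"available (deficit {config.n_true_fusions - len(true_ok)})"
        )
    picked_true = [true_ok[i][0] for i in
                   rng.choice(len(true_ok), size=config.n_true_fusions, replace=False)]
    remaining = [c for c in candidates if c[0] not in set(picked_true)
                 and (c[2] or c[3]) and c[1]]
    if len(remaining) < config.n_decoys:
        raise SimulationError(
            f"cannot plant {config.n_decoys} decoys: only {len(remaining)} "
            f"eligible families remain (deficit {config.n_decoys - len(remaining)})"
        )
    decoy_rows = [remaining[i] for i in
                  rng.choice(len(remaining), size=config.n_decoys, replace=False)]

    by_og = {c[0]: c for c in candidates}
    records: list[CompositeRecord] = []
    truth.true_fusion_ogs = set(picked_true)
    truth.decoy_ogs = {c[0] for c in decoy_rows}

    def components_for(og: str, decoy_rank: int | None) -> tuple[str, ...]:
        _, ancestral, same_node, non_anc = by_og[og]
        if decoy_rank is None:
            idx = rng.choice(len(ancestral), size=2, replace=False)
            return tuple(sorted(ancestral[i] for i in idx))
        good = ancestral[int(rng.integers(len(ancestral)))]
        pool = same_node if (decoy_rank % 2 == 0 and same_node) else non_anc
        if not pool:
            pool = same_node or non_anc
        bad = pool[int(rng.integers(len(pool)))]
        return tuple(sorted({good, bad}))

    def flag_members(og: str, comps: tuple[str, ...]) -> None:
        n = counts[og]
        n_flagged = int(math.floor(config.member_composite_fraction * n + 1e-9))
        for j in range(n):
            seq_id = f"{og}|m{j:03d}"
            if j < n_flagged:
                records.append(CompositeRecord(seq_id, og, True, comps))
            else:
                records.append(CompositeRecord(seq_id, og, False, ()))

    for og in sorted(picked_true):
        flag_members(og, components_for(og, None))
    for rank, row in enumerate(sorted(decoy_rows)):
        flag_members(row[0], components_for(row[0], rank))

    flagged = {r.og_id for r in records}
    for og in sorted(counts):
        if og in flagged:
            continue
        for j in range(counts[og]):
            records.append(CompositeRecord(f"{og}|m{j:03d}", og, False, ()))
    truth.composites = records
    return records


def simulate_hits(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward/reverse homology hit tables with a known incorporation outcome.

    Scenarios cycle over the chosen families: (0) a clean reciprocal
    external expected to be incorporated, (1) an external whose hits fail
    the 75% coverage rule by a hair (74.9), (2) an external whose best
    forward and reverse clusters disagree (reciprocity failure), (3) a
    boundary case with coverage exactly 75.0, expected to be incorporated.
    """
    config = config or truth.config
    rng = np.random.default_rng(stage_seed(config.seed, "hits"))
    counts = truth.member_counts
    ogs = [og for og in sorted(counts) if counts[og] >= 2]
    if len(ogs) < 2:
        raise SimulationError("need at least two multi-member families for hit tables")
    n_ext = min(config.n_external, len(ogs) - 1)
    chosen = [ogs[i] for i in rng.choice(len(ogs) - 1, size=n_ext, replace=False)]
    fwd_rows, rev_rows = [], []
    expected: dict[str, set[str]] = {}

    def member(og: str, j: int) -> str:
        return f"{og}|m{j:03d}"

    for k, og in enumerate(chosen):
        ext = f"ext{k:03d}"
        scenario = k % 4
        cov = 75.0 if scenario == 3 else float(np.round(80 + 15 * rng.random(), 1))
        n = counts[og]
        base = 200.0 + float(np.round(50 * rng.random(), 1))
        for j in range(n):
            score = base - j  # member m000 is the best reverse target
            qcov = 74.9 if scenario == 1 else cov
            fwd_rows.append({"query": member(og, j), "target": ext,
                             "score": score, "qcov": qcov, "tcov": cov})
            rev_rows.append({"query": ext, "target": member(og, j),
                             "score": score, "qcov": cov, "tcov": qcov})
        if scenario == 2:
            # a stronger reverse hit into a different family breaks reciprocity
            other = ogs[ogs.index(og) + 1]
            rev_rows.append({"query": ext, "target": member(other, 0),
                             "score": base + 50, "qcov": cov, "tcov": cov})
        if scenario in (0, 3):
            expected.setdefault(og, set()).add(ext)

    forward = pd.DataFrame(fwd_rows, columns=["query", "target", "score", "qcov", "tcov"])
    reverse = pd.DataFrame(rev_rows, columns=["query", "target", "score", "qcov", "tcov"])
    truth.expected_incorporation = expected
    return forward, reverse


def config_dict(config: SimConfig) -> dict:
    """Plain-YAML-safe dictionary form of a config (tuples become lists)."""
    raw = asdict(config)
    raw["categories"] = list(raw["categories"])
    return raw


def config_hash(config: SimConfig) -> str:
    blob = yaml.safe_dump(config_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_fixture(config: SimConfig, outdir: str | Path) -> Path:
    """Simulate everything and write a self-describing fixture directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events, truth = simulate_gene_content(config)
    annotations = simulate_annotations(truth, config)
    composites = simulate_composites(truth, config)
    forward, reverse = simulate_hits(truth, config)

    (outdir / "tree.nwk").write_text(write_newick(truth.tree) + "\n")
    write_event_table(events, outdir / "events.tsv")
    write_annotations(annotations, outdir / "annotations.tsv")
    write_composites(composites, outdir / "composites.tsv")
    write_hit_table(forward, outdir / "hits_forward.tsv")
    write_hit_table(reverse, outdir / "hits_reverse.tsv")
    truth.og_table[["ko", "ko_class"]].drop_duplicates().to_csv(
        outdir / "ko_classes.tsv", sep="\t", index=False
    )
    truth.og_table.to_csv(outdir / "truth_og.tsv", sep="\t", index=False)
    truth.composition.rename_axis("node").to_csv(
        outdir / "truth_composition.tsv", sep="\t", float_format="%.10g"
    )
    truth.gains_by_mechanism.rename_axis("node").to_csv(
        outdir / "truth_gains.tsv", sep="\t", float_format="%.10g"
    )
    pd.DataFrame(
        [{"og": og, "external": ext}
         for og in sorted(truth.expected_incorporation)
         for ext in sorted(truth.expected_incorporation[og])]
    ).to_csv(outdir / "expected_incorporation.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config_dict(config),
        "groups": {"clade_roots": truth.clade_roots},
        "true_fusions": sorted(truth.true_fusion_ogs),
        "decoys": sorted(truth.decoy_ogs),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return outdir
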