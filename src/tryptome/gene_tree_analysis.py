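"""Gene-tree inferences: ancestral clades, tandem pairs, monophyly.

Three read-outs of a gene phylogeny whose leaves carry taxon/locus
metadata (supplied as a sidecar table):

* **representation clades** — the deepest clades containing required
  minimum numbers of distinct species from named taxon groups (e.g. at
  least two anthozoan and two medusozoan species), each such clade being
  evidence of a distinct ancestral gene;
* **same-scaffold sister pairs** — cherries whose two genes come from the
  focal taxon and sit on one scaffold, the signature of tandem
  duplication, reported with the genomic gap between them;
* **monophyly** of an arbitrary leaf subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd


@dataclass(frozen=True)
class LeafMeta:
    taxon: str
    group: str | None = None
    scaffold: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class GeneTreeInfo:
    tree: dendropy.Tree
    meta: dict[str, LeafMeta]

    def __post_init__(self) -> None:
        missing = [
            lf.taxon.label
            for lf in self.tree.leaf_node_iter()
            if lf.taxon.label not in self.meta
        ]
        if missing:
            raise ValueError(f"leaves without metadata: {missing[:5]}")

    @classmethod
    def from_files(cls, newick_path: str | Path, meta_path: str | Path) -> "GeneTreeInfo":
        tree = dendropy.Tree.get(
            path=str(newick_path), schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        return cls(tree=tree, meta=read_leaf_metadata(meta_path))


@dataclass(frozen=True)
class CladeCall:
    """A clade satisfying a per-group representation criterion."""

    leaves: frozenset[str]
    criterion: tuple[tuple[str, int], ...]
    support: float | None = None


def read_leaf_metadata(path: str | Path) -> dict[str, LeafMeta]:
    """Sidecar TSV: leaf_id, taxon, group, scaffold, start, end (last four optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta = {}
    for r in df.itertuples(index=False):
        meta[r.leaf_id] = LeafMeta(
            taxon=r.taxon,
            group=getattr(r, "group", "") or None,
            scaffold=getattr(r, "scaffold", "") or None,
            start=int(r.start) if getattr(r, "start", "") else None,
            end=int(r.end) if getattr(r, "end", "") else None,
        )
    return meta


def write_leaf_metadata(meta: Mapping[str, LeafMeta], path: str | Path) -> None:
    rows = [
        {
            "leaf_id": leaf,
            "taxon": m.taxon,
            "group": m.group or "",
            "scaffold": m.scaffold or "",
            "start": "" if m.start is None else m.start,
            "end": "" if m.end is None else m.end,
        }
        for leaf, m in meta.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# representation clades
# ---------------------------------------------------------------------------

def _distinct_lineage(meta: LeafMeta, distinct_by: str) -> str:
    if distinct_by == "taxon":
        return meta.taxon
    if distinct_by == "genus":
        return meta.taxon.split()[0].split("_")[0]
    raise ValueError(f"unknown lineage mode {distinct_by!r}")


def _satisfies(
    leaves: Iterable[str],
    meta: Mapping[str, LeafMeta],
    criterion: Mapping[str, int],
    distinct_by: str,
) -> bool:
    seen: dict[str, set[str]] = {g: set() for g in criterion}
    for leaf in leaves:
        m = meta[leaf]
        if m.group in seen:
            seen[m.group].add(_distinct_lineage(m, distinct_by))
    return all(len(seen[g]) >= n for g, n in criterion.items())


def representation_clades(
    gt: GeneTreeInfo,
    criterion: Mapping[str, int],
    outgroup: Sequence[str] | None = None,
    distinct_by: str = "taxon",
) -> list[CladeCall]:
    """Deepest clades meeting every per-group minimum species count.

    Because group counts only grow toward the root, any ancestor of a
    satisfying clade also satisfies; the informative clades — each marking
    one ancestral gene — are those with no satisfying *descendant*.  They
    are mutually disjoint and returned sorted by leaf set.

    The tree must be rooted, or ``outgroup`` leaves must be given for
    rooting.  ``distinct_by`` controls what counts as one lineage
    ("taxon" = distinct species, "genus" = leading name token).
    """
    tree = gt.tree
    if outgroup:
        tree = tree.clone(depth=1)
        mrca = (
            tree.find_node_with_taxon_label(outgroup[0])
            if len(outgroup) == 1
            else tree.mrca(taxon_labels=list(outgroup))
        )
        if mrca is None:
            raise ValueError("outgroup taxa not found")
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    elif not tree.is_rooted:
        raise ValueError("tree is unrooted and no outgroup was given")

    calls: list[CladeCall] = []

    def visit(node: dendropy.Node) -> bool:
        """Returns True if any clade at/below node satisfies the criterion."""
        child_hits = [visit(c) for c in node.child_nodes()]
        if any(child_hits):
            return True
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if _satisfies(leaves, gt.meta, criterion, distinct_by):
            support = None
            if node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            calls.append(
                CladeCall(
                    leaves=frozenset(leaves),
                    criterion=tuple(sorted(criterion.items())),
                    support=support,
                )
            )
            return True
        return False

    visit(tree.seed_node)
    return sorted(calls, key=lambda c: sorted(c.leaves))


# ---------------------------------------------------------------------------
# tandem duplication candidates
# ---------------------------------------------------------------------------

def _genomic_gap(a: LeafMeta, b: LeafMeta) -> int | None:
    if None in (a.start, a.end, b.start, b.end):
        return None
    if a.start > b.start:
        a, b = b, a
    return max(b.start - a.end, 0)


def sister_same_scaffold(
    gt: GeneTreeInfo, focal_taxon: str
) -> list[tuple[tuple[str, str], str, int | None]]:
    """Cherries of focal-taxon genes sharing a scaffold, with genomic gaps.

    Each result is ((leaf1, leaf2), scaffold, gap_bp); the gap is the
    distance between the nearest feature ends (0 for overlapping features,
    None when coordinates are missing).  Sorted by gap, undefined gaps last.
    """
    out = []
    for node in gt.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2 or not all(c.is_leaf() for c in children):
            continue
        l1, l2 = sorted(c.taxon.label for c in children)
        m1, m2 = gt.meta[l1], gt.meta[l2]
        if m1.taxon != focal_taxon or m2.taxon != focal_taxon:
            continue
        if m1.scaffold is None or m1.scaffold != m2.scaffold:
            continue
        out.append(((l1, l2), m1.scaffold, _genomic_gap(m1, m2)))
    return sorted(out, key=lambda t: (t[2] is None, t[2] if t[2] is not None else 0, t[0]))


def same_scaffold_clades(
    gt: GeneTreeInfo, focal_taxon: str, min_size: int = 3
) -> list[tuple[frozenset[str], str]]:
    """Larger-than-cherry focal-taxon clades on one scaffold (candidates only)."""
    out = []
    for node in gt.tree.preorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if len(leaves) < min_size:
            continue
        metas = [gt.meta[l] for l in leaves]
        scaffolds = {m.scaffold for m in metas}
        if (
            all(m.taxon == focal_taxon for m in metas)
            and len(scaffolds) == 1
            and None not in scaffolds
        ):
            out.append((frozenset(leaves), metas[0].scaffold))
    return sorted(out, key=lambda t: sorted(t[0]))


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def monophyly(gt: GeneTreeInfo, leaf_subset: Iterable[str]) -> bool:
    """True iff the MRCA of the subset contains exactly the subset's leaves."""
    subset = set(leaf_subset)
    all_leaves = {lf.taxon.label for lf in gt.tree.leaf_node_iter()}
    unknown = subset - all_leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(subset) <= 1 or subset == all_leaves:
        return True
    mrca = gt.tree.mrca(taxon_labels=sorted(subset))
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == subset
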