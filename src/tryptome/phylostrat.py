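"""Phylostratigraphy of domains and domain associations on a species tree.

Each feature (a domain family, or a "trypsin+X" association meaning some
protein carries both a trypsin domain and family X) is dated by the most
recent common ancestor of all taxa possessing it — a single-gain (Dollo)
reading under which absences below the origin are losses.  Ages are ordinal
stratum ranks: the number of edges between a node and the root, so the root
is rank 0 (oldest) and larger ranks are younger.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from scipy.stats import spearmanr

from .hit_processing import DEFAULT_TRYPSIN_FAMILIES, Architecture

ASSOCIATION_PREFIX = "trypsin+"


@dataclass(frozen=True)
class OriginAssignment:
    """Dated origin of one feature.

    ``origin_leafset`` identifies the origin node by the taxa of its subtree
    (robust to unlabeled internal nodes); ``stratum`` is its root distance in
    edges.  ``inferred_losses`` are the maximal clades below the origin with
    no presence, each given as its leaf-taxon set.
    """

    feature: str
    origin_label: str | None
    origin_leafset: frozenset[str]
    stratum: int
    inferred_losses: tuple[frozenset[str], ...]


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree (from a path or a literal string)."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _node_level(node: dendropy.Node) -> int:
    level = 0
    while node.parent_node is not None:
        node = node.parent_node
        level += 1
    return level


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

def presence_from_architectures(
    per_taxon_archs: Mapping[str, Sequence[Architecture]],
    trypsin_families: frozenset[str] = DEFAULT_TRYPSIN_FAMILIES,
) -> pd.DataFrame:
    """Boolean feature-by-taxon matrix from per-taxon architectures.

    Features are every domain family seen anywhere plus every "trypsin+X"
    association; an association is present in a taxon iff some protein there
    carries both a trypsin-family domain and family X.
    """
    taxa = list(per_taxon_archs)
    families: set[str] = set()
    associations: set[str] = set()
    presence: dict[tuple[str, str], bool] = {}
    for taxon, archs in per_taxon_archs.items():
        for a in archs:
            fams = {d.family for d in a.domains}
            has_trypsin = bool(fams & trypsin_families)
            for f in fams:
                families.add(f)
                presence[(f, taxon)] = True
            if has_trypsin:
                for f in fams - trypsin_families:
                    assoc = ASSOCIATION_PREFIX + f
                    associations.add(assoc)
                    presence[(assoc, taxon)] = True
    features = sorted(families) + sorted(associations)
    mat = pd.DataFrame(False, index=features, columns=taxa)
    for (feat, taxon), val in presence.items():
        mat.loc[feat, taxon] = val
    return mat


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def write_presence_matrix(pm: pd.DataFrame, path: str | Path) -> None:
    pm.astype(int).to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# origin assignment
# ---------------------------------------------------------------------------

def _mrca(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Node:
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0])
        if node is None:
            raise ValueError(f"taxon {taxa[0]!r} not on tree")
        return node
    node = tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise ValueError(f"no MRCA found for {taxa}")
    return node


def _loss_clades(
    node: dendropy.Node, present: frozenset[str]
) -> list[frozenset[str]]:
    """Maximal all-absent clades below ``node`` (disjoint by construction)."""
    losses = []
    for child in node.child_nodes():
        leaves = _leaf_labels(child)
        if leaves & present:
            losses.extend(_loss_clades(child, present))
        else:
            losses.append(leaves)
    return losses


def assign_origin(
    pm: pd.DataFrame, tree: dendropy.Tree, warn_loss_count: int | None = None
) -> list[OriginAssignment]:
    """Date every feature at the MRCA of its presence taxa.

    Features with zero presence are skipped.  When ``warn_loss_count`` is
    set, features whose Dollo reading needs more than that many independent
    losses are additionally flagged (multiple independent gains are then an
    equally spartan explanation; the assignment itself is unchanged).
    """
    leaf_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assignments = []
    for feature, row in pm.iterrows():
        present = frozenset(t for t, v in row.items() if v)
        if not present:
            continue
        missing = present - leaf_set
        if missing:
            raise ValueError(f"feature {feature!r}: taxa not on tree: {sorted(missing)}")
        origin = _mrca(tree, sorted(present))
        losses = tuple(_loss_clades(origin, present))
        a = OriginAssignment(
            feature=str(feature),
            origin_label=origin.taxon.label if origin.taxon else origin.label,
            origin_leafset=_leaf_labels(origin),
            stratum=_node_level(origin),
            inferred_losses=losses,
        )
        assignments.append(a)
    if warn_loss_count is not None:
        import logging

        for a in assignments:
            if len(a.inferred_losses) > warn_loss_count:
                logging.getLogger(__name__).warning(
                    "feature %s needs %d losses under a single gain; "
                    "independent gains are plausible",
                    a.feature,
                    len(a.inferred_losses),
                )
    return assignments


# ---------------------------------------------------------------------------
# domain-age vs association-age
# ---------------------------------------------------------------------------

def age_relationship(
    domain_assignments: Iterable[OriginAssignment],
    association_assignments: Iterable[OriginAssignment],
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Pair each association's age with its partner domain's age.

    Returns the paired table (index: partner family X, columns
    domain_stratum / association_stratum) and the Spearman rank correlation
    (tie-corrected) over the pairs.  An association older than its own
    domain indicates inconsistent presence data and raises an error naming
    the feature.
    """
    dom = {a.feature: a for a in domain_assignments}
    rows = {}
    for a in association_assignments:
        if not a.feature.startswith(ASSOCIATION_PREFIX):
            raise ValueError(f"not an association feature: {a.feature!r}")
        partner = a.feature[len(ASSOCIATION_PREFIX):]
        if partner not in dom:
            raise ValueError(f"association {a.feature!r} has no matching domain feature")
        d = dom[partner]
        if a.stratum < d.stratum:
            raise ValueError(
                f"association {a.feature!r} predates its domain "
                f"(stratum {a.stratum} < {d.stratum}): inconsistent presence data"
            )
        rows[partner] = (d.stratum, a.stratum)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["domain_stratum", "association_stratum"]
    ).sort_index()
    if len(table) < 2:
        return table, (float("nan"), float("nan"))
    if (
        table["domain_stratum"].nunique() == 1
        or table["association_stratum"].nunique() == 1
    ):
        rho, p = float("nan"), float("nan")
        if (table["domain_stratum"] == table["association_stratum"]).all():
            rho = 1.0
    else:
        rho, p = spearmanr(table["domain_stratum"], table["association_stratum"])
        rho, p = float(rho), float(p)
    return table, (rho, p)


# ---------------------------------------------------------------------------
# tree pruning
# ---------------------------------------------------------------------------

def prune_tree(tree: dendropy.Tree, keep_taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep_taxa`` with unbranched internal nodes suppressed."""
    keep = list(dict.fromkeys(keep_taxa))
    if not keep:
        raise ValueError("keep_taxa must be nonempty")
    leaf_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(keep) - leaf_set
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    pruned.purge_taxon_namespace()
    return pruned


def write_origin_report(assignments: Sequence[OriginAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\torigin\tstratum\tn_losses\tloss_clades\n")
        for a in assignments:
            clades = ";".join(",".join(sorted(c)) for c in a.inferred_losses)
            origin = a.origin_label or ",".join(sorted(a.origin_leafset))
            fh.write(f"{a.feature}\t{origin}\t{a.stratum}\t{len(a.inferred_losses)}\t{clades}\n")
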