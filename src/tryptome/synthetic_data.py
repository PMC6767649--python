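"""Synthetic fixtures with planted ground truth for every pipeline stage.

Each generator writes the same plain-text formats the pipeline reads
(domtblout, GFF3, FASTA, Newick, TSV) together with a truth object, so
recovery of the planted signal can be checked exactly and offline.  A fixed
:class:`SimSpec` (including its seed) yields byte-identical files.

What the defaults emulate: a proteome whose trypsin-protein architectures
follow a catalog shaped like a real tryptome (a large trypsin-only class
plus multi-domain classes), trypsin domains occasionally reported as two
complementary partial hits, decoy hits straddling both E-value thresholds;
single-cell matrices whose trypsins-per-cell distribution has its mode at
one gene with a geometric tail of co-expressing cells and a planted
positive ubiquity-co-expression correlation; presence/absence characters
evolved by a single gain at a known node followed by independent lineage
losses; gene trees with planted same-scaffold sister pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------

DEFAULT_CATALOG: dict[str, float] = {
    # trypsin-only proteins dominate (28/72 in the reference tryptome)
    "Trypsin": 0.39,
    "Trypsin|ShK": 0.12,
    "Trypsin|ShK|ShK": 0.06,
    "Trypsin|PDZ": 0.08,
    "MAM|MAM|Trypsin": 0.07,
    "Trypsin|Sushi": 0.07,
    "Trypsin|SRCR": 0.06,
    "Trypsin|Astacin": 0.05,
    "Trypsin|Trypsin|Trypsin": 0.04,
    "Trypsin_2|ShK": 0.03,
    "Trypsin|WSC": 0.02,
    "Trypsin|Lustrin_cystein": 0.01,
}

FAMILY_LENGTHS: dict[str, int] = {
    "Trypsin": 220,
    "Trypsin_2": 230,
    "ShK": 35,
    "PDZ": 80,
    "MAM": 160,
    "Sushi": 55,
    "SRCR": 100,
    "Astacin": 200,
    "WSC": 90,
    "Lustrin_cystein": 60,
    "DIM": 40,
}

DECOY_FAMILIES: tuple[str, ...] = ("DUF4808", "zf-C2H2", "EGF", "Lectin_C", "Kazal_1")
DECOY_LENGTH = 45

PFAM_ACCESSIONS: dict[str, str] = {
    "Trypsin": "PF00089.29",
    "Trypsin_2": "PF13365.9",
}


@dataclass
class SimSpec:
    """Parameters and seed for every synthetic generator."""

    seed: int = 0
    # --- domain hits ---
    n_proteins: int = 50
    n_decoy_proteins: int = 20
    architecture_catalog: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATALOG)
    )
    split_probability: float = 0.25
    decoy_rate: float = 0.5  # expected decoy associated-domain hits per protein
    # --- cell matrix ---
    n_cells: int = 600
    n_genes: int = 60
    solo_weight: float = 0.49  # share of expressing cells with exactly one trypsin
    multi_mean: float = 4.0  # mean trypsins per co-expressing cell (geometric tail)
    popularity_sigma: float = 0.35  # lognormal sd of per-gene sampling weight
    planted_rho: float = 0.9
    count_mean: float = 2.0  # mean reads for an expressed entry (geometric)
    frac_silent: float = 0.10  # cells expressing no trypsin at all
    # --- presence evolution ---
    n_features: int = 50
    tree_leaves: int = 16
    loss_prob: float = 0.2
    # --- gene models ---
    n_gff_genes: int = 6
    n_intronless: int = 2
    # --- gene trees ---
    gene_tree_leaves: int = 40
    n_tandem_pairs: int = 4
    focal_taxon: str = "Nematostella_vectensis"

    def __post_init__(self) -> None:
        for name in ("split_probability", "solo_weight", "loss_prob", "frac_silent"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.architecture_catalog:
            raise ValueError("architecture catalog must be nonempty")


# per-stream offsets keep the generators independent of each other
_STREAMS = {"hits": 1, "gff": 2, "cells": 3, "presence": 4, "genetree": 5}


def _stream_rng(spec: SimSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAMS[stream]])


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


# ---------------------------------------------------------------------------
# domtblout + planted architectures
# ---------------------------------------------------------------------------

def _domtblout_row(
    family: str,
    protein: str,
    qlen: int,
    full_evalue: float,
    i_evalue: float,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
    dom_i: int,
    dom_n: int,
) -> str:
    tlen = FAMILY_LENGTHS.get(family, DECOY_LENGTH)
    acc = PFAM_ACCESSIONS.get(family, "-")
    return (
        f"{family} {acc} {tlen} {protein} - {qlen} "
        f"{full_evalue:.3g} 150.0 0.1 {dom_i} {dom_n} "
        f"{i_evalue:.3g} {i_evalue:.3g} 120.0 0.1 "
        f"{hmm_from} {hmm_to} {ali_from} {ali_to} "
        f"{max(ali_from - 2, 1)} {ali_to + 2} 0.95 synthetic domain hit\n"
    )


def gen_domain_hits(
    spec: SimSpec, out_path: str | Path
) -> tuple[Path, dict[str, str]]:
    """Write a synthetic hmmscan domtblout; return (path, planted key per protein).

    True proteins realize a catalog-drawn architecture with all E-values
    safely inside the thresholds; with ``split_probability`` a trypsin
    domain is emitted as two complementary partial hits.  Decoy hits
    straddle the independent-E-value threshold: passing decoys are appended
    to the planted key (they legitimately survive), failing ones must be
    filtered.  Decoy *proteins* carry only trypsin hits above the
    full-sequence threshold and never enter the truth table.
    """
    rng = _stream_rng(spec, "hits")
    keys = list(spec.architecture_catalog)
    probs = np.array([spec.architecture_catalog[k] for k in keys], dtype=float)
    probs = probs / probs.sum()

    lines: list[str] = []
    truth: dict[str, str] = {}

    for i in range(spec.n_proteins):
        pid = f"SP{i + 1:04d}"
        key = keys[rng.choice(len(keys), p=probs)]
        families = key.split("|")

        # lay out domains N->C with random linkers
        placements = []
        pos = int(rng.integers(1, 30))
        for fam in families:
            length = FAMILY_LENGTHS[fam]
            placements.append((fam, pos, pos + length - 1))
            pos += length + int(rng.integers(5, 40))

        # decoy associated-domain hits, placed beyond the last real domain
        decoy_placements = []
        n_decoys = int(rng.poisson(spec.decoy_rate))
        for _ in range(n_decoys):
            fam = DECOY_FAMILIES[rng.integers(len(DECOY_FAMILIES))]
            start = pos + int(rng.integers(5, 30))
            end = start + DECOY_LENGTH - 1
            passes = bool(rng.random() < 0.5)
            ie = (
                _log_uniform(rng, 1e-4, 0.045)
                if passes
                else _log_uniform(rng, 0.06, 10.0)
            )
            decoy_placements.append((fam, start, end, ie, passes))
            pos = end

        qlen = pos + int(rng.integers(5, 30))
        planted_families = list(families) + [
            d[0] for d in decoy_placements if d[4]
        ]
        truth[pid] = "|".join(planted_families)

        # full-sequence E-value is a property of the (protein, family) pair:
        # one draw per family, repeated on every row of that family
        full_by_family: dict[str, float] = {}

        def full_e_of(fam: str) -> float:
            if fam not in full_by_family:
                if fam.startswith("Trypsin"):
                    full_by_family[fam] = _log_uniform(rng, 1e-30, 1e-6)
                elif fam in DECOY_FAMILIES:
                    full_by_family[fam] = _log_uniform(rng, 1e-6, 1e-1)
                else:
                    full_by_family[fam] = _log_uniform(rng, 1e-20, 1e-3)
            return full_by_family[fam]

        rows = []
        for fam, start, end in placements:
            is_trypsin = fam.startswith("Trypsin")
            full_e = full_e_of(fam)
            ie = _log_uniform(rng, 1e-25, 1e-6)
            hmm_len = FAMILY_LENGTHS[fam]
            if is_trypsin and rng.random() < spec.split_probability:
                # two complementary partials: disjoint on the protein,
                # tiling distinct halves of the profile
                mid_aa = (start + end) // 2
                mid_hmm = hmm_len // 2
                rows.append(
                    (fam, full_e, ie, 1, mid_hmm, start, mid_aa)
                )
                rows.append(
                    (fam, full_e, _log_uniform(rng, 1e-25, 1e-6),
                     mid_hmm + 5, hmm_len, mid_aa + 3, end)
                )
            else:
                rows.append((fam, full_e, ie, 1, hmm_len, start, end))
        for fam, start, end, ie, _passes in decoy_placements:
            rows.append((fam, full_e_of(fam), ie, 1, DECOY_LENGTH, start, end))

        for dom_i, (fam, full_e, ie, hf, ht, af, at) in enumerate(rows, start=1):
            lines.append(
                _domtblout_row(fam, pid, qlen, full_e, ie, hf, ht, af, at, dom_i, len(rows))
            )

    # decoy proteins: trypsin hits above the full-sequence threshold
    for i in range(spec.n_decoy_proteins):
        pid = f"DP{i + 1:04d}"
        full_e = _log_uniform(rng, 2e-5, 1e-2)
        length = FAMILY_LENGTHS["Trypsin"]
        start = int(rng.integers(1, 20))
        lines.append(
            _domtblout_row(
                "Trypsin", pid, start + length + 20, full_e,
                _log_uniform(rng, 1e-6, 1e-2),
                1, length, start, start + length - 1, 1, 1,
            )
        )

    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("# synthetic hmmscan --domtblout table\n")
        fh.write("# target name        accession   tlen query name ...\n")
        fh.writelines(lines)
    return out_path, truth


def gen_proteome_fasta(
    spec: SimSpec, domtblout_path: str | Path, out_path: str | Path
) -> Path:
    """Placeholder protein sequences matching the qlen column of the hit table."""
    rng = _stream_rng(spec, "hits")  # independent content; length is what matters
    lengths: dict[str, int] = {}
    with open(domtblout_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            lengths[fields[3]] = int(fields[5])
    out_path = Path(out_path)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    with open(out_path, "w") as fh:
        for pid, length in sorted(lengths.items()):
            seq = "".join(rng.choice(alphabet, size=length))
            fh.write(f">{pid}\n{seq}\n")
    return out_path


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

# exon-1 coding length chosen so overhangs of exactly 8 and 11 nt into
# exon 2 are realizable on codon-aligned domain spans: 103*3-301=8, 104*3-301=11
_EXON1_NT = 301
_EXON2_NT = 400
_EXON3_NT = 301
_INTRON_NT = 150


def gen_gff(spec: SimSpec, out_path: str | Path) -> tuple[Path, dict]:
    """Write GFF3 gene models with planted intronless genes and overhangs.

    Multi-exon genes carry three planted domains: one fully inside exon 1,
    one reaching exactly 8 nt into exon 2 (single-exon call under the
    10-nt rule) and one reaching 11 nt (two-exon call).  Every forward-
    strand gene has a reverse-strand mirror with identical structure.
    Returns (path, truth) with per-gene strand, intronless flag,
    transcript id and (start, end, expected_exon_count) per domain.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    truth: dict[str, dict] = {}
    lines = ["##gff-version 3\n"]

    def emit_gene(gid: str, scaffold: str, strand: str, intronless: bool) -> None:
        tid = f"{gid}.m1"
        if intronless:
            n_aa = 150
            g_start, g_end = 1000, 1000 + n_aa * 3 - 1
            segs = [(g_start, g_end)]
            domains = [(10, 80, 1)]
        else:
            lens = [_EXON1_NT, _EXON2_NT, _EXON3_NT]
            if strand == "+":
                starts = []
                cur = 1000
                for ln in lens:
                    starts.append(cur)
                    cur += ln + _INTRON_NT
                segs = [(s, s + ln - 1) for s, ln in zip(starts, lens)]
            else:
                # transcription runs high->low: first coding exon highest
                starts = []
                cur = 5000
                for ln in lens:
                    starts.append(cur - ln + 1)
                    cur -= ln + _INTRON_NT
                segs = sorted(
                    (s, s + ln - 1) for s, ln in zip(starts, lens)
                )
            domains = [
                (5, 95, 1),    # 285 nt, entirely within exon 1
                (1, 103, 1),   # ends 8 nt into exon 2 -> still one exon
                (1, 104, 2),   # ends 11 nt into exon 2 -> two exons
            ]
        g_start = min(s for s, _ in segs)
        g_end = max(e for _, e in segs)
        lines.append(
            f"{scaffold}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gid}\n"
        )
        lines.append(
            f"{scaffold}\tsim\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}\n"
        )
        # phases in transcription order
        ordered = segs if strand == "+" else segs[::-1]
        phase, phased = 0, {}
        for s, e in ordered:
            phased[(s, e)] = phase
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
        for j, (s, e) in enumerate(segs, start=1):
            lines.append(
                f"{scaffold}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t{phased[(s, e)]}\t"
                f"ID={tid}.cds{j};Parent={tid}\n"
            )
        truth[gid] = {
            "transcript": tid,
            "strand": strand,
            "intronless": intronless,
            "domains": domains,
        }

    n_multi = max(spec.n_gff_genes - spec.n_intronless, 0)
    idx = 0
    for i in range(spec.n_intronless):
        idx += 1
        emit_gene(f"ig{idx:03d}", f"scaffold_{idx}", "+", True)
    for i in range(n_multi):
        idx += 1
        emit_gene(f"mg{idx:03d}f", f"scaffold_{idx}f", "+", False)
        emit_gene(f"mg{idx:03d}r", f"scaffold_{idx}r", "-", False)

    with open(out_path, "w") as fh:
        fh.writelines(lines)
    return out_path, truth


# ---------------------------------------------------------------------------
# predictor tables (SignalP / TMHMM short formats)
# ---------------------------------------------------------------------------

def gen_predictor_tables(
    spec: SimSpec, protein_ids: Sequence[str], out_dir: str | Path
) -> tuple[Path, Path, dict[str, tuple[bool, bool]]]:
    """Emit SignalP v4.1 / TMHMM v2.0 short tables with known flags."""
    rng = _stream_rng(spec, "gff")  # shares the gene-model stream
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict[str, tuple[bool, bool]] = {}
    sp_path = out_dir / "signalp_short.txt"
    tm_path = out_dir / "tmhmm_short.txt"
    with open(sp_path, "w") as sp, open(tm_path, "w") as tm:
        sp.write("# SignalP-4.1 euk predictions\n")
        sp.write("# name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used\n")
        for pid in protein_ids:
            has_sp = bool(rng.random() < 0.7)
            has_tm = bool(rng.random() < 0.1)
            truth[pid] = (has_sp, has_tm)
            d_score = rng.uniform(0.46, 0.95) if has_sp else rng.uniform(0.05, 0.44)
            sp.write(
                f"{pid} 0.30 22 0.40 22 0.60 15 0.45 {d_score:.3f} "
                f"{'Y' if has_sp else 'N'} 0.450 SignalP-noTM\n"
            )
            n_hel = int(rng.integers(1, 4)) if has_tm else 0
            tm.write(
                f"{pid}\tlen=300\tExpAA={n_hel * 20.0:.2f}\tFirst60=0.00\t"
                f"PredHel={n_hel}\tTopology=o\n"
            )
    return sp_path, tm_path, truth


# ---------------------------------------------------------------------------
# cell-by-gene count matrix
# ---------------------------------------------------------------------------

def gen_cell_matrix(spec: SimSpec, out_path: str | Path) -> tuple[Path, dict]:
    """Write a cells-by-genes TSV with a planted co-expression structure.

    Co-expressing cells pick 2+ genes (geometric tail) weighted by a
    heavy-tailed gene popularity; single-trypsin cells are then allotted
    per gene with a variance chosen so that corr(ubiquity, co-expression)
    lands at ``planted_rho``.  Silent cells carry no trypsin reads at all.
    The truth is the realized (not target) tally of the emitted matrix.
    """
    rng = _stream_rng(spec, "cells")
    n_genes = spec.n_genes
    genes = [f"T{i + 1:04d}" for i in range(n_genes)]

    n_multi = int(round(spec.n_cells * (1.0 - spec.frac_silent) * (1.0 - spec.solo_weight)))
    weights = rng.lognormal(mean=0.0, sigma=spec.popularity_sigma, size=n_genes)
    weights /= weights.sum()

    p_tail = 1.0 / max(spec.multi_mean - 1.0, 1.0)
    multi_members: list[np.ndarray] = []
    m = np.zeros(n_genes, dtype=int)
    for _ in range(n_multi):
        k = 1 + int(rng.geometric(p_tail))
        k = min(max(k, 2), n_genes)
        chosen = rng.choice(n_genes, size=k, replace=False, p=weights)
        multi_members.append(np.sort(chosen))
        m[chosen] += 1

    # solo cells: per-gene counts independent of the co-expression counts m,
    # with variance chosen so corr(ubiquity, co-expression) = corr(m+s, m)
    # lands at planted_rho; a gamma keeps counts non-negative at moderate CV
    rho = spec.planted_rho
    sigma_m = float(m.std())
    if n_multi == 0 or sigma_m == 0 or not (0 < rho < 1):
        n_solo_target = int(round(spec.n_cells * (1.0 - spec.frac_silent) * spec.solo_weight))
        s = rng.multinomial(n_solo_target, np.full(n_genes, 1.0 / n_genes))
    else:
        n_solo_target = n_multi * spec.solo_weight / (1.0 - spec.solo_weight)
        mean_s = max(n_solo_target / n_genes, 1e-9)
        sigma_s = sigma_m * math.sqrt(1.0 - rho**2) / rho
        shape = (mean_s / sigma_s) ** 2
        scale = sigma_s**2 / mean_s
        s = np.rint(rng.gamma(shape, scale, size=n_genes)).astype(int)

    incidence: list[np.ndarray] = list(multi_members)
    for g in range(n_genes):
        incidence.extend([np.array([g])] * s[g])
    n_silent = int(round((len(incidence)) * spec.frac_silent / (1.0 - spec.frac_silent)))
    incidence.extend([np.array([], dtype=int)] * n_silent)

    order = rng.permutation(len(incidence))
    counts = np.zeros((len(incidence), n_genes), dtype=int)
    for row, idx in enumerate(order):
        members = incidence[idx]
        if len(members):
            counts[row, members] = rng.geometric(1.0 / spec.count_mean, size=len(members))

    cells = [f"C{i + 1:05d}" for i in range(len(incidence))]
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("cell\t" + "\t".join(genes) + "\n")
        for cell, row in zip(cells, counts):
            fh.write(cell + "\t" + "\t".join(map(str, row)) + "\n")

    # realized truth, tallied directly from the emitted matrix
    mask = counts >= 1
    per_cell = mask.sum(axis=1)
    expressing = per_cell >= 1
    ks, cs = np.unique(per_cell[expressing], return_counts=True)
    ubiquity = mask.sum(axis=0)
    co_cells = mask[per_cell >= 2].sum(axis=0)
    if ubiquity.std() > 0 and co_cells.std() > 0:
        realized_rho = float(np.corrcoef(ubiquity, co_cells)[0, 1])
    else:
        realized_rho = float("nan")
    truth = {
        "genes": genes,
        "n_expressing_cells": int(expressing.sum()),
        "histogram": {int(k): int(c) for k, c in zip(ks, cs)},
        "ubiquity": {g: int(u) for g, u in zip(genes, ubiquity)},
        "co_cells": {g: int(c) for g, c in zip(genes, co_cells)},
        "realized_pearson": realized_rho,
    }
    return out_path, truth


# ---------------------------------------------------------------------------
# presence/absence evolution on a random tree
# ---------------------------------------------------------------------------

def _random_newick(rng: np.random.Generator, labels: Sequence[str]) -> str:
    """Uniform random binary join order over the given leaf labels."""
    nodes = [f"{lab}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def gen_presence(
    spec: SimSpec, out_dir: str | Path
) -> tuple[Path, Path, dict[str, dict]]:
    """Evolve presence/absence features by single gain plus lineage losses.

    Each feature gains at a uniformly chosen tree node; every edge strictly
    below the gain then fails (loses the feature, cutting off its whole
    subtree) independently with probability ``loss_prob``.  Features left
    with no presence are discarded.  Returns (tree path, matrix path,
    truth), truth mapping feature -> {gain_leafset, present}.
    """
    import dendropy

    rng = _stream_rng(spec, "presence")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [f"X{i + 1:03d}" for i in range(spec.tree_leaves)]
    newick = _random_newick(rng, labels)
    tree_path = out_dir / "species_tree.nwk"
    tree_path.write_text(newick + "\n")

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    nodes = list(tree.preorder_node_iter())

    truth: dict[str, dict] = {}
    rows: list[tuple[str, dict[str, int]]] = []
    for i in range(spec.n_features):
        feat = f"F{i + 1:04d}"
        gain = nodes[rng.integers(len(nodes))]

        present: list[str] = []

        def descend(node) -> None:
            if node.is_leaf():
                present.append(node.taxon.label)
                return
            for child in node.child_nodes():
                if rng.random() >= spec.loss_prob:
                    descend(child)

        descend(gain)
        if not present:
            import logging

            logging.getLogger(__name__).info("feature %s lost everywhere; discarded", feat)
            continue
        gain_leafset = frozenset(lf.taxon.label for lf in gain.leaf_iter())
        truth[feat] = {"gain_leafset": gain_leafset, "present": sorted(present)}
        rows.append((feat, {t: int(t in present) for t in labels}))

    matrix_path = out_dir / "presence.tsv"
    with open(matrix_path, "w") as fh:
        fh.write("feature\t" + "\t".join(labels) + "\n")
        for feat, row in rows:
            fh.write(feat + "\t" + "\t".join(str(row[t]) for t in labels) + "\n")
    return tree_path, matrix_path, truth


# ---------------------------------------------------------------------------
# gene trees with planted tandem pairs
# ---------------------------------------------------------------------------

def gen_gene_tree(
    spec: SimSpec, out_dir: str | Path
) -> tuple[Path, Path, list[tuple[str, str, str, int]]]:
    """Random gene tree with planted focal-taxon same-scaffold cherries.

    Cherries are built first as units and then joined randomly with the
    remaining leaves, so each planted pair is guaranteed to be sisters.
    Non-planted focal leaves each sit on their own scaffold and other taxa
    carry no coordinates, so exactly the planted pairs qualify.  Returns
    (newick path, metadata path, truth list of (leaf1, leaf2, scaffold, gap)).
    """
    from .gene_tree_analysis import LeafMeta, write_leaf_metadata

    rng = _stream_rng(spec, "genetree")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    other_taxa = ["Hydra_magnipapillata", "Aiptasia_pallida", "Acropora_digitifera",
                  "Alatina_alata", "Calvadosia_cruxmelitensis"]
    meta: dict[str, LeafMeta] = {}
    units: list[str] = []
    truth: list[tuple[str, str, str, int]] = []

    n_pair_leaves = 2 * spec.n_tandem_pairs
    if spec.gene_tree_leaves < n_pair_leaves + 2:
        raise ValueError("gene_tree_leaves too small for the requested tandem pairs")

    for p in range(spec.n_tandem_pairs):
        l1, l2 = f"NVJ_{70000 + 2 * p}", f"NVJ_{70001 + 2 * p}"
        scaffold = f"scaffold_{p + 1}"
        s1 = int(rng.integers(1_000, 50_000))
        e1 = s1 + int(rng.integers(500, 3_000))
        gap = int(rng.integers(200, 5_000))
        s2 = e1 + gap
        e2 = s2 + int(rng.integers(500, 3_000))
        meta[l1] = LeafMeta(taxon=spec.focal_taxon, group="anthozoan",
                            scaffold=scaffold, start=s1, end=e1)
        meta[l2] = LeafMeta(taxon=spec.focal_taxon, group="anthozoan",
                            scaffold=scaffold, start=s2, end=e2)
        units.append(f"({l1},{l2})")
        truth.append((l1, l2, scaffold, gap))

    for i in range(spec.gene_tree_leaves - n_pair_leaves):
        leaf = f"L{i + 1:03d}"
        if rng.random() < 0.4:
            meta[leaf] = LeafMeta(
                taxon=spec.focal_taxon, group="anthozoan",
                scaffold=f"solo_scaffold_{i}", start=1000, end=2000,
            )
        else:
            taxon = other_taxa[int(rng.integers(len(other_taxa)))]
            group = "medusozoan" if taxon in {
                "Hydra_magnipapillata", "Alatina_alata", "Calvadosia_cruxmelitensis"
            } else "anthozoan"
            meta[leaf] = LeafMeta(taxon=taxon, group=group)
        units.append(leaf)

    while len(units) > 1:
        i, j = sorted(rng.choice(len(units), size=2, replace=False))
        b = units.pop(j)
        a = units.pop(i)
        units.append(f"({a},{b})")
    newick = units[0] + ";"

    tree_path = out_dir / "gene_tree.nwk"
    tree_path.write_text(newick + "\n")
    meta_path = out_dir / "gene_tree_meta.tsv"
    write_leaf_metadata(meta, meta_path)
    return tree_path, meta_path, truth
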