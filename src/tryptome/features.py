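"""Per-protein functional annotation of a curated tryptome.

Three independent signals are attached to each trypsin protein:

* catalytic-triad status — His/Asp/Ser at positions 57/102/195 of a
  chymotrypsin-numbered reference, located in a multiple sequence alignment
  and checked letter-for-letter in every aligned protein;
* secretion/membrane flags read from SignalP v4.1 and TMHMM v2.0 short
  output tables (predictions are consumed, never recomputed);
* exon structure — for each placed domain, the number of coding exons it
  spans under the overhang rule (a domain reaching at most ``overhang_nt``
  nucleotides into a neighbouring exon still counts as single-exon), and
  whether the whole gene model is intronless (single CDS segment), the
  signature of retrotransposed copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .hit_processing import Architecture, PlacedDomain

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


class PredictorTableError(ValueError):
    """Raised on an unparseable SignalP/TMHMM line."""


@dataclass(frozen=True)
class TriadSpec:
    """Chymotrypsin-numbered catalytic-triad definition.

    ``positions`` are residue numbers on the (ungapped) reference sequence;
    ``required_residues`` the one-letter amino acids demanded there.
    """

    reference_id: str
    positions: tuple[int, int, int] = (57, 102, 195)
    required_residues: tuple[str, str, str] = ("H", "D", "S")

    def __post_init__(self) -> None:
        if not (self.positions[0] < self.positions[1] < self.positions[2]):
            raise ValueError("triad positions must be strictly increasing")


@dataclass
class FeatureRecord:
    protein_id: str
    has_triad: bool = False
    missing_triad_sites: tuple[int, ...] = ()
    has_signal_peptide: bool = False
    has_tm: bool = False
    intronless: bool = False
    scaffold: str | None = None
    domain_exon_counts: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# catalytic triad
# ---------------------------------------------------------------------------

def _load_alignment(msa: MultipleSeqAlignment | str | Path) -> MultipleSeqAlignment:
    if isinstance(msa, MultipleSeqAlignment):
        return msa
    return AlignIO.read(str(msa), "fasta")


def triad_columns(msa: MultipleSeqAlignment, spec: TriadSpec) -> tuple[int, ...]:
    """Alignment column index (0-based) of each triad position on the reference."""
    ref = next((rec for rec in msa if rec.id == spec.reference_id), None)
    if ref is None:
        raise ValueError(f"reference {spec.reference_id!r} not found in alignment")
    wanted = {p: None for p in spec.positions}
    residue = 0
    for col, ch in enumerate(str(ref.seq)):
        if ch in GAP_CHARS:
            continue
        residue += 1
        if residue in wanted:
            wanted[residue] = col
    missing = [p for p, col in wanted.items() if col is None]
    if missing:
        raise ValueError(
            f"reference {spec.reference_id!r} has only {residue} residues; "
            f"positions {missing} out of range"
        )
    return tuple(wanted[p] for p in spec.positions)


def triad_scan(
    msa: MultipleSeqAlignment | str | Path, spec: TriadSpec
) -> dict[str, tuple[bool, tuple[int, ...]]]:
    """Check every aligned protein for the catalytic triad.

    A protein passes a site iff it carries exactly the required residue
    (case-insensitive) in the alignment column anchored by the reference;
    a gap fails.  Returns protein_id -> (has_triad, missing site numbers).
    """
    aln = _load_alignment(msa)
    cols = triad_columns(aln, spec)
    out: dict[str, tuple[bool, tuple[int, ...]]] = {}
    for rec in aln:
        seq = str(rec.seq).upper()
        missing = tuple(
            pos
            for pos, col, req in zip(spec.positions, cols, spec.required_residues)
            if seq[col] != req.upper()
        )
        out[rec.id] = (not missing, missing)
    return out


# ---------------------------------------------------------------------------
# SignalP / TMHMM tables
# ---------------------------------------------------------------------------

def read_signalp_short(path: str | Path) -> dict[str, bool]:
    """SignalP v4.1 short format: the 10th column is the Y/N D-decision."""
    flags: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 10 or fields[9] not in {"Y", "N"}:
                raise PredictorTableError(f"{path}: line {lineno}: not SignalP short format")
            flags[fields[0]] = fields[9] == "Y"
    return flags


def read_tmhmm_short(path: str | Path) -> dict[str, bool]:
    """TMHMM v2.0 short format: one line per protein with a PredHel=N field."""
    flags: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            pred = next((f for f in fields if f.startswith("PredHel=")), None)
            if pred is None:
                raise PredictorTableError(f"{path}: line {lineno}: missing PredHel field")
            try:
                n_helices = int(pred.split("=", 1)[1])
            except ValueError as exc:
                raise PredictorTableError(f"{path}: line {lineno}: bad PredHel value") from exc
            flags[fields[0]] = n_helices > 0
    return flags


def read_predictor_tables(
    signalp_path: str | Path,
    tmhmm_path: str | Path,
    protein_ids: Iterable[str] | None = None,
) -> dict[str, tuple[bool, bool]]:
    """Combine predictor tables into protein -> (has_signal_peptide, has_tm).

    Proteins listed in ``protein_ids`` but absent from a table default to
    False with a warning.
    """
    sp = read_signalp_short(signalp_path)
    tm = read_tmhmm_short(tmhmm_path)
    universe = set(sp) | set(tm)
    if protein_ids is not None:
        for pid in protein_ids:
            if pid not in sp or pid not in tm:
                log.warning("protein %s missing from a predictor table; flags default to False", pid)
        universe |= set(protein_ids)
    return {pid: (sp.get(pid, False), tm.get(pid, False)) for pid in sorted(universe)}


# ---------------------------------------------------------------------------
# gene models / exon structure
# ---------------------------------------------------------------------------

def load_gene_models(gff_path: str | Path) -> gffutils.FeatureDB:
    """Load a GFF3 file into an in-memory feature database."""
    return gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _cds_segments(db: gffutils.FeatureDB, transcript_id: str) -> tuple[list[tuple[int, int]], str, str]:
    """CDS segments of a transcript in transcription order, plus strand/scaffold."""
    mrna = db[transcript_id]
    segs = sorted(
        (f.start, f.end)
        for f in db.children(transcript_id, featuretype="CDS")
    )
    if not segs:
        raise ValueError(f"transcript {transcript_id} has no CDS features")
    if mrna.strand == "-":
        segs = segs[::-1]
    return segs, mrna.strand, mrna.seqid


def domain_exon_counts_for_protein(
    db: gffutils.FeatureDB,
    transcript_id: str,
    domains: Sequence[PlacedDomain],
    overhang_nt: int = 10,
) -> list[int]:
    """Coding exons spanned by each domain under the overhang rule.

    A domain's amino-acid span is projected into transcript coding
    coordinates; the exon count is the number of CDS segments holding more
    than ``overhang_nt`` nucleotides of the domain's coding sequence (never
    below 1 — the segment with the largest share always counts).
    """
    segs, _strand, _scaffold = _cds_segments(db, transcript_id)
    lengths = [e - s + 1 for s, e in segs]
    total_nt = sum(lengths)

    # coding-coordinate interval of each CDS segment, in transcription order
    coding_ivals = []
    offset = 0
    for length in lengths:
        coding_ivals.append((offset + 1, offset + length))
        offset += length

    counts = []
    for d in domains:
        nt_start = (d.start - 1) * 3 + 1
        nt_end = d.end * 3
        if nt_end > total_nt:
            raise ValueError(
                f"domain {d.family} {d.start}-{d.end} exceeds coding length "
                f"of transcript {transcript_id} ({total_nt // 3} aa)"
            )
        n = 0
        best = 0
        for c_start, c_end in coding_ivals:
            shared = min(nt_end, c_end) - max(nt_start, c_start) + 1
            if shared > best:
                best = shared
            if shared > overhang_nt:
                n += 1
        counts.append(max(n, 1))
    return counts


def domain_exon_mapping(
    gff: gffutils.FeatureDB | str | Path,
    archs: Iterable[Architecture],
    protein_to_transcript: Mapping[str, str] | None = None,
    overhang_nt: int = 10,
) -> tuple[dict[str, list[int]], set[str]]:
    """Exon counts per placed domain for every protein with a gene model.

    Returns (protein_id -> counts aligned with the architecture's domain
    order, set of proteins lacking a gene model).
    """
    db = gff if isinstance(gff, gffutils.FeatureDB) else load_gene_models(gff)
    p2t = protein_to_transcript or {}
    counts: dict[str, list[int]] = {}
    missing: set[str] = set()
    for a in archs:
        tid = p2t.get(a.protein_id, a.protein_id)
        try:
            db[tid]
        except gffutils.FeatureNotFoundError:
            missing.add(a.protein_id)
            log.warning("protein %s has no gene model (transcript %s)", a.protein_id, tid)
            continue
        counts[a.protein_id] = domain_exon_counts_for_protein(
            db, tid, a.domains, overhang_nt=overhang_nt
        )
    return counts, missing


def detect_intronless(
    gff: gffutils.FeatureDB | str | Path,
    protein_ids: Iterable[str],
    protein_to_transcript: Mapping[str, str] | None = None,
) -> set[str]:
    """Proteins whose transcript consists of exactly one CDS segment."""
    db = gff if isinstance(gff, gffutils.FeatureDB) else load_gene_models(gff)
    p2t = protein_to_transcript or {}
    out = set()
    for pid in protein_ids:
        tid = p2t.get(pid, pid)
        try:
            segs, _, _ = _cds_segments(db, tid)
        except (gffutils.FeatureNotFoundError, ValueError):
            continue
        if len(segs) == 1:
            out.add(pid)
    return out


def scaffold_of(
    gff: gffutils.FeatureDB | str | Path,
    protein_id: str,
    protein_to_transcript: Mapping[str, str] | None = None,
) -> str | None:
    db = gff if isinstance(gff, gffutils.FeatureDB) else load_gene_models(gff)
    tid = (protein_to_transcript or {}).get(protein_id, protein_id)
    try:
        return db[tid].seqid
    except gffutils.FeatureNotFoundError:
        return None


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_feature_records(
    archs: Sequence[Architecture],
    triad: Mapping[str, tuple[bool, tuple[int, ...]]] | None = None,
    predictor_flags: Mapping[str, tuple[bool, bool]] | None = None,
    gff: gffutils.FeatureDB | str | Path | None = None,
    protein_to_transcript: Mapping[str, str] | None = None,
    overhang_nt: int = 10,
) -> list[FeatureRecord]:
    """Join triad, predictor and exon-structure annotations per protein."""
    triad = triad or {}
    predictor_flags = predictor_flags or {}
    db = None
    exon_counts: dict[str, list[int]] = {}
    intronless: set[str] = set()
    if gff is not None:
        db = gff if isinstance(gff, gffutils.FeatureDB) else load_gene_models(gff)
        exon_counts, _missing = domain_exon_mapping(
            db, archs, protein_to_transcript, overhang_nt=overhang_nt
        )
        intronless = detect_intronless(db, [a.protein_id for a in archs], protein_to_transcript)

    records = []
    for a in archs:
        has_triad, missing_sites = triad.get(a.protein_id, (False, ()))
        sp, tm = predictor_flags.get(a.protein_id, (False, False))
        records.append(
            FeatureRecord(
                protein_id=a.protein_id,
                has_triad=has_triad,
                missing_triad_sites=tuple(missing_sites),
                has_signal_peptide=sp,
                has_tm=tm,
                intronless=a.protein_id in intronless,
                scaffold=scaffold_of(db, a.protein_id, protein_to_transcript) if db else None,
                domain_exon_counts=tuple(exon_counts.get(a.protein_id, ())),
            )
        )
    return records


def write_feature_report(records: Sequence[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\thas_triad\tmissing_triad_sites\thas_signal_peptide\t"
            "has_tm\tintronless\tscaffold\tdomain_exon_counts\n"
        )
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.has_triad}\t"
                f"{','.join(map(str, r.missing_triad_sites))}\t{r.has_signal_peptide}\t"
                f"{r.has_tm}\t{r.intronless}\t{r.scaffold or ''}\t"
                f"{','.join(map(str, r.domain_exon_counts))}\n"
            )
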