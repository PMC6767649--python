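"""Curation of protein domain architectures from profile-HMM hit tables.

Raw per-domain hits (HMMER3 ``--domtblout`` tables from a Pfam-A scan) are
turned into one canonical :class:`Architecture` per trypsin-domain protein:

1. proteins with a significant trypsin-family hit are selected
   (full-sequence E-value cutoff, default 1e-05), minus an externally
   curated exclusion list;
2. associated domains are filtered on the independent (domain-specific)
   E-value (default 0.05);
3. partial hits of the same family that tile complementary parts of the
   profile are merged into one contiguous placed domain;
4. overlapping placements are resolved: pairs overlapping by at most a
   fraction of the shorter domain (default 20%) are both kept, otherwise
   the hit with the lower E-value wins.

All coordinates are 1-based inclusive amino-acid positions, as printed by
HMMER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

DEFAULT_TRYPSIN_FAMILIES = frozenset({"Trypsin", "Trypsin_2"})


class DomtbloutParseError(ValueError):
    """Raised when a domtblout data row cannot be interpreted."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain match.

    Coordinates come from the alignment ("ali") columns of the table and are
    1-based inclusive; ``hmm_start``/``hmm_end`` are positions on the profile.
    ``i_evalue`` is the independent (domain-specific) E-value, ``full_evalue``
    the full-sequence E-value of the protein/profile pair.
    """

    protein_id: str
    family: str
    accession: str
    ali_start: int
    ali_end: int
    hmm_start: int
    hmm_end: int
    i_evalue: float
    full_evalue: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(f"ali_start > ali_end for {self.protein_id}/{self.family}")
        if self.hmm_start > self.hmm_end:
            raise ValueError(f"hmm_start > hmm_end for {self.protein_id}/{self.family}")
        if self.i_evalue <= 0 or self.full_evalue <= 0:
            raise ValueError("E-values must be positive")


@dataclass(frozen=True)
class PlacedDomain:
    """A domain placed on a protein after merging of partial hits."""

    family: str
    start: int
    end: int
    i_evalue: float
    merged_from: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if self.merged_from < 1:
            raise ValueError("merged_from must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Architecture:
    """Ordered (N-to-C) placed domains of one protein."""

    protein_id: str
    domains: tuple[PlacedDomain, ...]

    @property
    def key(self) -> str:
        """Canonical architecture string, family names in N-to-C order."""
        return "|".join(d.family for d in self.domains)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and curation inputs for architecture building."""

    protein_evalue_max: float = 1e-05
    domain_ievalue_max: float = 0.05
    overlap_frac_max: float = 0.20
    trypsin_families: frozenset[str] = DEFAULT_TRYPSIN_FAMILIES
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.protein_evalue_max <= 0 or self.domain_ievalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")
        if not (0 <= self.overlap_frac_max < 1):
            raise ValueError("overlap_frac_max must lie in [0, 1)")
        object.__setattr__(self, "trypsin_families", frozenset(self.trypsin_families))
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

# hmmscan --domtblout column indices (whitespace-separated; the free-text
# description field is everything after column 22 and is ignored)
_COL_TARGET = 0
_COL_TARGET_ACC = 1
_COL_QUERY = 3
_COL_FULL_EVALUE = 6
_COL_I_EVALUE = 12
_COL_HMM_FROM = 15
_COL_HMM_TO = 16
_COL_ALI_FROM = 17
_COL_ALI_TO = 18
_MIN_FIELDS = 22


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Read an hmmscan per-domain table into a list of :class:`DomainHit`.

    The hmmscan orientation is assumed: the *target* is the Pfam family and
    the *query* is the protein.  Comment lines (``#``) are skipped; row order
    is preserved.  A malformed data row raises :class:`DomtbloutParseError`
    naming the line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _MIN_FIELDS:
                raise DomtbloutParseError(
                    f"{path}: line {lineno}: expected >= {_MIN_FIELDS} fields, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[_COL_QUERY],
                    family=fields[_COL_TARGET],
                    accession=fields[_COL_TARGET_ACC],
                    ali_start=int(fields[_COL_ALI_FROM]),
                    ali_end=int(fields[_COL_ALI_TO]),
                    hmm_start=int(fields[_COL_HMM_FROM]),
                    hmm_end=int(fields[_COL_HMM_TO]),
                    i_evalue=float(fields[_COL_I_EVALUE]),
                    full_evalue=float(fields[_COL_FULL_EVALUE]),
                )
            except ValueError as exc:
                raise DomtbloutParseError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_trypsin_proteins(
    hits: Iterable[DomainHit], cfg: PipelineConfig | None = None
) -> set[str]:
    """Proteins with a significant trypsin-family hit, minus curated exclusions.

    A protein qualifies when at least one hit to a family in
    ``cfg.trypsin_families`` has full-sequence E-value at or below
    ``cfg.protein_evalue_max``.
    """
    cfg = cfg or PipelineConfig()
    selected = {
        h.protein_id
        for h in hits
        if h.family in cfg.trypsin_families and h.full_evalue <= cfg.protein_evalue_max
    }
    return selected - cfg.exclusion_list


# ---------------------------------------------------------------------------
# merging of partial hits
# ---------------------------------------------------------------------------

def _complementary(a: DomainHit, b: DomainHit) -> bool:
    """True when two same-family hits look like parts of one split domain.

    Requires disjoint amino-acid spans and profile intervals that jointly
    cover more of the profile than either part alone (i.e. neither profile
    interval is contained in the other).
    """
    if a.family != b.family:
        return False
    if not (a.ali_end < b.ali_start or b.ali_end < a.ali_start):
        return False
    joint = _interval_union_len([(a.hmm_start, a.hmm_end), (b.hmm_start, b.hmm_end)])
    each = max(a.hmm_end - a.hmm_start + 1, b.hmm_end - b.hmm_start + 1)
    return joint > each


def _extends_chain(chain: Sequence[DomainHit], h: DomainHit) -> bool:
    """Whether ``h`` continues a chain of partials of one split domain.

    Beyond pairwise complementarity with the chain's last part, the hit must
    enlarge the chain's *cumulative* profile coverage — otherwise the first
    partial of a following same-family domain (which restarts at the profile
    start) would be absorbed into the previous domain's chain.
    """
    if not _complementary(chain[-1], h):
        return False
    chain_ivals = [(c.hmm_start, c.hmm_end) for c in chain]
    chain_cov = _interval_union_len(chain_ivals)
    joint_cov = _interval_union_len(chain_ivals + [(h.hmm_start, h.hmm_end)])
    return joint_cov > chain_cov


def _interval_union_len(ivals: Sequence[tuple[int, int]]) -> int:
    total, prev_end = 0, None
    for s, e in sorted(ivals):
        if prev_end is None or s > prev_end:
            total += e - s + 1
            prev_end = e
        elif e > prev_end:
            total += e - prev_end
            prev_end = e
    return total


def merge_partial_domains(
    hits: Iterable[DomainHit], cfg: PipelineConfig | None = None
) -> dict[str, list[PlacedDomain]]:
    """Merge complementary partial hits into contiguous placed domains.

    Within each protein and family, hits are chained in amino-acid order;
    consecutive hits that are pairwise complementary (disjoint on the protein
    and tiling distinct parts of the profile) join one chain.  Each chain
    becomes a single :class:`PlacedDomain` spanning min(start)..max(end) with
    the minimum independent E-value of its parts.

    Returns a mapping protein_id -> placed domains sorted by start.
    """
    del cfg  # merging has no tunable threshold; signature kept uniform
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)

    out: dict[str, list[PlacedDomain]] = {}
    for pid, phits in by_protein.items():
        placed: list[PlacedDomain] = []
        by_family: dict[str, list[DomainHit]] = {}
        for h in phits:
            by_family.setdefault(h.family, []).append(h)
        for fam, fhits in by_family.items():
            ordered = sorted(fhits, key=lambda h: (h.ali_start, h.ali_end, h.i_evalue))
            chains: list[list[DomainHit]] = []
            for h in ordered:
                if chains and _extends_chain(chains[-1], h):
                    chains[-1].append(h)
                else:
                    chains.append([h])
            for chain in chains:
                placed.append(
                    PlacedDomain(
                        family=fam,
                        start=min(h.ali_start for h in chain),
                        end=max(h.ali_end for h in chain),
                        i_evalue=min(h.i_evalue for h in chain),
                        merged_from=len(chain),
                    )
                )
        out[pid] = sorted(placed, key=lambda d: (d.start, d.end, d.family))
    return out


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def overlap_fraction(a: PlacedDomain, b: PlacedDomain) -> float:
    """Shared residues divided by the length of the shorter domain."""
    shared = min(a.end, b.end) - max(a.start, b.start) + 1
    if shared <= 0:
        return 0.0
    return shared / min(a.length, b.length)


def resolve_overlaps(
    domains: Sequence[PlacedDomain], cfg: PipelineConfig | None = None
) -> list[PlacedDomain]:
    """Greedy elimination of excessive overlaps among one protein's domains.

    Domains are considered in ascending independent E-value (ties: smaller
    start, then family name); each is kept unless it overlaps an
    already-kept domain by more than ``cfg.overlap_frac_max`` of the shorter
    of the two.  The survivors are returned sorted by start.
    """
    cfg = cfg or PipelineConfig()
    accepted: list[PlacedDomain] = []
    for d in sorted(domains, key=lambda d: (d.i_evalue, d.start, d.family, d.end)):
        if all(overlap_fraction(d, a) <= cfg.overlap_frac_max for a in accepted):
            accepted.append(d)
    return sorted(accepted, key=lambda d: (d.start, d.end, d.family))


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def build_architectures(
    hits: Iterable[DomainHit], cfg: PipelineConfig | None = None
) -> list[Architecture]:
    """Select trypsin proteins and assemble their curated architectures.

    Composition of select -> i-Evalue filter -> merge -> overlap resolution.
    One :class:`Architecture` per selected protein, ordered by protein id.
    A selected protein whose hits all fail the domain filter yields an empty
    architecture and a logged warning.
    """
    cfg = cfg or PipelineConfig()
    hits = list(hits)
    selected = select_trypsin_proteins(hits, cfg)

    kept = [
        h
        for h in hits
        if h.protein_id in selected and h.i_evalue <= cfg.domain_ievalue_max
    ]
    placed = merge_partial_domains(kept, cfg)

    archs: list[Architecture] = []
    for pid in sorted(selected):
        domains = resolve_overlaps(placed.get(pid, []), cfg)
        if not domains:
            log.warning("protein %s selected but no domain survived filtering", pid)
        archs.append(Architecture(protein_id=pid, domains=tuple(domains)))
    return archs


def write_architecture_report(archs: Sequence[Architecture], path: str | Path) -> None:
    """Write a TSV report: one header-tagged row per protein plus per-domain rows."""
    with open(path, "w") as fh:
        fh.write("protein_id\tkey\tfamily\tstart\tend\ti_evalue\tmerged_from\n")
        for a in archs:
            if not a.domains:
                fh.write(f"{a.protein_id}\t\t\t\t\t\t\n")
            for d in a.domains:
                fh.write(
                    f"{a.protein_id}\t{a.key}\t{d.family}\t{d.start}\t{d.end}"
                    f"\t{d.i_evalue:.3g}\t{d.merged_from}\n"
                )


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """One protein identifier per line; blank lines and '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return frozenset(ids)


def with_exclusions(cfg: PipelineConfig, ids: Iterable[str]) -> PipelineConfig:
    return replace(cfg, exclusion_list=frozenset(ids))
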