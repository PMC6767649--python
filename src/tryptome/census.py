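"""Tryptome census: classification, associated-domain enrichment, sharing.

Quantifies how a set of curated trypsin-protein architectures (the
"tryptome") is built: how many proteins carry only a trypsin domain versus
extra conserved domains, how abundant each trypsin-associated family is in
the tryptome relative to the rest of the predicted proteome, and which
architectures recur across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .hit_processing import DEFAULT_TRYPSIN_FAMILIES, Architecture

HIGH_ABUNDANCE_FRAC = 0.10
STRONG_ASSOCIATION_FRAC = 0.15


@dataclass(frozen=True)
class DomainAbundanceRow:
    """Tryptome-vs-background abundance of one associated domain family.

    ``frac_tryptome`` is the share of all proteome instances of the family
    that sit inside tryptome proteins.  ``high_abundance_flag`` marks
    families with at least 10% of instances in the tryptome;
    ``strong_association_flag`` marks at least 15%.
    """

    family: str
    n_tryptome: int
    n_background: int
    n_proteins_total: int
    frac_tryptome: float
    high_abundance_flag: bool
    strong_association_flag: bool
    p_enrichment: float | None = None


def classify_tryptome(
    archs: Iterable[Architecture],
    trypsin_families: frozenset[str] = DEFAULT_TRYPSIN_FAMILIES,
) -> tuple[int, int]:
    """Partition architectures into trypsin-only and multi-domain counts."""
    n_only = n_multi = 0
    for a in archs:
        if any(d.family not in trypsin_families for d in a.domains):
            n_multi += 1
        else:
            n_only += 1
    return n_only, n_multi


def domain_abundance(
    tryptome_archs: Iterable[Architecture],
    proteome_domain_table: Mapping[str, tuple[int, int]],
    trypsin_families: frozenset[str] = DEFAULT_TRYPSIN_FAMILIES,
    enrichment_pvalues: bool = False,
) -> tuple[list[DomainAbundanceRow], int]:
    """Per-family abundance of trypsin-associated domains.

    ``proteome_domain_table`` maps family -> (total instance count over the
    whole predicted proteome, number of proteins containing the family).
    Returns the rows (one per non-trypsin family appearing in the tryptome)
    and the count of distinct associated families.

    When ``enrichment_pvalues`` is set, a hypergeometric upper-tail p-value
    is attached (instances drawn into the tryptome vs the proteome pool);
    the thresholds themselves remain purely descriptive.
    """
    tryptome_counts: dict[str, int] = {}
    for a in tryptome_archs:
        for d in a.domains:
            if d.family not in trypsin_families:
                tryptome_counts[d.family] = tryptome_counts.get(d.family, 0) + 1

    total_instances = sum(v[0] for v in proteome_domain_table.values())
    total_in_tryptome = sum(tryptome_counts.values())

    rows: list[DomainAbundanceRow] = []
    for fam in sorted(tryptome_counts):
        if fam not in proteome_domain_table:
            raise ValueError(
                f"family {fam!r} present in tryptome but absent from the proteome table"
            )
        n_total, n_proteins = proteome_domain_table[fam]
        n_tryp = tryptome_counts[fam]
        if n_total < n_tryp:
            raise ValueError(
                f"family {fam!r}: proteome total {n_total} < tryptome count {n_tryp}"
            )
        n_back = n_total - n_tryp
        frac = n_tryp / n_total
        pval = None
        if enrichment_pvalues:
            pval = float(hypergeom.sf(n_tryp - 1, total_instances, n_total, total_in_tryptome))
        rows.append(
            DomainAbundanceRow(
                family=fam,
                n_tryptome=n_tryp,
                n_background=n_back,
                n_proteins_total=n_proteins,
                frac_tryptome=frac,
                high_abundance_flag=frac >= HIGH_ABUNDANCE_FRAC,
                strong_association_flag=frac >= STRONG_ASSOCIATION_FRAC,
                p_enrichment=pval,
            )
        )
    return rows, len(rows)


def architecture_sharing(
    per_taxon_archs: Mapping[str, Sequence[Architecture]],
    match_as_set: bool = False,
) -> pd.DataFrame:
    """Architecture-by-taxon sharing matrix.

    Rows are architecture keys, columns are taxa, cells count proteins with
    that exact ordered key in that taxon.  ``match_as_set`` collapses keys to
    the sorted set of families (sensitivity mode: re-arrangements match).
    """
    if not per_taxon_archs:
        raise ValueError("at least one taxon is required")

    def ident(a: Architecture) -> str:
        if match_as_set:
            return "|".join(sorted(set(d.family for d in a.domains)))
        return a.key

    taxa = list(per_taxon_archs)
    keys = sorted({ident(a) for archs in per_taxon_archs.values() for a in archs})
    mat = pd.DataFrame(0, index=keys, columns=taxa, dtype=int)
    for taxon, archs in per_taxon_archs.items():
        for a in archs:
            mat.loc[ident(a), taxon] += 1
    return mat


def unique_architectures(sharing: pd.DataFrame, focal_taxon: str) -> list[str]:
    """Architecture keys found in the focal taxon and nowhere else."""
    if focal_taxon not in sharing.columns:
        raise KeyError(focal_taxon)
    others = sharing.drop(columns=focal_taxon)
    mask = (sharing[focal_taxon] > 0) & (others.sum(axis=1) == 0)
    return list(sharing.index[mask])


def write_abundance_report(rows: Sequence[DomainAbundanceRow], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.to_csv(path, sep="\t", index=False)


def read_proteome_domain_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """TSV with columns family, n_instances, n_proteins."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.family): (int(r.n_instances), int(r.n_proteins))
        for r in df.itertuples(index=False)
    }
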