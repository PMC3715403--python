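"""Family-based variant screens: de novo, recessive, dominant, compound het.

All four tools walk the loaded database with the pedigree from the samples
table and apply fixed genotype rules per family:

* de novo          — child HET, both parents HOM_REF, all three called
                     (optionally all three depths >= a minimum);
* autosomal recessive — affected child HOM_ALT, both (unaffected) parents HET;
* autosomal dominant  — every affected member HET, every unaffected member
                     HOM_REF, and any affected member with genotyped parents
                     must have at least one affected carrier parent;
* compound heterozygote — within one gene, pairs of sites where a sample is
                     HET at both; parental genotypes, when available, must
                     place the two alternate alleles on opposite parental
                     origins; phased genotypes must sit on opposite
                     haplotypes; with neither source of phase information
                     the pair is reported as putative/unphased.

Variants with any uncalled genotype in the family under test are skipped,
never guessed. X and Y records are excluded from the autosomal screens.
Every rule is expressible as a query-DSL genotype filter, and each reported
hit re-derives under that filter — the tools are conveniences, not a second
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .gtstore import HET, HOM_ALT, HOM_REF, UNKNOWN
from .session import FrameworkSession, open_session

__all__ = [
    "Trio",
    "InheritanceHit",
    "find_de_novo",
    "find_autosomal_recessive",
    "find_autosomal_dominant",
    "find_comp_hets",
    "NoTrioError",
    "NoGeneAnnotationError",
]

SEX_CHROMS = {"x", "y", "chrx", "chry"}
_SEVERITY_RANK = {"HIGH": 3, "MED": 2, "LOW": 1}


class NoTrioError(RuntimeError):
    """The samples table contains no complete mother-father-child trio."""


class NoGeneAnnotationError(RuntimeError):
    """No variant carries a gene assignment, so gene grouping is impossible."""


@dataclass(frozen=True)
class Trio:
    family_id: str
    child: str
    father: str
    mother: str
    child_affected: bool


@dataclass
class InheritanceHit:
    pattern: str  # de_novo | recessive | dominant | comp_het
    family_id: str
    variant_id: Union[int, tuple[int, int]]
    sample: Optional[str] = None
    gene: Optional[str] = None
    genotypes: dict = field(default_factory=dict)
    note: Optional[str] = None


def _as_session(db) -> tuple[FrameworkSession, bool]:
    if isinstance(db, FrameworkSession):
        return db, False
    return open_session(db), True


def _trios(session: FrameworkSession) -> list[Trio]:
    in_cohort = set(session.samples)
    trios = []
    for row in session.sample_rows():
        dad, mom = row["paternal_id"], row["maternal_id"]
        if dad in in_cohort and mom in in_cohort:
            trios.append(
                Trio(
                    family_id=row["family_id"] or "",
                    child=row["name"],
                    father=dad,
                    mother=mom,
                    child_affected=row["phenotype"] == "affected",
                )
            )
    return trios


def _is_autosomal(chrom: str) -> bool:
    return chrom.lower() not in SEX_CHROMS


def find_de_novo(db, min_depth: int = 0) -> list[InheritanceHit]:
    """Variants present in a child but in neither parent.

    Both parents HOM_REF, child HET, all three genotypes called. When
    ``min_depth`` > 0 all three sequencing depths must reach it (a missing
    depth never qualifies). One hit per (variant, trio).
    """
    session, own = _as_session(db)
    try:
        trios = _trios(session)
        if not trios:
            raise NoTrioError("no complete trios in the samples table")
        idx = session.sample_index
        hits = []
        for row in session.variants():
            if not _is_autosomal(row.chrom):
                continue
            types = row.gt_types
            depths = row.gt_depths
            for trio in trios:
                ic, idd, im = idx[trio.child], idx[trio.father], idx[trio.mother]
                if (
                    types[ic] == HET
                    and types[idd] == HOM_REF
                    and types[im] == HOM_REF
                    and (
                        min_depth <= 0
                        or min(depths[ic], depths[idd], depths[im]) >= min_depth
                    )
                ):
                    gts = row.gts
                    hits.append(
                        InheritanceHit(
                            pattern="de_novo",
                            family_id=trio.family_id,
                            variant_id=row.variant_id,
                            sample=trio.child,
                            gene=row.gene,
                            genotypes={
                                trio.child: gts[ic],
                                trio.father: gts[idd],
                                trio.mother: gts[im],
                            },
                        )
                    )
        return hits
    finally:
        if own:
            session.close()


def find_autosomal_recessive(db) -> list[InheritanceHit]:
    """Affected child homozygous for an allele each unaffected parent carries
    once: child HOM_ALT, both parents HET."""
    session, own = _as_session(db)
    try:
        all_trios = _trios(session)
        if not all_trios:
            raise NoTrioError("no complete trios in the samples table")
        pheno = {r["name"]: r["phenotype"] for r in session.sample_rows()}
        trios = [
            t
            for t in all_trios
            if t.child_affected
            and pheno.get(t.father) == "unaffected"
            and pheno.get(t.mother) == "unaffected"
        ]
        idx = session.sample_index
        hits = []
        for row in session.variants():
            if not _is_autosomal(row.chrom):
                continue
            types = row.gt_types
            for trio in trios:
                ic, idd, im = idx[trio.child], idx[trio.father], idx[trio.mother]
                if types[ic] == HOM_ALT and types[idd] == HET and types[im] == HET:
                    gts = row.gts
                    hits.append(
                        InheritanceHit(
                            pattern="recessive",
                            family_id=trio.family_id,
                            variant_id=row.variant_id,
                            sample=trio.child,
                            gene=row.gene,
                            genotypes={
                                trio.child: gts[ic],
                                trio.father: gts[idd],
                                trio.mother: gts[im],
                            },
                        )
                    )
        return hits
    finally:
        if own:
            session.close()


def find_autosomal_dominant(
    db, allow_unaffected_carriers: bool = False
) -> list[InheritanceHit]:
    """One transmitted allele tracking the phenotype through a family.

    Every affected member must be HET and every unaffected member HOM_REF
    (full penetrance; ``allow_unaffected_carriers`` drops the second
    requirement). Affected members with genotyped parents must have at
    least one affected parent carrying the allele. One hit per
    (variant, family).
    """
    session, own = _as_session(db)
    try:
        rows = session.sample_rows()
        idx = session.sample_index
        families: dict[str, list] = {}
        for r in rows:
            families.setdefault(r["family_id"] or "", []).append(r)
        screened = {
            fam: members
            for fam, members in families.items()
            if any(m["phenotype"] == "affected" for m in members)
            and any(m["phenotype"] == "unaffected" for m in members)
        }
        if not screened:
            raise NoTrioError(
                "no family with both affected and unaffected genotyped members"
            )
        hits = []
        for row in session.variants():
            if not _is_autosomal(row.chrom):
                continue
            types = row.gt_types
            for fam, members in screened.items():
                affected = [m for m in members if m["phenotype"] == "affected"]
                unaffected = [m for m in members if m["phenotype"] == "unaffected"]
                member_types = {m["name"]: types[idx[m["name"]]] for m in members}
                if any(t == UNKNOWN for t in member_types.values()):
                    continue
                if not all(member_types[m["name"]] == HET for m in affected):
                    continue
                if not allow_unaffected_carriers and not all(
                    member_types[m["name"]] == HOM_REF for m in unaffected
                ):
                    continue
                pheno = {m["name"]: m["phenotype"] for m in members}
                transmitted = True
                for m in affected:
                    parents = [
                        p
                        for p in (m["paternal_id"], m["maternal_id"])
                        if p in member_types
                    ]
                    if not parents:
                        continue  # founder: no transmission constraint
                    if not any(
                        pheno.get(p) == "affected"
                        and member_types[p] in (HET, HOM_ALT)
                        for p in parents
                    ):
                        transmitted = False
                        break
                if not transmitted:
                    continue
                gts = row.gts
                hits.append(
                    InheritanceHit(
                        pattern="dominant",
                        family_id=fam,
                        variant_id=row.variant_id,
                        gene=row.gene,
                        genotypes={
                            m["name"]: gts[idx[m["name"]]] for m in members
                        },
                    )
                )
        return hits
    finally:
        if own:
            session.close()


def _phased_alt_haplotype(gt: str, ref: str, alt: str) -> Optional[int]:
    """Haplotype index (0/1) carrying the alternate allele, if phased HET."""
    if "|" not in gt:
        return None
    parts = gt.split("|")
    if len(parts) != 2 or sorted(parts) != sorted([ref, alt]):
        return None
    return parts.index(alt)


def find_comp_hets(
    db,
    min_severity: str = "MED",
    only_affected: bool = True,
) -> list[InheritanceHit]:
    """Putative compound heterozygotes: two HET sites in one gene in trans.

    Candidate sites default to impact severity MED or higher. For samples
    with genotyped parents, each site must show exactly one carrier parent
    (the other HOM_REF) and the two sites must have opposite origins;
    ambiguous parental configurations are dropped. Phased child genotypes
    must place the two alternate alleles on opposite haplotypes. With
    neither parents nor phase, the pair is reported with
    ``note='putative_unphased'``.
    """
    session, own = _as_session(db)
    try:
        rank = _SEVERITY_RANK.get(min_severity)
        if rank is None:
            raise ValueError(f"unknown severity {min_severity!r}")
        if session.scalar(
            "SELECT COUNT(*) FROM variants WHERE gene IS NOT NULL"
        ) == 0:
            raise NoGeneAnnotationError(
                "no gene assignments in the variants table; load a VCF with "
                "snpEff/VEP impact annotations"
            )
        rows = [
            r
            for r in session.variants("gene IS NOT NULL AND impact_severity IS NOT NULL")
            if _SEVERITY_RANK.get(r.impact_severity, 0) >= rank
        ]
        sample_rows = session.sample_rows()
        pheno = {r["name"]: r["phenotype"] for r in sample_rows}
        parents = {
            r["name"]: (r["paternal_id"], r["maternal_id"]) for r in sample_rows
        }
        idx = session.sample_index
        samples = [
            s
            for s in session.samples
            if not only_affected or pheno.get(s) == "affected"
        ]

        hits = []
        for sample in samples:
            si = idx[sample]
            dad, mom = parents.get(sample, (None, None))
            have_parents = dad in idx and mom in idx
            by_gene: dict[str, list] = {}
            for row in rows:
                if row.gt_types[si] == HET:
                    by_gene.setdefault(row.gene, []).append(row)
            for gene, sites in by_gene.items():
                sites.sort(key=lambda r: r.variant_id)
                for a_i in range(len(sites)):
                    for b_i in range(a_i + 1, len(sites)):
                        a, b = sites[a_i], sites[b_i]
                        note = None
                        if have_parents:
                            origin_a = _single_carrier_parent(a, idx[dad], idx[mom])
                            origin_b = _single_carrier_parent(b, idx[dad], idx[mom])
                            if origin_a is None or origin_b is None:
                                continue
                            if origin_a == origin_b:
                                continue  # cis: both from one parent
                        else:
                            hap_a = _phased_alt_haplotype(a.gts[si], a.ref, a.alt)
                            hap_b = _phased_alt_haplotype(b.gts[si], b.ref, b.alt)
                            if hap_a is not None and hap_b is not None:
                                if hap_a == hap_b:
                                    continue
                            else:
                                note = "putative_unphased"
                        hits.append(
                            InheritanceHit(
                                pattern="comp_het",
                                family_id=_family_of(sample_rows, sample),
                                variant_id=(a.variant_id, b.variant_id),
                                sample=sample,
                                gene=gene,
                                genotypes={
                                    a.variant_id: a.gts[si],
                                    b.variant_id: b.gts[si],
                                },
                                note=note,
                            )
                        )
        return hits
    finally:
        if own:
            session.close()


def _single_carrier_parent(row, dad_idx: int, mom_idx: int) -> Optional[str]:
    """'dad' or 'mom' when exactly one parent is HET and the other HOM_REF."""
    t_dad, t_mom = row.gt_types[dad_idx], row.gt_types[mom_idx]
    if t_dad == HET and t_mom == HOM_REF:
        return "dad"
    if t_mom == HET and t_dad == HOM_REF:
        return "mom"
    return None


def _family_of(sample_rows, sample: str) -> str:
    for r in sample_rows:
        if r["name"] == sample:
            return r["family_id"] or ""
    return ""
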