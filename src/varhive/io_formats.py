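"""Readers for VCF and PED inputs, plus consequence-annotation standardization.

VCF records are converted to 0-based half-open coordinates on the way in
(``start = POS - 1``, ``end = start + len(REF)``) so that interval overlap
against BED-style tracks needs no further convention juggling. Multi-allelic
sites are split into one record per ALT allele; sample genotypes are recoded
relative to that allele, and genotypes carrying any *other* ALT allele are
treated as uncalled for the split record.

Transcript-consequence predictions are not computed here — they are parsed
from the ``ANN``/``EFF`` (snpEff) or ``CSQ`` (VEP) INFO fields an upstream
annotator wrote, and standardized to one Sequence Ontology vocabulary with a
fixed HIGH/MED/LOW severity map (see :mod:`varhive._vocab`).
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

from cyvcf2 import VCF

from . import _vocab
from .gtstore import GenotypeRow, HET, HOM_ALT, HOM_REF, UNKNOWN

__all__ = [
    "VariantSite",
    "PedigreeEntry",
    "TranscriptImpact",
    "VcfReader",
    "read_vcf",
    "read_ped",
    "parse_impacts",
    "pick_primary_impact",
    "VcfFormatError",
    "VcfParseError",
    "PedFormatError",
    "ValidationError",
]


class VcfFormatError(ValueError):
    """The file is not a structurally valid VCF (e.g. missing header)."""


class VcfParseError(ValueError):
    """A data line could not be parsed; the message names the record."""


class PedFormatError(ValueError):
    """A PED row violates the 6-column PLINK layout."""


class ValidationError(ValueError):
    """Semantically invalid content (duplicate samples, bad allele index...)."""


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")

SEX_CODES = {"1": "male", "2": "female"}
PHENO_CODES = {"1": "unaffected", "2": "affected"}


@dataclass
class VariantSite:
    """One (post-split) variant row in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    variant_id: int
    quality: Optional[float] = None
    filter: Optional[str] = None
    type: str = "snp"
    sub_type: str = "ts"
    info: dict = field(default_factory=dict)

    @property
    def pos(self) -> int:
        """1-based POS, as printed in the source VCF."""
        return self.start + 1


@dataclass
class PedigreeEntry:
    family_id: str
    sample_id: str
    paternal_id: Optional[str]
    maternal_id: Optional[str]
    sex: str  # male / female / unknown
    phenotype: str  # affected / unaffected / unknown

    @property
    def is_founder(self) -> bool:
        return self.paternal_id is None and self.maternal_id is None


@dataclass
class TranscriptImpact:
    variant_id: int
    gene: str
    transcript: str
    consequence: str
    impact_severity: str
    is_lof: bool
    amino_acid_change: Optional[str] = None
    is_primary: bool = False


def _classify_alleles(ref: str, alt: str) -> tuple[str, str]:
    """Return (type, sub_type) for a REF/ALT pair."""
    if alt.startswith("<") or "[" in alt or "]" in alt:
        return "sv", alt.strip("<>").lower()
    if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES:
        return "snp", "ts" if (ref, alt) in _TRANSITIONS else "tv"
    if len(alt) > len(ref):
        return "indel", "ins"
    if len(alt) < len(ref):
        return "indel", "del"
    return "indel", "complex"


def _check_header(path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            for line in fh:
                if line.startswith("#CHROM"):
                    return
                if not line.startswith("#"):
                    break
    except OSError as exc:
        raise VcfFormatError(f"cannot read {path}: {exc}") from exc
    raise VcfFormatError(f"{path}: no #CHROM header line before data")


class VcfReader:
    """Iterate a VCF as (VariantSite, GenotypeRow) pairs.

    Multi-allelic records are split; ``variant_id`` is assigned sequentially
    over the *post-split* stream, starting at 1.
    """

    def __init__(self, path: str):
        _check_header(str(path))
        self._path = str(path)
        self._vcf = VCF(self._path, strict_gt=True)
        self.samples: list[str] = list(self._vcf.samples)
        self.csq_fields: Optional[list[str]] = self._parse_csq_header()

    def _parse_csq_header(self) -> Optional[list[str]]:
        try:
            desc = self._vcf.get_header_type("CSQ").get("Description", "")
        except KeyError:
            return None
        m = re.search(r"Format:\s*([\w|./]+)", desc)
        if not m:
            return None
        return m.group(1).split("|")

    def __iter__(self) -> Iterator[tuple[VariantSite, GenotypeRow]]:
        next_id = 1
        record_no = 0
        it = iter(self._vcf)
        while True:
            try:
                variant = next(it)
            except StopIteration:
                return
            except Exception as exc:  # cyvcf2 surfaces htslib parse failures
                raise VcfParseError(
                    f"{self._path}: failed to parse record "
                    f"{record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            alts = variant.ALT or []
            for alt_index, alt in enumerate(alts):
                site = self._make_site(variant, alt, next_id)
                row = self._make_row(variant, alt_index, alt)
                yield site, row
                next_id += 1

    def _make_site(self, variant, alt: str, variant_id: int) -> VariantSite:
        ref = variant.REF.upper()
        alt = alt.upper()
        vtype, sub = _classify_alleles(ref, alt)
        start = variant.POS - 1
        return VariantSite(
            chrom=variant.CHROM,
            start=start,
            end=start + len(ref),
            ref=ref,
            alt=alt,
            variant_id=variant_id,
            quality=variant.QUAL,
            filter=variant.FILTER,  # None means PASS/'.' per cyvcf2
            type=vtype,
            sub_type=sub,
            info=dict(variant.INFO),
        )

    def _make_row(self, variant, alt_index: int, alt: str) -> GenotypeRow:
        """Recode sample genotypes relative to one ALT allele."""
        wanted = alt_index + 1
        ref = variant.REF.upper()
        gts, gt_types, gt_phases = [], [], []
        for geno in variant.genotypes or []:  # None when the VCF has no samples
            *alleles, phased = geno
            # any third allele makes the call uninterpretable for this record
            if any(a not in (-1, 0, wanted) for a in alleles):
                alleles = [-1] * len(alleles)
            called = [a for a in alleles if a != -1]
            sep = "|" if phased else "/"
            if not called:
                gts.append("./.")
                gt_types.append(UNKNOWN)
                gt_phases.append(False)
                continue
            bases = [ref if a == 0 else alt if a == wanted else "." for a in alleles]
            gts.append(sep.join(bases))
            gt_phases.append(bool(phased))
            if len(called) < len(alleles):
                gt_types.append(UNKNOWN)
            elif all(a == 0 for a in called):
                gt_types.append(HOM_REF)
            elif all(a == wanted for a in called):
                gt_types.append(HOM_ALT)
            else:
                gt_types.append(HET)
        try:
            dp = variant.format("DP")
        except KeyError:  # DP absent from the FORMAT header definitions
            dp = None
        if dp is None:
            depths = [-1] * len(self.samples)
        else:
            # htslib encodes a missing integer as INT32_MIN
            depths = [int(d) if 0 <= int(d) < 2**31 - 1 else -1 for d in dp[:, 0]]
        return GenotypeRow(
            gts=gts, gt_types=gt_types, gt_phases=gt_phases, gt_depths=depths
        )


def read_vcf(path: str) -> VcfReader:
    """Open a VCF (plain or bgzipped) for streaming."""
    return VcfReader(path)


def read_ped(path: str) -> list[PedigreeEntry]:
    """Parse a PLINK 6-column pedigree file.

    Sex and phenotype use the 1/2 integer convention; 0 and -9 mean
    unknown. A parental id of "0" marks a founder.
    """
    entries: list[PedigreeEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedFormatError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(cols)}"
                )
            fam, sample, dad, mom, sex, pheno = cols[:6]
            if not sample or sample == "0":
                raise PedFormatError(f"{path}:{lineno}: empty sample id")
            if sample in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            seen.add(sample)
            entries.append(
                PedigreeEntry(
                    family_id=fam,
                    sample_id=sample,
                    paternal_id=None if dad in ("0", "-9") else dad,
                    maternal_id=None if mom in ("0", "-9") else mom,
                    sex=SEX_CODES.get(sex, "unknown"),
                    phenotype=PHENO_CODES.get(pheno, "unknown"),
                )
            )
    return entries


def _impact_from_ann_block(block: str, variant_id: int) -> TranscriptImpact:
    # ANN: Allele|Annotation|Putative_impact|Gene_Name|Gene_ID|Feature_type|
    #      Feature_ID|Transcript_biotype|Rank|HGVS.c|HGVS.p|...
    fields = block.split("|")
    if len(fields) < 4:
        raise ValueError("too few ANN sub-fields")
    terms = [_vocab.normalize_term(t) for t in fields[1].split("&") if t]
    consequence = max(
        terms, key=lambda t: _vocab.SEVERITY_RANK[_vocab.severity_of(t)]
    )
    return TranscriptImpact(
        variant_id=variant_id,
        gene=fields[3],
        transcript=fields[6] if len(fields) > 6 else "",
        consequence=consequence,
        impact_severity=_vocab.severity_of(consequence),
        is_lof=_vocab.is_lof(consequence),
        amino_acid_change=(fields[10] or None) if len(fields) > 10 else None,
    )


_EFF_RE = re.compile(r"^\s*(\w+)\((.*)\)\s*$")


def _impact_from_eff_block(block: str, variant_id: int) -> TranscriptImpact:
    # EFF (classic): Effect(Impact|Functional_Class|Codon_Change|AA_Change|
    #                AA_Length|Gene_Name|Biotype|Coding|Transcript_ID|...)
    m = _EFF_RE.match(block)
    if not m:
        raise ValueError("not an Effect(...) block")
    consequence = _vocab.normalize_term(m.group(1))
    inner = m.group(2).split("|")
    return TranscriptImpact(
        variant_id=variant_id,
        gene=inner[5] if len(inner) > 5 else "",
        transcript=inner[8] if len(inner) > 8 else "",
        consequence=consequence,
        impact_severity=_vocab.severity_of(consequence),
        is_lof=_vocab.is_lof(consequence),
        amino_acid_change=(inner[3] or None) if len(inner) > 3 else None,
    )


def _impact_from_csq_block(
    block: str, variant_id: int, csq_fields: list[str]
) -> TranscriptImpact:
    values = dict(zip(csq_fields, block.split("|")))
    raw = values.get("Consequence", "")
    terms = [_vocab.normalize_term(t) for t in raw.split("&") if t]
    if not terms:
        raise ValueError("CSQ block without Consequence")
    consequence = max(
        terms, key=lambda t: _vocab.SEVERITY_RANK[_vocab.severity_of(t)]
    )
    return TranscriptImpact(
        variant_id=variant_id,
        gene=values.get("SYMBOL") or values.get("Gene", ""),
        transcript=values.get("Feature", ""),
        consequence=consequence,
        impact_severity=_vocab.severity_of(consequence),
        is_lof=_vocab.is_lof(consequence),
        amino_acid_change=values.get("Amino_acids") or None,
    )


def parse_impacts(
    site: VariantSite, csq_fields: Optional[list[str]] = None
) -> list[TranscriptImpact]:
    """Standardize the site's transcript impacts from ANN, EFF or CSQ.

    One annotation source is consumed per site (ANN preferred, then EFF,
    then CSQ). Malformed blocks are skipped with a warning — an upstream
    annotator glitch must never abort a load. Returns ``[]`` when no
    impact field is present.
    """
    sources = (
        ("ANN", _impact_from_ann_block, None),
        ("EFF", _impact_from_eff_block, None),
        ("CSQ", _impact_from_csq_block, csq_fields),
    )
    for key, builder, extra in sources:
        raw = site.info.get(key)
        if raw is None:
            continue
        impacts = []
        for block in str(raw).split(","):
            try:
                if extra is not None:
                    impacts.append(builder(block, site.variant_id, extra))
                else:
                    impacts.append(builder(block, site.variant_id))
            except (ValueError, IndexError) as exc:
                warnings.warn(
                    f"variant {site.variant_id}: skipping malformed "
                    f"{key} block ({exc})"
                )
        return impacts
    return []


def pick_primary_impact(impacts: list[TranscriptImpact]) -> TranscriptImpact:
    """Select the single representative impact for a variant.

    Highest severity wins; among equals the lexicographically smallest
    transcript id is taken so the choice is order-independent. The chosen
    impact is returned with ``is_primary`` set; the others are cleared.
    """
    if not impacts:
        raise LookupError("no impacts to choose from")
    best = min(
        impacts,
        key=lambda i: (-_vocab.SEVERITY_RANK[i.impact_severity], i.transcript),
    )
    for imp in impacts:
        imp.is_primary = imp is best
    return best
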