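"""Ground-truth-labelled synthetic inputs: VCF, PED, tracks, gene lists.

Every consumer module in the package is exercised against files produced
here, with the truth recorded next to them, so no external download or
reference bundle is ever needed.

Cohort simulation draws, per site, an alternate-allele frequency from
Beta(0.5, 5) — a rare-variant-heavy spectrum resembling a sequenced human
cohort — then genotypes i.i.d. under Hardy-Weinberg equilibrium, followed
by optional uniform genotype missingness. The truth table records every
per-site statistic computed by a separate, straightforward implementation
(explicit formulas; the chi-square tail via ``erfc``), deliberately not
the :mod:`varhive.stats` code it is used to check.

Family simulation builds two households: a trio with an affected child,
and a two-generation quartet with an affected parent and affected child.
Background sites are founder-HWE draws transmitted by Mendelian sampling;
sites that would satisfy an inheritance pattern by chance are redrawn, so
the planted events are exactly the pattern-positive sites. Planted events
carry MED-severity impact annotations in per-event genes; background sites
are LOW severity, keeping them out of the compound-het candidate universe.

All randomness flows from one integer seed through numpy's PCG64
generator, so identical specs give byte-identical files on any platform.
No linkage disequilibrium, recombination, or sequencing-error model is
attempted.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "FamilySpec",
    "simulate_cohort",
    "simulate_families",
    "simulate_inbred_gt_types",
    "make_tracks",
    "SpecError",
]

_BASES = ("A", "C", "G", "T")


class SpecError(ValueError):
    """Invalid simulation specification."""


@dataclass
class CohortSpec:
    n_samples: int = 20
    n_variants: int = 100
    beta_a: float = 0.5
    beta_b: float = 5.0
    missingness: float = 0.0
    seed: int = 0
    chrom: str = "chr1"

    def validate(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise SpecError("missingness must be in [0, 1]")
        if self.n_samples == 0 and self.missingness > 0:
            raise SpecError("missingness is meaningless with zero samples")
        if self.n_variants < 0 or self.n_samples < 0:
            raise SpecError("negative sizes")


@dataclass
class FamilySpec:
    n_variants: int = 1000
    n_de_novo: int = 7
    n_recessive: int = 5
    n_dominant: int = 5
    n_comp_het_trans: int = 4
    n_comp_het_cis: int = 4
    seed: int = 0
    chrom: str = "chr1"

    @property
    def n_planted_sites(self) -> int:
        return (
            self.n_de_novo
            + self.n_recessive
            + self.n_dominant
            + 2 * (self.n_comp_het_trans + self.n_comp_het_cis)
        )

    def validate(self) -> None:
        if self.n_planted_sites > self.n_variants:
            raise SpecError(
                f"{self.n_planted_sites} planted sites exceed "
                f"{self.n_variants} variants"
            )


# ---------------------------------------------------------------------------
# independent statistic formulas for truth tables


def _truth_stats(gt_types: Sequence[int]) -> dict:
    hom_ref = sum(1 for t in gt_types if t == 0)
    het = sum(1 for t in gt_types if t == 1)
    hom_alt = sum(1 for t in gt_types if t == 3)
    unknown = sum(1 for t in gt_types if t == 2)
    total = len(gt_types)
    called = hom_ref + het + hom_alt
    out = {
        "num_hom_ref": hom_ref,
        "num_het": het,
        "num_hom_alt": hom_alt,
        "num_unknown": unknown,
        "call_rate": called / total if total else None,
        "aaf": None,
        "hwe_chi2": None,
        "hwe_p": None,
        "inbreeding_F": None,
        "pi": None,
    }
    if called == 0:
        return out
    j = het + 2 * hom_alt
    m = 2 * called
    out["aaf"] = j / m
    p = (2 * hom_ref + het) / m
    q = 1 - p
    chi2 = 0.0
    for obs, exp in (
        (hom_ref, p * p * called),
        (het, 2 * p * q * called),
        (hom_alt, q * q * called),
    ):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    out["hwe_chi2"] = chi2
    # upper tail of chi-square with 1 d.f. via the complementary error function
    out["hwe_p"] = math.erfc(math.sqrt(chi2 / 2.0))
    if 2 * p * q > 0:
        out["inbreeding_F"] = 1.0 - (het / called) / (2 * p * q)
    if m >= 2:
        out["pi"] = 2.0 * j * (m - j) / (m * (m - 1))
    return out


# ---------------------------------------------------------------------------
# VCF writing


def _vcf_header(samples: Sequence[str], chrom: str, length: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={length}>",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
        "annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | "
        "Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | "
        "HGVS.c | HGVS.p'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def _gt_string(a1: int, a2: int, ref: str, alt: str) -> str:
    bases = {0: "0", 1: "1"}
    return f"{bases[a1]}/{bases[a2]}"


def _gt_type_of(a1: Optional[int], a2: Optional[int]) -> int:
    if a1 is None or a2 is None:
        return 2
    if a1 == a2:
        return 0 if a1 == 0 else 3
    return 1


def _ann_field(ref, alt, pos, gene, consequence, impact, tx) -> str:
    return (
        f"ANN={alt}|{consequence}|{impact}|{gene}|{gene}|transcript|{tx}"
        f"|protein_coding|1|c.{pos}{ref}>{alt}|p.Ala1Val"
    )


def _fmt(value, digits: int = 6) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.{digits}g}"
    return str(value)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(spec: CohortSpec, out_dir: str) -> dict:
    """Write ``cohort.vcf`` and ``cohort_truth.tsv``; return their paths
    and the in-memory truth rows."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    vcf_path = os.path.join(out_dir, "cohort.vcf")
    truth_path = os.path.join(out_dir, "cohort_truth.tsv")

    truth_rows = []
    with open(vcf_path, "w") as vcf:
        vcf.write(
            _vcf_header(samples, spec.chrom, 1000 * (spec.n_variants + 2))
        )
        for i in range(spec.n_variants):
            pos = 1000 * (i + 1)
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            ref, alt = _BASES[ref], _BASES[alt]
            p = float(rng.beta(spec.beta_a, spec.beta_b))
            alleles = rng.random((spec.n_samples, 2)) < p
            missing = rng.random(spec.n_samples) < spec.missingness
            depths = rng.poisson(30, size=spec.n_samples) + 1
            cells, gt_types = [], []
            for s in range(spec.n_samples):
                if missing[s]:
                    cells.append("./.:.")
                    gt_types.append(2)
                else:
                    a1, a2 = int(alleles[s, 0]), int(alleles[s, 1])
                    cells.append(f"{_gt_string(a1, a2, ref, alt)}:{depths[s]}")
                    gt_types.append(_gt_type_of(a1, a2))
            vcf.write(
                f"{spec.chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
            stats = _truth_stats(gt_types)
            stats.update({"variant_id": i + 1, "pos": pos, "p_true": p})
            truth_rows.append(stats)

    header = [
        "variant_id",
        "pos",
        "p_true",
        "num_hom_ref",
        "num_het",
        "num_hom_alt",
        "num_unknown",
        "call_rate",
        "aaf",
        "hwe_chi2",
        "hwe_p",
        "inbreeding_F",
        "pi",
    ]
    with open(truth_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in truth_rows:
            fh.write("\t".join(_fmt(row[k], 10) for k in header) + "\n")
    return {
        "vcf": vcf_path,
        "truth": truth_path,
        "samples": samples,
        "truth_rows": truth_rows,
    }


def simulate_inbred_gt_types(
    n: int, p: float, f: float, n_sites: int, seed: int
) -> list[list[int]]:
    """Genotype-type arrays under a planted inbreeding coefficient.

    Mixture construction: with probability ``f`` a sample is an
    identical-by-descent homozygote (one Bernoulli(p) allele copied), else
    a Hardy-Weinberg draw; the expected per-site F equals ``f``.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for _ in range(n_sites):
        ibd = rng.random(n) < f
        a1 = (rng.random(n) < p).astype(int)
        a2 = np.where(ibd, a1, (rng.random(n) < p).astype(int))
        sites.append([_gt_type_of(int(x), int(y)) for x, y in zip(a1, a2)])
    return sites


# ---------------------------------------------------------------------------
# families

FAM1 = ("dad1", "mom1", "kid1")
FAM2 = ("dad2", "mom2", "kid3", "kid4")
SAMPLES = FAM1 + FAM2

PED_TEXT = """\
fam1 dad1 0 0 1 1
fam1 mom1 0 0 2 1
fam1 kid1 dad1 mom1 1 2
fam2 dad2 0 0 1 2
fam2 mom2 0 0 2 1
fam2 kid3 dad2 mom2 1 2
fam2 kid4 dad2 mom2 2 1
"""


def _mendelian_child(rng, dad: tuple[int, int], mom: tuple[int, int]):
    return (dad[rng.integers(2)], mom[rng.integers(2)])


def _background_site(rng, p: float) -> dict[str, tuple[int, int]]:
    """Founder HWE draws + Mendelian transmission for both families."""
    draw = lambda: (int(rng.random() < p), int(rng.random() < p))
    geno = {"dad1": draw(), "mom1": draw(), "dad2": draw(), "mom2": draw()}
    geno["kid1"] = _mendelian_child(rng, geno["dad1"], geno["mom1"])
    geno["kid3"] = _mendelian_child(rng, geno["dad2"], geno["mom2"])
    geno["kid4"] = _mendelian_child(rng, geno["dad2"], geno["mom2"])
    return geno


def _type(g: tuple[int, int]) -> int:
    return _gt_type_of(g[0], g[1])


def _matches_any_pattern(geno: dict) -> bool:
    """Would these genotypes satisfy a screened inheritance pattern?"""
    # fam1 recessive: affected kid1 HOM_ALT, unaffected parents HET
    if (
        _type(geno["kid1"]) == 3
        and _type(geno["dad1"]) == 1
        and _type(geno["mom1"]) == 1
    ):
        return True
    # fam2 dominant: affected dad2+kid3 HET, unaffected mom2+kid4 HOM_REF
    if (
        _type(geno["dad2"]) == 1
        and _type(geno["kid3"]) == 1
        and _type(geno["mom2"]) == 0
        and _type(geno["kid4"]) == 0
    ):
        return True
    return False


_HOM_REF = (0, 0)


def simulate_families(spec: FamilySpec, out_dir: str) -> dict:
    """Write ``families.vcf``, ``families.ped`` and ``families_truth.tsv``.

    The truth table lists every planted event with its pattern, family,
    carrier sample, gene and variant id(s); cis decoy pairs are recorded
    as ``comp_het_cis_decoy`` and must produce no hits.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)

    planted_ids = rng.choice(
        np.arange(1, spec.n_variants + 1), size=spec.n_planted_sites, replace=False
    )
    planted_ids = [int(v) for v in planted_ids]
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        out = planted_ids[cursor : cursor + n]
        cursor += n
        return out

    events = []  # (pattern, family, sample, gene, [variant_ids], genotypes)
    plan: dict[int, tuple] = {}  # variant_id -> (genotypes, gene, consequence)

    for j, vid in enumerate(take(spec.n_de_novo)):
        geno = {s: _HOM_REF for s in SAMPLES}
        geno["kid1"] = (0, 1)
        plan[vid] = (geno, f"DNGENE{j + 1}", "missense_variant")
        events.append(("de_novo", "fam1", "kid1", f"DNGENE{j + 1}", [vid]))
    for j, vid in enumerate(take(spec.n_recessive)):
        geno = {s: _HOM_REF for s in SAMPLES}
        geno.update({"dad1": (0, 1), "mom1": (0, 1), "kid1": (1, 1)})
        plan[vid] = (geno, f"ARGENE{j + 1}", "missense_variant")
        events.append(("recessive", "fam1", "kid1", f"ARGENE{j + 1}", [vid]))
    for j, vid in enumerate(take(spec.n_dominant)):
        geno = {s: _HOM_REF for s in SAMPLES}
        geno.update({"dad2": (0, 1), "kid3": (0, 1)})
        plan[vid] = (geno, f"ADGENE{j + 1}", "missense_variant")
        events.append(("dominant", "fam2", "kid3", f"ADGENE{j + 1}", [vid]))
    for j in range(spec.n_comp_het_trans):
        va, vb = sorted(take(2))
        gene = f"CHGENE{j + 1}"
        geno_a = {s: _HOM_REF for s in SAMPLES}
        geno_a.update({"mom1": (0, 1), "kid1": (0, 1)})  # maternal origin
        geno_b = {s: _HOM_REF for s in SAMPLES}
        geno_b.update({"dad1": (0, 1), "kid1": (0, 1)})  # paternal origin
        plan[va] = (geno_a, gene, "missense_variant")
        plan[vb] = (geno_b, gene, "missense_variant")
        events.append(("comp_het", "fam1", "kid1", gene, [va, vb]))
    for j in range(spec.n_comp_het_cis):
        va, vb = sorted(take(2))
        gene = f"CISGENE{j + 1}"
        for v in (va, vb):  # both alleles from mom: cis, must NOT be a hit
            geno = {s: _HOM_REF for s in SAMPLES}
            geno.update({"mom1": (0, 1), "kid1": (0, 1)})
            plan[v] = (geno, gene, "missense_variant")
        events.append(("comp_het_cis_decoy", "fam1", "kid1", gene, [va, vb]))

    vcf_path = os.path.join(out_dir, "families.vcf")
    ped_path = os.path.join(out_dir, "families.ped")
    truth_path = os.path.join(out_dir, "families_truth.tsv")

    with open(ped_path, "w") as fh:
        fh.write(PED_TEXT)

    with open(vcf_path, "w") as vcf:
        vcf.write(_vcf_header(SAMPLES, spec.chrom, 1000 * (spec.n_variants + 2)))
        for vid in range(1, spec.n_variants + 1):
            pos = 1000 * vid
            ref_i, alt_i = rng.choice(len(_BASES), size=2, replace=False)
            ref, alt = _BASES[ref_i], _BASES[alt_i]
            if vid in plan:
                geno, gene, consequence = plan[vid]
                impact = "MODERATE"
            else:
                p = float(rng.beta(0.5, 5.0))
                geno = _background_site(rng, p)
                for _ in range(1000):
                    if not _matches_any_pattern(geno):
                        break
                    geno = _background_site(rng, p)
                else:  # pragma: no cover - p would have to be pathological
                    raise RuntimeError("could not draw a pattern-free site")
                gene, consequence, impact = f"BGGENE{vid}", "intron_variant", "MODIFIER"
            depths = rng.integers(20, 41, size=len(SAMPLES))
            cells = [
                f"{_gt_string(*geno[s], ref, alt)}:{depths[k]}"
                for k, s in enumerate(SAMPLES)
            ]
            info = _ann_field(ref, alt, pos, gene, consequence, impact, f"TX{vid}")
            vcf.write(
                f"{spec.chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t{info}\t"
                "GT:DP\t" + "\t".join(cells) + "\n"
            )

    with open(truth_path, "w") as fh:
        fh.write("pattern\tfamily\tsample\tgene\tvariant_ids\n")
        for pattern, family, sample, gene, vids in events:
            fh.write(
                f"{pattern}\t{family}\t{sample}\t{gene}\t"
                + ",".join(map(str, vids))
                + "\n"
            )
    return {
        "vcf": vcf_path,
        "ped": ped_path,
        "truth": truth_path,
        "samples": list(SAMPLES),
        "events": events,
    }


# ---------------------------------------------------------------------------
# annotation tracks


def make_tracks(
    variants: Sequence[tuple[str, int, int, int]],
    overlap_fraction: float,
    seed: int,
    out_dir: str,
) -> dict:
    """Write BED / GFF3 / sites-VCF tracks overlapping a known variant subset.

    ``variants`` is (chrom, start, end, variant_id) in 0-based half-open
    coordinates. A fraction of variants is chosen to be covered by one
    interval per track; the truth table is then recomputed by a brute-force
    all-pairs overlap scan over what was actually written, so it stays
    correct even when intervals happen to graze a non-chosen variant.
    Truth values per track: bed_hit (0/1), gff_label (comma-joined Name
    attributes or NA), vcf_count (int).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise SpecError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    variants = list(variants)
    n_pick = int(round(overlap_fraction * len(variants)))
    order = rng.permutation(len(variants))
    chosen = sorted(int(i) for i in order[:n_pick])

    bed_iv, gff_iv, vcf_iv = [], [], []
    for rank, i in enumerate(chosen):
        chrom, start, end, _ = variants[i]
        pad_l = int(rng.integers(0, 50))
        pad_r = int(rng.integers(0, 50))
        lo, hi = max(0, start - pad_l), end + pad_r
        bed_iv.append((chrom, lo, hi, f"region{rank}"))
        gff_iv.append((chrom, lo, hi, f"label{rank}"))
        vcf_iv.append((chrom, start, end))

    bed_path = os.path.join(out_dir, "track.bed")
    gff_path = os.path.join(out_dir, "track.gff3")
    sites_path = os.path.join(out_dir, "track_sites.vcf")
    with open(bed_path, "w") as fh:
        for chrom, lo, hi, name in bed_iv:
            fh.write(f"{chrom}\t{lo}\t{hi}\t{name}\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, lo, hi, label in gff_iv:
            fh.write(
                f"{chrom}\tsynth\tregion\t{lo + 1}\t{hi}\t.\t+\t.\t"
                f"ID={label};Name={label}\n"
            )
    with open(sites_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, start, end in vcf_iv:
            fh.write(f"{chrom}\t{start + 1}\t.\t{'N' * (end - start)}\tA\t.\t.\t.\n")

    # brute-force truth over what was written
    def overlaps(chrom, s, e, ivs):
        return [iv for iv in ivs if iv[0] == chrom and iv[1] < e and s < iv[2]]

    truth_path = os.path.join(out_dir, "tracks_truth.tsv")
    truth_rows = {}
    with open(truth_path, "w") as fh:
        fh.write("variant_id\tbed_hit\tgff_label\tvcf_count\n")
        for chrom, start, end, vid in variants:
            bed_hit = 1 if overlaps(chrom, start, end, bed_iv) else 0
            labels = sorted({iv[3] for iv in overlaps(chrom, start, end, gff_iv)})
            gff_label = ",".join(labels) if labels else None
            vcf_count = len(overlaps(chrom, start, end, vcf_iv))
            truth_rows[vid] = (bed_hit, gff_label, vcf_count)
            fh.write(
                f"{vid}\t{bed_hit}\t{gff_label if gff_label else 'NA'}\t{vcf_count}\n"
            )
    return {
        "bed": bed_path,
        "gff": gff_path,
        "vcf_sites": sites_path,
        "truth": truth_path,
        "truth_rows": truth_rows,
    }
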