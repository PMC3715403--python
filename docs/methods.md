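# Methods

This document records what `varhive` computes, how, and why the defaults
are what they are. Nothing here makes an empirical claim that is not
checked by the test suite or `scripts/acceptance.py`.

## Data model

One SQLite file holds five tables:

- `variants` — one row per (site, alternate allele). Multi-allelic VCF
  records are split; in each split row, any sample genotype carrying a
  *different* alternate allele is recoded as uncalled rather than
  reinterpreted. Rationale: a `0/2` call says nothing reliable about the
  `ALT=G` row, and fabricating `HOM_REF` there would silently bias allele
  frequencies downward.
- `variant_impacts` — one row per transcript consequence (from snpEff
  `ANN`, legacy snpEff `EFF`, or VEP `CSQ` INFO fields). One impact per
  variant is flagged `is_primary` (highest severity; ties broken by
  transcript id for determinism) and denormalized into `variants`.
- `samples` — pedigree (PLINK 6-column PED): family, parents, sex,
  phenotype. Samples in the VCF but not the PED load with NULL pedigree
  fields and a warning; PED samples missing from the VCF are an error,
  because every downstream genotype lookup would be undefined.
- `resources` — input file paths and MD5 checksums.
- `meta` — schema version.

Coordinates are 0-based half-open internally (`start = POS − 1`,
`end = start + len(REF)`); BED input is used as-is, GFF is converted from
its 1-based inclusive convention.

Genotype type codes are fixed public constants: `HOM_REF=0`, `HET=1`,
`UNKNOWN=2`, `HOM_ALT=3`.

## Genotype storage

Per variant, four parallel arrays (genotype strings, type codes, phase
flags, depths) are serialized and zlib-compressed (level 6, fixed) into
one blob each. The blob frame is: 1-byte codec tag, 1-byte kind marker
(string/int/bool), 4-byte Adler-32 of the payload, payload. The checksum
turns silent corruption into an explicit `BlobIntegrityError`; the tag
lets a future codec change fail loudly (`CodecVersionError`) instead of
decoding garbage. Fixed compression settings make packing byte-
deterministic, which is what makes parallel loading verifiable (below).
Missing depth is the sentinel −1; missing genotype is `./.` / type 2.

## Per-site statistics

Computed at load over called genotypes only:

- `aaf = j/m` with `j = het + 2·hom_alt`, `m = 2·called`;
- HWE: Pearson chi-square, 1 d.f., expected counts `(p²n, 2pqn, q²n)`;
  p-value is the upper tail (`scipy.stats.chi2.sf`). Monomorphic sites fit
  exactly (chi2 0, p 1). No continuity correction and no exact test: the
  plain chi-square is the standard screening statistic, and its null
  calibration is verified empirically (rejection rate at p<0.05 within
  [0.03, 0.07] for n=500, p=0.3).
- inbreeding coefficient `F = 1 − H_obs/(2pq)`; NULL when monomorphic.
- nucleotide diversity `π = 2j(m−j)/(m(m−1))` (unbiased pairwise
  heterozygosity over the sampled alleles).

Undefined values are SQL NULL throughout; a NULL never compares true in a
WHERE clause, which is the behavior analysts expect from missing data.

## Query DSL

SQL cannot reach inside the genotype blobs, so the query layer adds
`COLUMN.SAMPLE` pseudo-columns (`gts`, `gt_types`, `gt_phases`,
`gt_depths`) in select lists, and a boolean `--gt-filter` expression
grammar (`and`, `or`, `not`, parentheses, the six comparison operators;
`=  =` is accepted as `==`). The filter is applied row-by-row *after* SQL
execution, so it can only prune the SQL result set, never widen it.

Missing-data semantics: comparing an uncalled genotype against a called
literal makes `==` false and `!=` true; ordered comparisons are false.
Depth −1 follows plain numeric semantics by default so that
`gt_depths.s < 10` treats unknown depth as failing quality, and
`--strict-missing` instead makes every comparison on missing data false.

## Parallel, chunked loading

Variant ids are assigned while streaming the VCF, before work is
distributed, and all per-record processing is pure, so the database
content is a function of the input alone: any `--cores` value, chunk size
or batch size produces identical `variants`/`variant_impacts`/`samples`
tables. Independently loaded VCF slices (with `first_variant_id` offsets)
can be combined with `merge_chunks`, which validates that id ranges are
contiguous and non-overlapping; the merged tables equal a single-process
load of the whole file. (The `resources` table necessarily differs — it
records which files were loaded.)

## Interval annotation

Tracks (BED, GFF3, sites-VCF) are loaded into per-chromosome interval
trees, indexed under both `chr1` and `1` spellings so mixed chromosome
naming still matches. Overlap is strict half-open intersection. Modes:
`boolean`, `count`, `extract` (sorted unique values, comma-joined —
deterministic under track line reordering), `extract_numeric` (maximum).
Sites-VCF tracks can optionally require REF/ALT agreement.

## Inheritance screens

- **de novo**: child HET, both parents HOM_REF, all called; optional
  minimum depth for all three.
- **autosomal recessive**: affected child HOM_ALT, both unaffected
  parents HET.
- **autosomal dominant**: every affected family member HET, every
  unaffected HOM_REF (full penetrance by default;
  `--allow-unaffected-carriers` relaxes it), and every affected member
  with genotyped parents must have at least one affected carrier parent —
  the transmission requirement that separates dominance from coincidence.
- **compound heterozygote**: pairs of HET sites in one gene. With
  genotyped parents, each site must have exactly one carrier parent and
  the two sites opposite carriers (trans); ambiguous parental
  configurations are dropped rather than guessed. Without parents, phased
  genotypes must put the alternates on opposite haplotypes; with neither,
  the pair is reported as `putative_unphased`. Candidate sites default to
  severity MED+ (LOW-severity pairs are overwhelmingly benign noise), and
  scanning defaults to affected samples only.

Sites with any uncalled genotype in the family under test are skipped.
X/Y records are excluded from the autosomal screens. Each screen's
genotype rule is expressible as a `--gt-filter` expression and is tested
to agree with it.

## Fixture generator

`fixtures cohort` draws per-site allele frequencies from Beta(0.5, 5) — a
rare-variant-heavy spectrum — then genotypes i.i.d. under HWE, with
optional uniform missingness. The accompanying truth table is computed by
a separate, deliberately simple implementation (explicit formulas; the
chi-square tail via `erfc`), not by the package's own statistics code.

`fixtures families` builds a trio (affected child) and a quartet
(affected parent and child) and plants de novo, recessive, dominant, and
trans/cis compound-het events at randomly chosen sites, each in its own
gene, with MED-severity annotations; planted sites are silent (HOM_REF)
in the other family. Background sites are founder-HWE draws transmitted
Mendelianly and carry LOW-severity annotations; any background draw that
would satisfy a screened pattern by chance is redrawn. Consequently the
planted events are *exactly* the pattern-positive sites, which is what
makes "sensitivity 1.0, zero false positives" a meaningful check rather
than a statistical statement.

Not modeled: linkage disequilibrium, recombination, sequencing error,
de novo rate realism, sex chromosomes. The generator exists to exercise
the analysis code against known truth, not to be a population-genetics
simulator.

All randomness flows from one integer seed through numpy's PCG64;
identical specs give byte-identical files.

## Acceptance script

`python scripts/acceptance.py --seed N --out PATH` regenerates all
fixtures from the seed and reports, as JSON: agreement of 50 randomized
SQL+filter queries with a brute-force scan (5,000×20 fixture), planted
inheritance recovery over 5 seeds, the fixed-count statistic values and
simulation calibrations, codec round-trip over 10,000 rows, load
determinism across core counts and chunkings, annotation agreement with
an all-pairs scan, tool/DSL agreement for the recessive screen, and the
database-size-to-text-size ratio for a 200×1,000 fixture.

## Numerical and design choices

- zlib level 6: determinism matters (it is part of the load-determinism
  guarantee); marginal size differences between levels do not.
- Adler-32 rather than CRC-32: both detect the corruption classes of
  interest; Adler-32 is what zlib already provides alongside compression.
- When a record carries several impact INFO fields, preference is
  `ANN` > `EFF` > `CSQ` (newest, best-specified format first).
- Severity mapping is a fixed vocabulary table (HIGH for truncating /
  splice-disrupting consequences, MED for protein-altering, LOW
  otherwise), with legacy `EFF` terms normalized onto the same
  vocabulary.
- Seeds are kept below 2³¹ for portability.

## Limitations

- Single-node SQLite: no concurrent writers, databases in the
  hundreds-of-GB range are out of scope.
- The genotype filter runs in Python per row; highly selective SQL
  pre-filters are the intended usage pattern.
- Gene matching in the gene-set/interaction tools is by uppercased
  symbol, with no alias resolution.
- Sex-chromosome inheritance (X-linked models, hemizygosity) is not
  implemented; X/Y sites are simply excluded from autosomal screens.
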