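# varhive

A single-file SQL warehouse for exploring genetic variation in sequenced
cohorts and families.

A VCF file answers "what was called where", but most analysis questions —
*which rare, damaging variants fit a recessive model in this family?* —
combine variant-level facts (position, consequence, allele frequency) with
sample-level genotypes. `varhive` loads a VCF (plus an optional PED
pedigree and interval annotation tracks) into one SQLite database and
makes both layers queryable together:

- **Variant columns** (coordinates, consequence, severity, LoF flag,
  per-site statistics) are ordinary SQL columns.
- **Genotypes** are stored as compressed per-variant arrays and addressed
  with a `COLUMN.SAMPLE` notation that plain SQL lacks: select
  `gts.NA12878`, or filter with
  `--gt-filter "gt_types.mom == HET and gt_types.dad == HET"`.
- Built-in screens cover de novo, autosomal recessive, autosomal dominant
  and compound-heterozygote inheritance, plus gene-set and
  protein-interaction views of a sample's variant load.
- A fixture generator produces synthetic VCF/PED/track files with exact
  ground truth, so every feature is testable offline.

## Model and notation

Genotypes are coded per sample as `HOM_REF=0`, `HET=1`, `UNKNOWN=2`,
`HOM_ALT=3`. Coordinates are stored 0-based half-open (`start`, `end`);
multi-allelic records are split into one row per alternate allele, and a
genotype that carries a different alternate allele is treated as uncalled
in that row.

Per site, with genotype counts (hom-ref, het, hom-alt) among the *n*
called samples, allele count *j = het + 2·hom-alt* over *m = 2n* alleles:

- alternate allele frequency `aaf = j/m`;
- Hardy–Weinberg equilibrium: Pearson chi-square with 1 d.f. against
  expected counts `(p²n, 2pqn, q²n)`, p-value from the upper tail;
- inbreeding coefficient `F = 1 − H_obs / (2pq)`;
- nucleotide diversity `π = 2j(m−j) / (m(m−1))`.

Statistics that are undefined (no called genotypes, monomorphic for `F`)
are stored as SQL `NULL`, never as 0.

## Worked example

Generate a synthetic two-family cohort with planted inheritance events,
load it, and query it (all output below is real):

```console
$ varhive fixtures families --seed 11 --variants 300 --out fx
wrote fx/families.vcf, fx/families.ped and fx/families_truth.tsv
$ varhive load -v fx/families.vcf -p fx/families.ped study.db
loaded 300 variants, 7 samples -> study.db
$ varhive query -q "select chrom, start, ref, alt, gene, aaf, gts.kid1 \
    from variants where impact_severity = 'MED' and aaf < 0.3 limit 5" \
    --header study.db
chrom	start	ref	alt	gene	aaf	gts.kid1
chr1	34999	G	C	DNGENE1	0.07142857142857142	G/C
chr1	35999	A	C	DNGENE7	0.07142857142857142	A/C
chr1	74999	C	A	DNGENE6	0.07142857142857142	C/A
chr1	153999	A	G	DNGENE2	0.07142857142857142	A/G
chr1	164999	G	A	DNGENE4	0.07142857142857142	G/A
$ varhive de_novo study.db | head -4
pattern	family	sample	gene	variant_id	genotypes	note
de_novo	fam1	kid1	DNGENE1	35	kid1=G/C;dad1=G/G;mom1=G/G
de_novo	fam1	kid1	DNGENE7	36	kid1=A/C;dad1=A/A;mom1=A/A
de_novo	fam1	kid1	DNGENE6	75	kid1=C/A;dad1=C/C;mom1=C/C
```

The same database is scriptable through the API:

```pycon
>>> from varhive import open_session
>>> with open_session("study.db") as s:
...     s.scalar("SELECT COUNT(*) FROM variants WHERE hwe < 0.05")
...     row = next(s.variants("gene = 'ARGENE1'"))
...     (row.gene, row.chrom, row.start, row.genotypes("kid1"))
3
('ARGENE1', 'chr1', 280999, ('C/C', 3, False, 34))
```

`row.genotypes(sample)` returns `(genotype string, type code, phased,
depth)`.

Other commands: `autosomal_recessive`, `autosomal_dominant`, `comp_hets`,
`pathways`, `interactions`, `annotate` (adds an interval-track column to
an existing database), and `fixtures cohort|families|tracks`. Run any
command with `--help` for options.

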