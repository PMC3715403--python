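import os

import pytest

from varhive import load, simulate
from varhive.annotate import AnnotationTrack
from varhive.io_formats import read_vcf


@pytest.fixture(scope="session")
def family_fixture(tmp_path_factory):
    """Planted-event family VCF/PED (7 de novo, 5 recessive, 5 dominant,
    4 trans comp-het pairs + 4 cis decoys among 1000 sites), loaded."""
    out = tmp_path_factory.mktemp("families")
    fx = simulate.simulate_families(
        simulate.FamilySpec(n_variants=1000, seed=3), str(out)
    )
    fx["db"] = str(out / "families.db")
    load(fx["db"], fx["vcf"], ped_path=fx["ped"])
    return fx


@pytest.fixture(scope="session")
def cohort_fixture(tmp_path_factory):
    """A 20-sample, 300-site HWE cohort with 5% missingness plus three
    annotation tracks, loaded with all tracks attached."""
    out = tmp_path_factory.mktemp("cohort")
    fx = simulate.simulate_cohort(
        simulate.CohortSpec(n_samples=20, n_variants=300, missingness=0.05, seed=5),
        str(out),
    )
    variants = [
        (s.chrom, s.start, s.end, s.variant_id) for s, _ in read_vcf(fx["vcf"])
    ]
    tr = simulate.make_tracks(variants, 0.4, seed=7, out_dir=str(out))
    fx["tracks_truth"] = tr["truth_rows"]
    fx["track_list"] = [
        AnnotationTrack(name="bedtrk", path=tr["bed"], format="bed", mode="boolean"),
        AnnotationTrack(
            name="gfftrk",
            path=tr["gff"],
            format="gff",
            mode="extract",
            extract_column="Name",
        ),
        AnnotationTrack(
            name="sitestrk", path=tr["vcf_sites"], format="vcf-sites", mode="count"
        ),
    ]
    fx["db"] = str(out / "cohort.db")
    load(fx["db"], fx["vcf"], tracks=fx["track_list"])
    return fx
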