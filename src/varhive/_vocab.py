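"""Controlled vocabulary for transcript consequences.

Consequence terms follow the Sequence Ontology. Upstream annotators emit
either SO terms directly (snpEff ``ANN``, VEP ``CSQ``) or the legacy
snpEff ``EFF`` "classic" names, which are translated here so that one
shared vocabulary reaches the database regardless of the annotation tool.
"""

from __future__ import annotations

HIGH = "HIGH"
MED = "MED"
LOW = "LOW"

SEVERITY_RANK = {HIGH: 3, MED: 2, LOW: 1}

HIGH_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "transcript_ablation",
    }
)

MED_TERMS = frozenset(
    {
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_region_variant",
        "protein_altering_variant",
    }
)

LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

# Legacy snpEff "classic" EFF names -> Sequence Ontology terms.
EFF_SYNONYMS = {
    "STOP_GAINED": "stop_gained",
    "STOP_LOST": "stop_lost",
    "START_LOST": "start_lost",
    "FRAME_SHIFT": "frameshift_variant",
    "SPLICE_SITE_ACCEPTOR": "splice_acceptor_variant",
    "SPLICE_SITE_DONOR": "splice_donor_variant",
    "SPLICE_SITE_REGION": "splice_region_variant",
    "TRANSCRIPT_ABLATION": "transcript_ablation",
    "NON_SYNONYMOUS_CODING": "missense_variant",
    "NON_SYNONYMOUS_START": "missense_variant",
    "CODON_INSERTION": "inframe_insertion",
    "CODON_DELETION": "inframe_deletion",
    "CODON_CHANGE_PLUS_CODON_INSERTION": "protein_altering_variant",
    "CODON_CHANGE_PLUS_CODON_DELETION": "protein_altering_variant",
    "SYNONYMOUS_CODING": "synonymous_variant",
    "SYNONYMOUS_STOP": "stop_retained_variant",
    "START_GAINED": "5_prime_UTR_premature_start_codon_gain_variant",
    "UTR_5_PRIME": "5_prime_UTR_variant",
    "UTR_3_PRIME": "3_prime_UTR_variant",
    "INTRON": "intron_variant",
    "INTRAGENIC": "intragenic_variant",
    "INTERGENIC": "intergenic_variant",
    "UPSTREAM": "upstream_gene_variant",
    "DOWNSTREAM": "downstream_gene_variant",
    "EXON": "exon_variant",
    "GENE": "gene_variant",
    "TRANSCRIPT": "transcript_variant",
    "CDS": "coding_sequence_variant",
    "REGULATION": "regulatory_region_variant",
}


def normalize_term(term: str) -> str:
    """Map an annotator-emitted consequence term to the shared vocabulary."""
    term = term.strip()
    return EFF_SYNONYMS.get(term, term.lower())


def severity_of(consequence: str) -> str:
    """Classify a (normalized) consequence term as HIGH, MED or LOW."""
    if consequence in HIGH_TERMS:
        return HIGH
    if consequence in MED_TERMS:
        return MED
    return LOW


def is_lof(consequence: str) -> bool:
    return consequence in LOF_TERMS
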