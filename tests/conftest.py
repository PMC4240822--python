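"""Shared fixtures: packaged resources and a family-A-like worked dataset."""

from __future__ import annotations

import pytest
from hypothesis import settings

from trioprior import data as tdata

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from trioprior.model import FrequencyTable, PedSample, Pedigree, Variant
from trioprior.consequence import TranscriptModel


@pytest.fixture(scope="session")
def panel():
    return tdata.default_panel()


@pytest.fixture(scope="session")
def transcripts():
    return tdata.default_transcripts()


@pytest.fixture(scope="session")
def alignments():
    return tdata.default_alignments()


@pytest.fixture(scope="session")
def known():
    return tdata.known_mutations()


@pytest.fixture(scope="session")
def published_scores():
    return tdata.published_scores()


@pytest.fixture
def minus_transcript():
    """Synthetic minus-strand two-exon transcript for strand-handling checks."""
    # transcript order 5'->3' = descending genomic; CDS = ATG GAT CAT CTG TAA
    cds = "ATGGATCATCTGTAA"
    # exon1 (transcript): genomic 2041..2049 (9 nt), exon2: 2001..2006 (6 nt)
    return TranscriptModel(
        gene="MINUS1",
        chrom="chr9",
        strand="-",
        exons=[(2041, 2049), (2001, 2006)],
        cds_start_cdna=1,
        cds_seq=cds,
    )


def make_family_a_pedigree() -> Pedigree:
    """Four members: unaffected spouse I:1, affected I:2, II:1, II:2."""
    return Pedigree(
        [
            PedSample("I:1", None, None, 1, False),
            PedSample("I:2", None, None, 2, True),
            PedSample("II:1", "I:1", "I:2", 1, True),
            PedSample("II:2", "I:1", "I:2", 2, True),
        ]
    )


def coseg_genotypes():
    """Co-segregating pattern: alt in all affecteds, absent in the spouse."""
    return {"I:1": (0, 0), "I:2": (0, 1), "II:1": (0, 1), "II:2": (0, 1)}


#: six co-segregating panel variants of the family-A worked example:
#: five with population MAFs spanning 8.5%-52.4%, one rare (0/8,600)
FAMILY_A_VARIANTS = [
    ("chr2", 208989018, "C", "A", "rs28931605", None),  # CRYGD causal, 0/8600
    ("chr10", 91222287, "T", "G", "rs3740030", 0.085),  # SLC16A12
    ("chr11", 31820000, "G", "A", "rs1000001", 0.195),  # PAX6
    ("chr11", 111780500, "C", "T", "rs1000002", 0.302),  # CRYAB
    ("chr17", 73755000, "A", "G", "rs1000003", 0.413),  # GALK1
    ("chr17", 73756000, "G", "C", "rs1000004", 0.524),  # GALK1
]


@pytest.fixture
def family_a():
    """Family-A-like dataset: pedigree, variants and frequency table.

    Besides the six co-segregating panel variants it carries one panel
    variant that fails segregation and one off-panel variant, so every
    exclusion stage appears in the trails.
    """
    ped = make_family_a_pedigree()
    variants = []
    entries = {}
    an = 8600
    for chrom, pos, ref, alt, vid, maf in FAMILY_A_VARIANTS:
        variants.append(Variant(chrom, pos, ref, alt, vid, dict(coseg_genotypes())))
        ac = 0 if maf is None else round(maf * an)
        entries[(chrom, pos, ref, alt)] = (ac, an)
    # panel variant carried by the unaffected spouse -> fails segregation
    variants.append(
        Variant("chr2", 208989100, "G", "T", "rs1000005",
                {"I:1": (0, 1), "I:2": (0, 1), "II:1": (0, 1), "II:2": (0, 1)})
    )
    # off-panel variant
    variants.append(
        Variant("chr5", 1000000, "A", "C", "rs1000006", dict(coseg_genotypes()))
    )
    return {
        "pedigree": ped,
        "variants": variants,
        "frequencies": FrequencyTable(entries),
    }
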