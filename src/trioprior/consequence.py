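"""Genomic-to-cDNA mapping, codon arithmetic and HGVS substitution nomenclature.

The engine maps an exonic genomic substitution onto a transcript's coding
sequence (CDS), computes the affected codon, translates reference and mutant
codons with the standard genetic code, and emits HGVS ``c.``/``p.`` strings.
Only single-nucleotide substitutions within the CDS are in scope; protein
numbering follows the recommended convention with the initiator methionine as
residue 1, with mature-protein renumbering (initiator removed) available as an
explicit separate view.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .exceptions import (
    HgvsParseError,
    InputFormatError,
    NonCodingPositionError,
    ReferenceMismatchError,
    TrioPriorError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """Exon structure plus coding sequence for one gene.

    ``exons`` are 1-based inclusive genomic intervals ordered 5'→3' in
    transcript orientation (descending genomic coordinates on the minus
    strand).  ``cds_start_cdna`` is the 1-based cDNA offset of the A of the
    initiator ATG.  ``cds_seq`` is the coding sequence in transcript
    orientation, including the terminal stop codon.
    """

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: List[Tuple[int, int]]
    cds_start_cdna: int
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputFormatError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise InputFormatError(f"exon {start}-{end}: start > end")
        # non-overlap, ordered in transcript orientation
        genomic_order = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if e1 >= s2:
                raise InputFormatError("exons must be non-overlapping and ordered")
        if len(self.cds_seq) % 3 != 0:
            raise InputFormatError(
                f"{self.gene}: CDS length {len(self.cds_seq)} not divisible by 3"
            )
        if not self.cds_seq.startswith("ATG"):
            raise InputFormatError(f"{self.gene}: CDS must begin with ATG")
        internal = [
            self.cds_seq[i : i + 3]
            for i in range(0, len(self.cds_seq) - 3, 3)
        ]
        if any(c in ("TAA", "TAG", "TGA") for c in internal):
            raise InputFormatError(f"{self.gene}: CDS contains an internal stop codon")
        exonic = sum(e - s + 1 for s, e in self.exons)
        if self.cds_start_cdna < 1 or self.cds_start_cdna + len(self.cds_seq) - 1 > exonic:
            raise InputFormatError(f"{self.gene}: CDS does not fit within the exons")

    @property
    def cds_len(self) -> int:
        return len(self.cds_seq)

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3


def genomic_to_cdna(pos: int, tm: TranscriptModel) -> int:
    """Map a 1-based genomic position to a 1-based CDS coordinate.

    Raises :class:`NonCodingPositionError` for intronic, intergenic or UTR
    positions — the cascade's variants of interest are exonic and coding.
    """
    offset = 0
    cdna = None
    for start, end in tm.exons:
        length = end - start + 1
        if start <= pos <= end:
            within = pos - start if tm.strand == "+" else end - pos
            cdna = offset + within + 1
            break
        offset += length
    if cdna is None:
        raise NonCodingPositionError(
            f"{tm.chrom}:{pos} is not exonic in transcript {tm.gene}"
        )
    c_pos = cdna - tm.cds_start_cdna + 1
    if not 1 <= c_pos <= tm.cds_len:
        raise NonCodingPositionError(
            f"{tm.chrom}:{pos} maps to cDNA {cdna}, outside the CDS of {tm.gene}"
        )
    return c_pos


def cdna_to_genomic(c_pos: int, tm: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cdna`."""
    if not 1 <= c_pos <= tm.cds_len:
        raise NonCodingPositionError(f"c.{c_pos} outside CDS of {tm.gene}")
    cdna = c_pos + tm.cds_start_cdna - 1
    offset = 0
    for start, end in tm.exons:
        length = end - start + 1
        if cdna <= offset + length:
            within = cdna - offset - 1
            return start + within if tm.strand == "+" else end - within
        offset += length
    raise NonCodingPositionError(f"c.{c_pos} beyond the exons of {tm.gene}")


def codon_of(c_pos: int) -> Tuple[int, int]:
    """(codon_index, within_codon_offset) for a 1-based CDS position.

    Codon 1 is the initiator ATG; offsets are 0, 1, 2 across the codon.
    """
    if c_pos < 1:
        raise TrioPriorError(f"c_pos must be >= 1, got {c_pos}")
    return (c_pos - 1) // 3 + 1, (c_pos - 1) % 3


def mature_numbering(codon_index: int) -> int:
    """Mature-protein residue number after cleavage of the initiator Met.

    Residue 1 of the mature protein is canonical codon 2, so canonical codon
    24 of γD-crystallin is mature residue 23 (p.Pro24Thr ≡ p.Pro23Thr).
    """
    if codon_index < 2:
        raise TrioPriorError(
            "the initiator methionine has no mature-protein number"
        )
    return codon_index - 1


@dataclass(frozen=True)
class ConsequenceCall:
    """Protein-level description of a coding substitution."""

    gene: str
    c_pos: int
    ref_base: str
    alt_base: str
    codon_index: int
    within_codon_offset: int
    ref_aa: str  # 3-letter code, or "Ter"
    alt_aa: str
    klass: str  # missense | synonymous | nonsense | start-lost

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.c_pos}{self.ref_base}>{self.alt_base}"

    @property
    def hgvs_p(self) -> str:
        if self.klass == "synonymous":
            return "p.(=)"
        if self.klass == "start-lost":
            return "p.Met1?"
        return f"p.{self.ref_aa}{self.codon_index}{self.alt_aa}"


def _aa3(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "Ter" if aa == "*" else seq3(aa)


def translate_substitution(
    tm: TranscriptModel, c_pos: int, ref_base: str, alt_base: str
) -> ConsequenceCall:
    """Consequence of substituting ``ref_base``→``alt_base`` at CDS position ``c_pos``.

    The stated reference base must match the transcript's coding sequence;
    a disagreement raises :class:`ReferenceMismatchError` carrying both bases.
    """
    if not 1 <= c_pos <= tm.cds_len:
        raise NonCodingPositionError(f"c.{c_pos} outside CDS of {tm.gene}")
    observed = tm.cds_seq[c_pos - 1]
    if observed != ref_base:
        raise ReferenceMismatchError(observed, ref_base, c_pos)
    codon_index, offset = codon_of(c_pos)
    codon_start = (codon_index - 1) * 3
    ref_codon = tm.cds_seq[codon_start : codon_start + 3]
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = _aa3(ref_codon)
    alt_aa = _aa3(alt_codon)
    if ref_aa == alt_aa:
        klass = "synonymous"
    elif codon_index == 1 and alt_codon != "ATG":
        klass = "start-lost"
    elif alt_aa == "Ter":
        klass = "nonsense"
    else:
        klass = "missense"
    return ConsequenceCall(
        gene=tm.gene,
        c_pos=c_pos,
        ref_base=ref_base,
        alt_base=alt_base,
        codon_index=codon_index,
        within_codon_offset=offset,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        klass=klass,
    )


def annotate_variant(variant_chrom: str, pos: int, ref: str, alt: str,
                     tm: TranscriptModel) -> ConsequenceCall:
    """Consequence of a genomic SNV against a transcript.

    Alleles are given on the forward genomic strand and are complemented for
    minus-strand transcripts before codon translation.
    """
    if variant_chrom != tm.chrom:
        raise NonCodingPositionError(
            f"variant chromosome {variant_chrom} != transcript {tm.gene} on {tm.chrom}"
        )
    if len(ref) != 1 or len(alt) != 1:
        raise TrioPriorError("only single-nucleotide substitutions are supported")
    c_pos = genomic_to_cdna(pos, tm)
    if tm.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return translate_substitution(tm, c_pos, ref, alt)


_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


def format_hgvs(call: ConsequenceCall) -> Tuple[str, str]:
    """(hgvs_c, hgvs_p) strings for a consequence call."""
    return call.hgvs_c, call.hgvs_p


def parse_hgvs_c(text: str) -> Tuple[int, str, str]:
    """Parse ``c.<pos><ref>><alt>`` into (c_pos, ref, alt).

    Round-trips with :func:`format_hgvs` for every valid substitution.
    """
    m = _HGVS_C.match(text.strip())
    if m is None:
        for i, (a, b) in enumerate(zip(text, "c.")):
            if a != b:
                break
        else:
            i = min(len(text), 2)
        raise HgvsParseError(f"malformed HGVS c. substitution {text!r} (near index {i})")
    return int(m.group(1)), m.group(2), m.group(3)


def conservation_fraction(alignment, column_index: int) -> float:
    """Cross-species conservation of one reference residue.

    ``alignment`` is a Biopython multiple alignment whose first row is the
    reference protein; ``column_index`` is 1-based over the *residues* of the
    reference row (gaps in the reference do not count).  Returns the fraction
    of non-reference rows whose residue at that alignment column equals the
    reference residue; gaps count as mismatches.
    """
    if len(alignment) < 2:
        raise TrioPriorError("no comparison rows in alignment")
    ref = str(alignment[0].seq)
    if column_index < 1:
        raise TrioPriorError(f"column_index must be >= 1, got {column_index}")
    seen = 0
    col = None
    for i, ch in enumerate(ref):
        if ch != "-":
            seen += 1
            if seen == column_index:
                col = i
                break
    if col is None:
        raise TrioPriorError(
            f"column_index {column_index} beyond the {seen} residues of the reference row"
        )
    ref_res = ref[col]
    others = [str(rec.seq)[col] for rec in alignment[1:]]
    return sum(1 for r in others if r == ref_res) / len(others)


def alignment_offset(record_id: str) -> int:
    """Protein start coordinate encoded in a ``name/start-end`` FASTA id.

    Alignment fixtures cover a window of the protein; the reference row id
    carries the window start so codon indices can be mapped onto alignment
    columns.  Ids without the ``/start-end`` suffix start at residue 1.
    """
    m = re.search(r"/(\d+)-(\d+)$", record_id)
    return int(m.group(1)) if m else 1


def conservation_at_codon(alignment, codon_index: int) -> Optional[float]:
    """Conservation fraction at a protein residue, or None if outside the window."""
    start = alignment_offset(alignment[0].id)
    column = codon_index - start + 1
    ref_len = sum(1 for ch in str(alignment[0].seq) if ch != "-")
    if not 1 <= column <= ref_len:
        return None
    return conservation_fraction(alignment, column)
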