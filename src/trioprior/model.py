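"""Domain types for the prioritization cascade.

A ``Variant`` is one normalized bi-allelic call with per-sample genotypes;
alleles are coded ``0`` (reference), ``1`` (alternate) or ``None`` (missing).
Multi-allelic VCF records are split into one ``Variant`` per alternate allele
at read time, so exactly one ``alt`` flows through the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .exceptions import InputFormatError, PedigreeError

#: unphased allele pair; 0 = ref, 1 = alt, None = missing
Genotype = Tuple[Optional[int], Optional[int]]

_BASES = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One normalized variant record (single alternate allele)."""

    chrom: str
    pos: int  # 1-based genomic coordinate
    ref: str
    alt: str
    vid: str = "novel"  # rs number or "novel"
    genotypes: Dict[str, Genotype] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"variant position must be >= 1, got {self.pos}")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= _BASES:
                raise InputFormatError(
                    f"{label} allele must be non-empty uppercase A/C/G/T, got {allele!r}"
                )

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def alt_count(self, sample: str) -> Optional[int]:
        """Number of alt alleles carried by *sample*; None if any allele missing."""
        gt = self.genotypes[sample]
        if gt[0] is None or gt[1] is None:
            return None
        return gt[0] + gt[1]


@dataclass(frozen=True)
class PedSample:
    sid: str
    father: Optional[str]
    mother: Optional[str]
    sex: int  # 1 male, 2 female, 0 unknown
    affected: Optional[bool]  # True affected, False unaffected, None unknown


@dataclass
class Pedigree:
    """Samples with parent links and affection status."""

    samples: List[PedSample]

    def __post_init__(self) -> None:
        ids = [s.sid for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate sample id(s): {', '.join(dup)}")
        known = set(ids)
        for s in self.samples:
            for parent in (s.father, s.mother):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"parent id {parent!r} of sample {s.sid!r} not in pedigree"
                    )

    @property
    def sample_ids(self) -> List[str]:
        return [s.sid for s in self.samples]

    @property
    def affected_ids(self) -> List[str]:
        return [s.sid for s in self.samples if s.affected is True]

    @property
    def unaffected_ids(self) -> List[str]:
        return [s.sid for s in self.samples if s.affected is False]

    def require_informative(self) -> None:
        """The dominant co-segregation filter needs both affection classes."""
        if not self.affected_ids:
            raise PedigreeError("pedigree has no affected samples; filter undefined")
        if not self.unaffected_ids:
            raise PedigreeError("pedigree has no unaffected samples; filter undefined")


@dataclass(frozen=True)
class PanelRegion:
    gene: str
    chrom: str
    start: int  # 0-based inclusive (BED)
    end: int  # 0-based exclusive (BED)


@dataclass
class GenePanel:
    """Candidate-gene panel as half-open BED intervals, one region per gene."""

    regions: List[PanelRegion]

    def __post_init__(self) -> None:
        genes = [r.gene for r in self.regions]
        if len(genes) != len(set(genes)):
            raise InputFormatError("panel gene symbols must be unique")
        for r in self.regions:
            if r.start >= r.end:
                raise InputFormatError(
                    f"panel region {r.gene}: start {r.start} >= end {r.end}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        """Gene whose region contains the 1-based position, else None."""
        for r in self.regions:
            if r.chrom == chrom and r.start < pos <= r.end:
                return r.gene
        return None


@dataclass
class FrequencyTable:
    """Population allele counts keyed by (chrom, pos, ref, alt), EVS-style."""

    entries: Dict[Tuple[str, int, str, str], Tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (ac, an) in self.entries.items():
            if an <= 0 or ac < 0 or ac > an:
                raise InputFormatError(
                    f"invalid allele counts {ac}/{an} for {key[0]}:{key[1]}"
                )

    def maf(self, variant: Variant) -> Optional[float]:
        """Minor allele frequency, or None when the variant is absent (novel)."""
        counts = self.entries.get(variant.key)
        if counts is None:
            return None
        ac, an = counts
        p = ac / an
        return min(p, 1.0 - p)


@dataclass(frozen=True)
class PredictorScores:
    """External in-silico predictor scores for one variant; any field may be absent."""

    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    pmut_nn: Optional[float] = None
    pmut_reliability: Optional[int] = None
    panther_subpsec: Optional[float] = None
    panther_pdel: Optional[float] = None
    ponp2_prob: Optional[float] = None
    ponp2_se: Optional[float] = None
    mutpred_prob: Optional[float] = None

    _UNIT = ("sift", "polyphen2", "pmut_nn", "panther_pdel", "ponp2_prob", "mutpred_prob")

    def __post_init__(self) -> None:
        for name in self._UNIT:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InputFormatError(f"{name} must lie in [0,1], got {v}")
        if self.panther_subpsec is not None and self.panther_subpsec > 0:
            raise InputFormatError("panther_subpsec must be <= 0")
        if self.ponp2_se is not None and self.ponp2_se < 0:
            raise InputFormatError("ponp2_se must be >= 0")
        if self.pmut_reliability is not None and not 0 <= self.pmut_reliability <= 9:
            raise InputFormatError("pmut_reliability must be in 0..9")

    def present(self) -> Dict[str, float]:
        return {
            name: getattr(self, name)
            for name in (
                "sift", "polyphen2", "pmut_nn", "pmut_reliability", "panther_subpsec",
                "panther_pdel", "ponp2_prob", "ponp2_se", "mutpred_prob",
            )
            if getattr(self, name) is not None
        }


@dataclass
class FilterConfig:
    """Cascade configuration.

    maf_threshold reads the "MAF > 0.01%" exclusion rule literally: variants
    strictly above it are excluded, a MAF exactly at the threshold is kept.
    """

    maf_threshold: float = 1e-4
    model: str = "dominant"
    missing_policy: str = "strict"  # strict: missing genotype fails the variant

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise InputFormatError("maf_threshold must lie in [0,1]")
        if self.model != "dominant":
            raise InputFormatError("only the dominant model is implemented")
        if self.missing_policy not in ("strict", "lenient"):
            raise InputFormatError("missing_policy must be 'strict' or 'lenient'")


def maf_from_counts(ac: int, an: int) -> float:
    """Minor allele frequency from alt/total allele counts."""
    p = ac / an
    return min(p, 1.0 - p)


def hardy_weinberg_genotype_probs(maf: float) -> Tuple[float, float, float]:
    """(hom-ref, het, hom-alt) probabilities at Hardy–Weinberg equilibrium."""
    q = maf
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def binomial_se(p: float, n: int) -> float:
    """Standard error of a proportion estimate."""
    return math.sqrt(p * (1.0 - p) / n)
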