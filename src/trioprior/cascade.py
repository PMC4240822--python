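"""The prioritization cascade: panel → co-segregation → frequency → review.

Each stage is a pure function of its inputs, so the three hard filters
commute; :func:`prioritize` evaluates all stages for every variant and
records the outcome in an auditable :class:`PrioritizationTrail`.  The
consequence, conservation and predictor stages are advisory annotations
only — they never change the candidate/excluded verdict, mirroring a
workflow in which a recurrent mutation is retained as the causal candidate
even when in-silico tools score it benign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .consequence import ConsequenceCall, annotate_variant, conservation_at_codon
from .exceptions import NoScoresError, TrioPriorError
from .model import (
    FilterConfig,
    FrequencyTable,
    GenePanel,
    Pedigree,
    PredictorScores,
    Variant,
    hardy_weinberg_genotype_probs,
)

VariantKey = Tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# Stage filters

def panel_filter(
    variants: Sequence[Variant], panel: GenePanel
) -> Tuple[List[Tuple[Variant, str]], Tuple[int, int]]:
    """Variants falling in a panel region, annotated with the gene symbol.

    Returns the retained (variant, gene) pairs and a summary
    (n_variants, n_genes_hit).
    """
    hits: List[Tuple[Variant, str]] = []
    for v in variants:
        gene = panel.gene_at(v.chrom, v.pos)
        if gene is not None:
            hits.append((v, gene))
    genes = {g for _, g in hits}
    return hits, (len(hits), len(genes))


def segregates_dominant(
    variant: Variant, ped: Pedigree, cfg: FilterConfig
) -> Tuple[bool, Optional[str]]:
    """Fully-penetrant dominant co-segregation test for one variant.

    Passes iff every affected sample carries at least one alt allele and
    every unaffected sample carries none; unknown-status samples are
    ignored.  Under the strict missing-genotype policy a missing genotype in
    any consulted sample fails the variant; under lenient that sample is
    skipped.  Returns (verdict, failing sample id or None).
    """
    ped.require_informative()
    for sid in ped.affected_ids:
        n = variant.alt_count(sid)
        if n is None:
            if cfg.missing_policy == "strict":
                return False, sid
            continue
        if n == 0:
            return False, sid
    for sid in ped.unaffected_ids:
        n = variant.alt_count(sid)
        if n is None:
            if cfg.missing_policy == "strict":
                return False, sid
            continue
        if n > 0:
            return False, sid
    return True, None


def segregation_filter(
    variants: Sequence[Variant], ped: Pedigree, cfg: Optional[FilterConfig] = None
) -> List[Variant]:
    cfg = cfg or FilterConfig()
    return [v for v in variants if segregates_dominant(v, ped, cfg)[0]]


def frequency_filter(
    variants: Sequence[Variant], freqs: FrequencyTable, cfg: Optional[FilterConfig] = None
) -> List[Variant]:
    """Exclude variants whose population MAF exceeds the threshold.

    Variants absent from the table are treated as novel (MAF 0) and
    retained; the rule is strictly greater-than, so a MAF exactly at the
    threshold is kept.
    """
    cfg = cfg or FilterConfig()
    kept = []
    for v in variants:
        maf = freqs.maf(v)
        if maf is None or maf <= cfg.maf_threshold:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# Predictor-score classification

#: PolyPhen-2 category cutpoints (probably-damaging / possibly-damaging floor)
POLYPHEN2_CUTPOINTS = (0.453, 0.957)


def classify_predictions(
    scores: PredictorScores,
    polyphen2_cutpoints: Tuple[float, float] = POLYPHEN2_CUTPOINTS,
) -> Dict[str, object]:
    """Per-tool verdicts from published decision thresholds.

    SIFT: not tolerated iff score < 0.05 (strict).  PolyPhen-2: benign /
    possibly damaging / probably damaging by the configured cutpoints.
    PMUT: pathological iff NN output > 0.5.  PANTHER: deleterious iff
    subPSEC < −3 (P_deleterious > 0.5 concordance reported alongside).
    PON-P2: pathogenic / neutral when probability ± SE clears 0.5, unknown
    when the interval straddles it.  MutPred: deleterious iff probability
    > 0.5.  ``damaging_count`` totals the tools voting damaging.
    """
    if not scores.present():
        raise NoScoresError("no predictor scores present for this variant")
    verdicts: Dict[str, object] = {}
    damaging = 0

    if scores.sift is not None:
        hit = scores.sift < 0.05
        verdicts["sift"] = "not tolerated" if hit else "tolerated"
        damaging += hit
    if scores.polyphen2 is not None:
        lo, hi = polyphen2_cutpoints
        if scores.polyphen2 >= hi:
            verdicts["polyphen2"] = "probably damaging"
            damaging += 1
        elif scores.polyphen2 >= lo:
            verdicts["polyphen2"] = "possibly damaging"
            damaging += 1
        else:
            verdicts["polyphen2"] = "benign"
    if scores.pmut_nn is not None:
        hit = scores.pmut_nn > 0.5
        verdicts["pmut"] = "pathological" if hit else "neutral"
        damaging += hit
    if scores.panther_subpsec is not None:
        hit = scores.panther_subpsec < -3.0
        verdicts["panther"] = "deleterious" if hit else "neutral"
        damaging += hit
        if scores.panther_pdel is not None:
            verdicts["panther_pdel_concordant"] = (scores.panther_pdel > 0.5) == hit
    if scores.ponp2_prob is not None:
        se = scores.ponp2_se or 0.0
        if scores.ponp2_prob - se > 0.5:
            verdicts["ponp2"] = "pathogenic"
            damaging += 1
        elif scores.ponp2_prob + se < 0.5:
            verdicts["ponp2"] = "neutral"
        else:
            verdicts["ponp2"] = "unknown"
    if scores.mutpred_prob is not None:
        hit = scores.mutpred_prob > 0.5
        verdicts["mutpred"] = "deleterious" if hit else "neutral"
        damaging += hit

    verdicts["damaging_count"] = int(damaging)
    return verdicts


# ---------------------------------------------------------------------------
# Trails and the end-to-end cascade

@dataclass
class PrioritizationTrail:
    """Auditable per-variant record of every cascade stage."""

    variant: Variant
    gene: Optional[str] = None
    in_panel: bool = False
    segregates: bool = False
    failing_sample: Optional[str] = None
    maf: Optional[float] = None  # None == novel (absent from the table)
    passes_frequency: bool = False
    consequence: Optional[ConsequenceCall] = None
    conservation: Optional[float] = None
    predictions: Dict[str, object] = field(default_factory=dict)
    final: str = "excluded"
    exclusion_reason: Optional[str] = None

    @property
    def damaging_count(self) -> int:
        return int(self.predictions.get("damaging_count", 0))

    @property
    def maf_display(self) -> str:
        return "novel" if self.maf is None else f"{self.maf:.6g}"


def prioritize(
    variants: Sequence[Variant],
    ped: Pedigree,
    panel: GenePanel,
    freqs: FrequencyTable,
    transcripts: Optional[Dict[str, object]] = None,
    scores: Optional[Dict[VariantKey, PredictorScores]] = None,
    alignments: Optional[Dict[str, list]] = None,
    cfg: Optional[FilterConfig] = None,
) -> List[PrioritizationTrail]:
    """Run the full cascade and return one trail per input variant.

    Candidates (in panel ∧ co-segregating ∧ rare) sort first, ordered by
    damaging-score count (desc), then MAF (asc, novel = 0), then genomic
    coordinate; excluded variants follow in coordinate order with the first
    failed stage as the exclusion reason.  Consequence, conservation and
    prediction stages are annotations and are skipped per variant when their
    inputs are unavailable.
    """
    cfg = cfg or FilterConfig()
    ped.require_informative()
    transcripts = transcripts or {}
    scores = scores or {}
    alignments = alignments or {}

    trails: List[PrioritizationTrail] = []
    for v in variants:
        t = PrioritizationTrail(variant=v)
        t.gene = panel.gene_at(v.chrom, v.pos)
        t.in_panel = t.gene is not None
        t.segregates, t.failing_sample = segregates_dominant(v, ped, cfg)
        t.maf = freqs.maf(v)
        t.passes_frequency = t.maf is None or t.maf <= cfg.maf_threshold

        if t.in_panel and t.gene in transcripts and len(v.ref) == len(v.alt) == 1:
            try:
                t.consequence = annotate_variant(
                    v.chrom, v.pos, v.ref, v.alt, transcripts[t.gene]
                )
            except TrioPriorError:
                t.consequence = None  # non-coding or mismatching: annotation skipped
        if t.consequence is not None and t.gene in alignments:
            for aln in alignments[t.gene]:
                frac = conservation_at_codon(aln, t.consequence.codon_index)
                if frac is not None:
                    t.conservation = frac
                    break
        if v.key in scores:
            t.predictions = classify_predictions(scores[v.key])

        if t.in_panel and t.segregates and t.passes_frequency:
            t.final = "candidate"
        else:
            t.final = "excluded"
            if not t.in_panel:
                t.exclusion_reason = "not in panel"
            elif not t.segregates:
                t.exclusion_reason = (
                    f"does not co-segregate (sample {t.failing_sample})"
                )
            else:
                t.exclusion_reason = f"population MAF {t.maf_display} > threshold"
        trails.append(t)

    def sort_key(t: PrioritizationTrail):
        if t.final == "candidate":
            return (0, -t.damaging_count, t.maf or 0.0, t.variant.chrom, t.variant.pos)
        return (1, 0, 0.0, t.variant.chrom, t.variant.pos)

    trails.sort(key=sort_key)
    return trails


def stage_counts(trails: Sequence[PrioritizationTrail], panel: GenePanel
                 ) -> Dict[str, object]:
    """Per-stage summary in the "N variants in M of 39 genes" style."""
    in_panel = [t for t in trails if t.in_panel]
    seg = [t for t in in_panel if t.segregates]
    rare = [t for t in seg if t.passes_frequency]
    return {
        "n_input": len(trails),
        "n_in_panel": len(in_panel),
        "n_genes_hit": len({t.gene for t in in_panel}),
        "panel_size": len(panel),
        "n_cosegregating": len(seg),
        "n_candidates": len(rare),
    }


# ---------------------------------------------------------------------------
# Closed-form chance co-segregation

def chance_cosegregation_prob(maf: float, ped: Pedigree) -> float:
    """Probability that a background variant co-segregates by chance.

    Treats every sample as an independent Hardy–Weinberg draw at the given
    population MAF: each affected must be a carrier, each unaffected a
    non-carrier.  Ignoring within-family transmission makes this an
    approximation, but it preserves the key ordering — more informative
    samples give a strictly smaller chance rate.
    """
    hom_ref, het, hom_alt = hardy_weinberg_genotype_probs(maf)
    carrier = het + hom_alt
    prob = 1.0
    for _ in ped.affected_ids:
        prob *= carrier
    for _ in ped.unaffected_ids:
        prob *= hom_ref
    return prob
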