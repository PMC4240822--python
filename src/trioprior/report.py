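"""Human-readable and machine-readable per-family reports.

The candidate summary mirrors the layout of a mutation table (pedigree,
physical location, gene, cDNA and protein variant, population allele
frequency, Novel/Recurrent status), the prediction grid mirrors a per-tool
in-silico verdict table, and the markdown report carries the per-stage
filter-trail counts ("N variants in M of 39 candidate genes").
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .cascade import PrioritizationTrail, stage_counts
from .model import GenePanel

_TRAIL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vid", "gene", "in_panel", "segregates",
    "failing_sample", "maf", "passes_frequency", "hgvs_c", "hgvs_p",
    "consequence_class", "conservation", "damaging_count", "status", "final",
    "exclusion_reason",
]


def variant_status(gene: Optional[str], hgvs_c: Optional[str],
                   hgvs_p: Optional[str], known: pd.DataFrame) -> str:
    """Novel/Recurrent lookup against the editable known-mutation list."""
    if gene is None:
        return "Novel"
    rows = known[known["gene"] == gene]
    for _, row in rows.iterrows():
        if hgvs_c and isinstance(row.get("hgvs_c"), str) and row["hgvs_c"] == hgvs_c:
            return "Recurrent"
        if hgvs_p and isinstance(row.get("hgvs_p"), str) and row["hgvs_p"] == hgvs_p:
            return "Recurrent"
    return "Novel"


def trail_row(t: PrioritizationTrail, known: Optional[pd.DataFrame] = None) -> Dict:
    c = t.consequence
    hgvs_c = c.hgvs_c if c else None
    hgvs_p = c.hgvs_p if c else None
    status = variant_status(t.gene, hgvs_c, hgvs_p, known) if known is not None else None
    return {
        "chrom": t.variant.chrom,
        "pos": t.variant.pos,
        "ref": t.variant.ref,
        "alt": t.variant.alt,
        "vid": t.variant.vid,
        "gene": t.gene,
        "in_panel": t.in_panel,
        "segregates": t.segregates,
        "failing_sample": t.failing_sample,
        "maf": t.maf_display,
        "passes_frequency": t.passes_frequency,
        "hgvs_c": hgvs_c,
        "hgvs_p": hgvs_p,
        "consequence_class": c.klass if c else None,
        "conservation": t.conservation,
        "damaging_count": t.damaging_count,
        "status": status,
        "final": t.final,
        "exclusion_reason": t.exclusion_reason,
    }


def trails_to_frame(trails: Sequence[PrioritizationTrail],
                    known: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    rows = [trail_row(t, known) for t in trails]
    return pd.DataFrame(rows, columns=_TRAIL_COLUMNS)


def trails_to_json(trails: Sequence[PrioritizationTrail],
                   known: Optional[pd.DataFrame] = None) -> str:
    payload = []
    for t in trails:
        row = trail_row(t, known)
        row["predictions"] = t.predictions
        payload.append(row)
    return json.dumps(payload, indent=2, default=str) + "\n"


def candidate_table(trails: Sequence[PrioritizationTrail],
                    known: pd.DataFrame) -> pd.DataFrame:
    """Mutation-summary table for the final candidates."""
    rows = []
    for t in trails:
        if t.final != "candidate":
            continue
        r = trail_row(t, known)
        rows.append(
            {
                "location": f"{r['chrom']}:{r['pos']:,}",
                "gene": r["gene"],
                "cDNA variant": r["hgvs_c"],
                "protein variant": r["hgvs_p"],
                "allele frequency": r["maf"],
                "status": r["status"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["location", "gene", "cDNA variant", "protein variant",
                 "allele frequency", "status"],
    )


def prediction_grid(trails: Sequence[PrioritizationTrail]) -> pd.DataFrame:
    """Per-tool verdict grid (tools as rows, candidate variants as columns)."""
    cols = {}
    for t in trails:
        if not t.predictions:
            continue
        label = t.consequence.hgvs_c if t.consequence else f"{t.variant.chrom}:{t.variant.pos}"
        if t.gene:
            label = f"{t.gene} {label}"
        cols[label] = {
            k: v for k, v in t.predictions.items() if k != "damaging_count"
        } | {"damaging_count": t.predictions.get("damaging_count")}
    return pd.DataFrame(cols)


def render_markdown(trails: Sequence[PrioritizationTrail], panel: GenePanel,
                    known: pd.DataFrame) -> str:
    """Markdown per-family report: stage counts, candidates, predictions."""
    counts = stage_counts(trails, panel)
    lines = ["# Variant prioritization report", ""]
    lines.append(
        f"{counts['n_in_panel']} variants in {counts['n_genes_hit']} of "
        f"{counts['panel_size']} candidate genes"
    )
    lines.append("")
    lines.append(
        f"- input variants: {counts['n_input']}\n"
        f"- in panel: {counts['n_in_panel']}\n"
        f"- co-segregating with disease: {counts['n_cosegregating']}\n"
        f"- rare (passing the MAF filter): {counts['n_candidates']}"
    )
    lines.append("")
    cand = candidate_table(trails, known)
    lines.append("## Candidates")
    lines.append("")
    if cand.empty:
        lines.append("No candidate variants survived the cascade.")
    else:
        lines.append(cand.to_markdown(index=False))
    grid = prediction_grid(trails)
    if not grid.empty:
        lines += ["", "## In-silico predictions", "", grid.to_markdown()]
    lines.append("")
    return "\n".join(lines)
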