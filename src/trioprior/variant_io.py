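"""Readers and writers for the cascade's standard-format inputs.

VCF handling goes through pysam; alignments through Biopython; tabular inputs
through pandas.  Coordinate dialects follow the standards: VCF and all
``Variant`` positions are 1-based, BED intervals half-open 0-based, converted
here at the boundary.  Only PASS/"." VCF records enter the cascade (the
variant set this pipeline consumes is post-calling); missing genotypes are
kept at read time and handled by the segregation filter's policy.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import pysam
from Bio import AlignIO

from .consequence import TranscriptModel
from .exceptions import InputFormatError, MissingSampleError, PedigreeError
from .model import (
    FrequencyTable,
    GenePanel,
    Genotype,
    PanelRegion,
    PedSample,
    Pedigree,
    PredictorScores,
    Variant,
)

_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str, pedigree: Optional[Pedigree] = None) -> List[Variant]:
    """Read a multi-sample VCF into normalized bi-allelic ``Variant`` records.

    Multi-allelic records are split into one ``Variant`` per alternate allele;
    genotypes are recoded against the retained alt (alleles of other alts are
    coded as reference).  Records with a FILTER other than PASS/"." are
    dropped.  Every pedigree sample must appear in the VCF header; a record
    whose genotypes cannot be parsed is dropped with a warning.  Without a
    pedigree only sites are read (no genotypes), the mode used by
    consequence-only annotation.
    """
    sample_ids = pedigree.sample_ids if pedigree is not None else []
    variants: List[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = set(vcf.header.samples)
        for sid in sample_ids:
            if sid not in vcf_samples:
                raise MissingSampleError(
                    f"pedigree sample {sid!r} missing from VCF header"
                )
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            try:
                raw_gts = {
                    sid: tuple(rec.samples[sid].get("GT") or (None, None))
                    for sid in sample_ids
                }
            except Exception as exc:  # malformed genotype field
                warnings.warn(
                    f"dropping {rec.chrom}:{rec.pos}: malformed genotype ({exc})"
                )
                continue
            if any(len(gt) != 2 for gt in raw_gts.values()):
                warnings.warn(
                    f"dropping {rec.chrom}:{rec.pos}: non-diploid genotype"
                )
                continue
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                if not alt or not set(alt) <= _BASES:
                    warnings.warn(
                        f"dropping {rec.chrom}:{rec.pos} alt {alt!r}: not a sequence allele"
                    )
                    continue
                genotypes: Dict[str, Genotype] = {}
                for sid, gt in raw_gts.items():
                    genotypes[sid] = tuple(
                        None if a is None else (1 if a == alt_idx else 0) for a in gt
                    )  # type: ignore[assignment]
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        vid=rec.id or "novel",
                        genotypes=genotypes,
                    )
                )
    return variants


def write_vcf(variants: Iterable[Variant], sample_ids: List[str], path: str) -> None:
    """Write variants back out as an uncompressed multi-sample VCF 4.2."""
    header = pysam.VariantHeader()
    header.add_line("##source=trioprior")
    header.formats.add("GT", 1, "String", "Genotype")
    variants = list(variants)
    seen: List[str] = []
    for v in variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        header.contigs.add(chrom, length=536870912)
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                id=None if v.vid == "novel" else v.vid,
                filter="PASS",
            )
            for sid in sample_ids:
                gt = v.genotypes.get(sid, (None, None))
                rec.samples[sid]["GT"] = gt
                rec.samples[sid].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# PED

_AFFECTION = {"2": True, "1": False, "0": None, "-9": None}


def read_ped(path: str) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Affection coding: 2 → affected, 1 → unaffected, 0/−9 → unknown.
    """
    samples: List[PedSample] = []
    lines = Path(path).read_text().splitlines()
    rows = [ln.split() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise PedigreeError(f"PED file {path} is empty")
    for row in rows:
        if len(row) < 6:
            raise PedigreeError(f"PED row has {len(row)} columns, expected 6: {row}")
        _fam, sid, father, mother, sex, pheno = row[:6]
        if pheno not in _AFFECTION:
            raise PedigreeError(f"unknown affection code {pheno!r} for sample {sid}")
        samples.append(
            PedSample(
                sid=sid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
                affected=_AFFECTION[pheno],
            )
        )
    return Pedigree(samples)


def write_ped(ped: Pedigree, path: str, family_id: str = "FAM1") -> None:
    rows = []
    for s in ped.samples:
        pheno = {True: "2", False: "1", None: "0"}[s.affected]
        rows.append(
            f"{family_id}\t{s.sid}\t{s.father or 0}\t{s.mother or 0}\t{s.sex}\t{pheno}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# BED panel

def read_panel(path: str) -> GenePanel:
    """Read a BED4+ candidate-gene panel (0-based half-open intervals)."""
    regions: List[PanelRegion] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        cols = ln.split()
        if len(cols) < 4:
            raise InputFormatError(f"BED line needs >= 4 columns: {ln!r}")
        chrom, start, end, gene = cols[0], int(cols[1]), int(cols[2]), cols[3]
        if start >= end:
            raise InputFormatError(f"BED region {gene}: start {start} >= end {end}")
        regions.append(PanelRegion(gene=gene, chrom=chrom, start=start, end=end))
    return GenePanel(regions)


# ---------------------------------------------------------------------------
# Frequency table

def parse_count_pair(text: str) -> Tuple[int, int]:
    """Parse an EVS-style ``alt/total`` allele-count cell such as ``0/8,600``."""
    parts = str(text).replace(",", "").split("/")
    if len(parts) != 2:
        raise InputFormatError(f"cannot parse allele-count cell {text!r}")
    ac, an = int(parts[0]), int(parts[1])
    if an <= 0 or ac < 0:
        raise InputFormatError(f"invalid allele counts in {text!r}")
    if ac > an:
        raise InputFormatError(f"alt count {ac} exceeds total {an}")
    return ac, an


def _parse_int(cell) -> int:
    return int(str(cell).replace(",", ""))


def read_frequencies(path: str) -> FrequencyTable:
    """Read a TSV of population allele counts (chrom, pos, ref, alt, ac, an).

    ``ac``/``an`` cells accept thousands separators; alternatively a single
    ``counts`` column holds ``alt/total`` pairs like ``0/8,600``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise InputFormatError(
            f"frequency TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    entries: Dict[Tuple[str, int, str, str], Tuple[int, int]] = {}
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if "counts" in df.columns and pd.notna(row.get("counts")):
            ac, an = parse_count_pair(row["counts"])
        elif {"ac", "an"} <= set(df.columns):
            ac, an = _parse_int(row["ac"]), _parse_int(row["an"])
            if ac > an:
                raise InputFormatError(f"alt count {ac} exceeds total {an} at {key}")
        else:
            raise InputFormatError("frequency TSV needs 'ac'+'an' or 'counts' columns")
        entries[key] = (ac, an)
    return FrequencyTable(entries)


def write_frequencies(table: FrequencyTable, path: str) -> None:
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "ac": ac, "an": an}
        for (c, p, r, a), (ac, an) in table.entries.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Predictor scores

_SCORE_FIELDS = (
    "sift", "polyphen2", "pmut_nn", "pmut_reliability", "panther_subpsec",
    "panther_pdel", "ponp2_prob", "ponp2_se", "mutpred_prob",
)


def read_scores(path: str) -> Dict[Tuple[str, int, str, str], PredictorScores]:
    """Read per-variant external predictor scores keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise InputFormatError(
            f"score TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: Dict[Tuple[str, int, str, str], PredictorScores] = {}
    for _, row in df.iterrows():
        kwargs = {}
        for field in _SCORE_FIELDS:
            if field in df.columns and pd.notna(row[field]):
                val = row[field]
                kwargs[field] = int(val) if field == "pmut_reliability" else float(val)
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        out[key] = PredictorScores(**kwargs)
    return out


# ---------------------------------------------------------------------------
# Transcript models

def read_transcripts(path: str) -> Dict[str, TranscriptModel]:
    """Read transcript models from a TSV.

    Columns: gene, chrom, strand, exons (``start-end;start-end`` in transcript
    order, 1-based inclusive), cds_start_cdna, cds_seq.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, TranscriptModel] = {}
    for _, row in df.iterrows():
        exons = []
        for span in row["exons"].split(";"):
            s, e = span.split("-")
            exons.append((int(s), int(e)))
        tm = TranscriptModel(
            gene=row["gene"],
            chrom=row["chrom"],
            strand=row["strand"],
            exons=exons,
            cds_start_cdna=int(row["cds_start_cdna"]),
            cds_seq=row["cds_seq"].upper(),
        )
        out[tm.gene] = tm
    return out


# ---------------------------------------------------------------------------
# Alignments

def read_alignment(path: str):
    """Read one aligned multi-FASTA (all rows equal length, first row = reference)."""
    aln = AlignIO.read(str(path), "fasta")
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise InputFormatError(f"alignment rows in {path} have unequal lengths")
    return aln


def read_alignments(path: str) -> Dict[str, list]:
    """Load protein alignment windows keyed by gene.

    ``path`` may be a single aligned FASTA or a directory of them.  The
    reference (first) row id encodes the gene and window as
    ``GENE/start-end``; one gene may have several windows.
    """
    p = Path(path)
    files = sorted(p.glob("*.fa")) + sorted(p.glob("*.fasta")) if p.is_dir() else [p]
    out: Dict[str, list] = {}
    for f in files:
        aln = read_alignment(str(f))
        gene = aln[0].id.split("/")[0]
        out.setdefault(gene, []).append(aln)
    return out


# ---------------------------------------------------------------------------
# Variant summary tables (supplement-style long format)

def read_variant_table(path: str) -> pd.DataFrame:
    """Read a long-format per-family variant table.

    Columns: family, gene, chrom, pos, ref, alt, vid — one row per
    (family, variant) observation, the layout of a per-trio exome review.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pos": int})
    required = {"family", "gene", "chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise InputFormatError(
            f"variant table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def tally_variant_table(df: pd.DataFrame, family: Optional[str] = None
                        ) -> Tuple[int, int]:
    """(distinct variants, distinct genes hit) over a variant table.

    With ``family`` given, restrict to that family's rows first — the
    "N variants in M of 39 genes" summary of a candidate-gene review.
    """
    if family is not None:
        df = df[df["family"] == family]
    n_variants = df.drop_duplicates(["chrom", "pos", "ref", "alt"]).shape[0]
    n_genes = df["gene"].nunique()
    return n_variants, n_genes
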