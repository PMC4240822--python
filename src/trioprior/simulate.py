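"""Synthetic family datasets with a planted dominant causal variant.

The generator emulates the statistical structure the cascade assumes: a
nuclear family (trio, or the larger four/five-member shapes), one fully
penetrant autosomal-dominant causal variant planted in a candidate-panel
gene and absent from the population frequency table, and background panel
variants whose founder genotypes are drawn from Hardy–Weinberg equilibrium
at population frequencies spanning 0–55% (a point mass at zero models the
novel fraction).  Children inherit one allele per parent uniformly at
random; optional genotyping noise flips individual alleles.  Identical
configurations (including the seed) produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import data as _data
from .cascade import FilterConfig, prioritize
from .exceptions import PedigreeError, TrioPriorError
from .model import (
    FrequencyTable,
    GenePanel,
    Genotype,
    PedSample,
    Pedigree,
    Variant,
)
from . import variant_io

_BASES = "ACGT"

#: total allele count reported in the simulated population frequency table
_TABLE_AN = 8600


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated family dataset."""

    shape: str = "trio"  # trio | family_b | family_c
    n_background: int = 100
    novel_fraction: float = 0.05  # point mass at population frequency 0
    maf_low: float = 0.004
    maf_high: float = 0.55
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("trio", "family_b", "family_c"):
            raise TrioPriorError(f"unknown pedigree shape {self.shape!r}")
        if self.n_background < 0:
            raise TrioPriorError("n_background must be >= 0")
        for p in (self.novel_fraction, self.genotype_error_rate):
            if not 0.0 <= p <= 1.0:
                raise TrioPriorError("probabilities must lie in [0,1]")


def pedigree_for_shape(shape: str) -> Pedigree:
    """Pedigree of the requested family shape.

    ``trio``: affected parent, unaffected spouse, affected child.
    ``family_b``: five samples, four affected (affected parent, three
    affected children).  ``family_c``: four samples, two affected.
    """
    if shape == "trio":
        samples = [
            PedSample("I:1", None, None, 1, False),
            PedSample("I:2", None, None, 2, True),
            PedSample("II:1", "I:1", "I:2", 1, True),
        ]
    elif shape == "family_b":
        samples = [
            PedSample("I:1", None, None, 1, True),
            PedSample("I:2", None, None, 2, False),
            PedSample("II:1", "I:1", "I:2", 1, True),
            PedSample("II:2", "I:1", "I:2", 2, True),
            PedSample("II:3", "I:1", "I:2", 2, True),
        ]
    elif shape == "family_c":
        samples = [
            PedSample("I:1", None, None, 1, True),
            PedSample("I:2", None, None, 2, False),
            PedSample("II:1", "I:1", "I:2", 1, False),
            PedSample("II:2", "I:1", "I:2", 2, True),
        ]
    else:
        raise TrioPriorError(f"unknown pedigree shape {shape!r}")
    ped = Pedigree(samples)
    if not ped.affected_ids:
        raise PedigreeError("pedigree shape has no affected samples")
    return ped


@dataclass
class SimResult:
    variants: List[Variant]
    pedigree: Pedigree
    frequencies: FrequencyTable
    truth: Dict[str, object]
    config: SimConfig = field(default=None)  # type: ignore[assignment]


def sample_founder_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n founder genotypes (alleles as an (n, 2) 0/1 array) at Hardy–Weinberg."""
    return (rng.random((n, 2)) < maf).astype(int)


def _inherit(rng: np.random.Generator, parent: Tuple[int, int]) -> int:
    return parent[int(rng.integers(2))]


def _draw_positions(
    rng: np.random.Generator, panel: GenePanel, n: int, taken: set
) -> List[Tuple[str, int, str]]:
    """n distinct (chrom, pos, gene) positions uniform over panel regions."""
    lengths = np.array([r.end - r.start for r in panel.regions], dtype=float)
    weights = lengths / lengths.sum()
    out = []
    while len(out) < n:
        r = panel.regions[int(rng.choice(len(panel.regions), p=weights))]
        pos = int(rng.integers(r.start + 1, r.end + 1))
        if (r.chrom, pos) in taken:
            continue
        taken.add((r.chrom, pos))
        out.append((r.chrom, pos, r.gene))
    return out


def _ref_alt(rng: np.random.Generator) -> Tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
    return ref, alt


def simulate_family(cfg: SimConfig, panel: Optional[GenePanel] = None) -> SimResult:
    """Simulate one family dataset under the given configuration.

    The planted causal variant is heterozygous in every affected sample,
    absent from every unaffected sample and from the frequency table; each
    affected child receives the alt allele from its affected parent, so the
    transmission is Mendelian-consistent by construction.  Background
    variants carry population frequencies from the configured mixture;
    genotyping noise, when enabled, flips each written allele independently.
    """
    panel = panel or _data.default_panel()
    rng = np.random.default_rng(cfg.seed)
    ped = pedigree_for_shape(cfg.shape)
    founders = [s for s in ped.samples if s.father is None and s.mother is None]
    children = [s for s in ped.samples if s.father is not None or s.mother is not None]

    taken: set = set()
    # the inheritance model is autosomal dominant: plant the causal variant
    # in an autosomal panel gene (background variants may fall anywhere)
    autosomes = GenePanel(
        [r for r in panel.regions if r.chrom not in ("chrX", "chrY", "X", "Y")]
    )
    causal_chrom, causal_pos, causal_gene = _draw_positions(rng, autosomes, 1, taken)[0]
    causal_ref, causal_alt = _ref_alt(rng)
    background = _draw_positions(rng, panel, cfg.n_background, taken)

    variants: List[Variant] = []
    freq_entries: Dict[Tuple[str, int, str, str], Tuple[int, int]] = {}

    # planted causal variant: dominant, fully penetrant
    genotypes: Dict[str, Genotype] = {}
    for s in founders:
        genotypes[s.sid] = (0, 1) if s.affected else (0, 0)
    for s in children:
        paternal = 1 if (s.affected and ped_sample(ped, s.father).affected) else 0
        maternal = 1 if (s.affected and ped_sample(ped, s.mother).affected) else 0
        genotypes[s.sid] = (paternal, maternal)
    variants.append(
        Variant(causal_chrom, causal_pos, causal_ref, causal_alt, "novel", genotypes)
    )

    rs = 5000001
    for chrom, pos, _gene in background:
        if rng.random() < cfg.novel_fraction:
            p_alt = 0.0
            vid = "novel"
        else:
            p_alt = float(rng.uniform(cfg.maf_low, cfg.maf_high))
            vid = f"rs{rs}"
            rs += 1
        ref, alt = _ref_alt(rng)
        gts: Dict[str, Genotype] = {}
        for s in founders:
            a = sample_founder_genotypes(p_alt, 1, rng)[0]
            gts[s.sid] = (int(a[0]), int(a[1]))
        for s in children:
            gts[s.sid] = (
                _inherit(rng, gts[s.father]),
                _inherit(rng, gts[s.mother]),
            )
        if vid != "novel":
            ac = int(round(p_alt * _TABLE_AN))
            freq_entries[(chrom, pos, ref, alt)] = (ac, _TABLE_AN)
        variants.append(Variant(chrom, pos, ref, alt, vid, gts))

    if cfg.genotype_error_rate > 0:
        noisy = []
        for v in variants:
            gts = {}
            for sid, gt in v.genotypes.items():
                gts[sid] = tuple(
                    (1 - a) if rng.random() < cfg.genotype_error_rate else a
                    for a in gt
                )
            noisy.append(dataclasses.replace(v, genotypes=gts))
        variants = noisy

    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    truth = {
        "chrom": causal_chrom,
        "pos": causal_pos,
        "ref": causal_ref,
        "alt": causal_alt,
        "gene": causal_gene,
    }
    return SimResult(variants, ped, FrequencyTable(freq_entries), truth, cfg)


def ped_sample(ped: Pedigree, sid: str) -> PedSample:
    for s in ped.samples:
        if s.sid == sid:
            return s
    raise PedigreeError(f"no sample {sid!r} in pedigree")


def mendelian_consistent(variant: Variant, ped: Pedigree) -> bool:
    """Every child genotype is producible from its parents' genotypes."""
    for s in ped.samples:
        if s.father is None and s.mother is None:
            continue
        child = variant.genotypes[s.sid]
        father = variant.genotypes[s.father]
        mother = variant.genotypes[s.mother]
        if None in child or None in father or None in mother:
            continue
        ok = any(
            sorted((a, b)) == sorted(child) for a in father for b in mother
        )
        if not ok:
            return False
    return True


def write_dataset(sim: SimResult, out_dir: str) -> Dict[str, str]:
    """Write the dataset in the dialects the readers consume; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "family.vcf"),
        "ped": str(out / "family.ped"),
        "frequencies": str(out / "frequencies.tsv"),
        "truth": str(out / "truth.json"),
    }
    variant_io.write_vcf(sim.variants, sim.pedigree.sample_ids, paths["vcf"])
    variant_io.write_ped(sim.pedigree, paths["ped"])
    variant_io.write_frequencies(sim.frequencies, paths["frequencies"])
    Path(paths["truth"]).write_text(json.dumps(sim.truth, indent=2) + "\n")
    return paths


def recovery_experiment(
    error_rates: Sequence[float],
    n_reps: int,
    base_cfg: Optional[SimConfig] = None,
    seed: int = 0,
    panel: Optional[GenePanel] = None,
    filter_cfg: Optional[FilterConfig] = None,
) -> pd.DataFrame:
    """Planted-variant recovery as a function of genotyping error rate.

    For each error rate, ``n_reps`` independent families are simulated and
    prioritized; recovery is the fraction of replicates in which the planted
    variant is among the final candidates.  Recovery is monotone
    non-increasing in the error rate up to Monte-Carlo noise.
    """
    if n_reps < 1:
        raise TrioPriorError("n_reps must be >= 1")
    base_cfg = base_cfg or SimConfig()
    panel = panel or _data.default_panel()
    seeds = np.random.SeedSequence(seed).generate_state(
        len(error_rates) * n_reps
    ) % (2**31)
    rows = []
    k = 0
    for rate in error_rates:
        hits = 0
        false_candidates = 0
        for _ in range(n_reps):
            cfg = dataclasses.replace(
                base_cfg, genotype_error_rate=float(rate), seed=int(seeds[k])
            )
            k += 1
            sim = simulate_family(cfg, panel)
            trails = prioritize(
                sim.variants, sim.pedigree, panel, sim.frequencies, cfg=filter_cfg
            )
            truth_key = (
                sim.truth["chrom"], sim.truth["pos"], sim.truth["ref"], sim.truth["alt"]
            )
            cands = {t.variant.key for t in trails if t.final == "candidate"}
            hits += truth_key in cands
            false_candidates += len(cands - {truth_key})
        rows.append(
            {
                "genotype_error_rate": float(rate),
                "recovery": hits / n_reps,
                "false_candidates_per_family": false_candidates / n_reps,
            }
        )
    return pd.DataFrame(rows)
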