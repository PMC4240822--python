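"""Access to the packaged fixtures.

Ships the 39-gene cataract candidate panel, anchored transcript models for
CRYGD and GJA8, the published predictor-score table for the three study
variants, the editable known-mutation lookup used for Novel/Recurrent
status, synthetic cross-species alignment windows, and a synthetic stand-in
for a per-family candidate-gene variant review table.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

from . import variant_io
from .consequence import TranscriptModel
from .model import GenePanel


def data_path(name: str) -> str:
    return str(resources.files("trioprior").joinpath("data", name))


def default_panel() -> GenePanel:
    """The 39-gene inherited-cataract candidate panel (BED4, hg19-style)."""
    return variant_io.read_panel(data_path("panel_39genes.bed"))


def default_transcripts() -> Dict[str, TranscriptModel]:
    """Transcript fixtures anchored to the published genomic↔cDNA pairs."""
    return variant_io.read_transcripts(data_path("transcripts.tsv"))


def default_alignments() -> Dict[str, list]:
    """Synthetic cross-species alignment windows around the study residues."""
    return variant_io.read_alignments(data_path(""))


def known_mutations() -> pd.DataFrame:
    """Editable lookup of previously reported mutations (gene, hgvs_c, hgvs_p)."""
    return pd.read_csv(data_path("known_mutations.tsv"), sep="\t", dtype=str)


def published_scores():
    """Predictor scores for the three study variants, keyed by variant."""
    return variant_io.read_scores(data_path("predictor_scores.tsv"))


def synthetic_supplement() -> pd.DataFrame:
    """Synthetic per-family variant review table (see file name: a stand-in)."""
    return variant_io.read_variant_table(
        data_path("supplement_variants_synthetic.tsv")
    )
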