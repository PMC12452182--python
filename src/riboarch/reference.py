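"""Headline totals of the genome-scale riboswitch survey these methods target.

The survey scanned the intergenic regions of 5,418 non-redundant
representative prokaryotic genomes (37 phylogenetic clades) with the 50
covariance models describing riboswitch aptamer classes, clustered into 27
ligand-based families. These totals are inputs for worked-example
arithmetic (per-gene riboswitch prevalence); the full-genome scan itself is
out of scope for this package.
"""

from __future__ import annotations

SURVEY_N_GENOMES = 5_418
SURVEY_N_CLADES = 37

#: genes across all representative genomes
SURVEY_TOTAL_GENES = 19_940_848
#: riboswitch aptamers identified across the collection
SURVEY_TOTAL_RIBOSWITCHES = 70_892

#: the same two counts restricted to Pseudomonadota
SURVEY_PSEUDOMONADOTA_GENES = 8_493_198
SURVEY_PSEUDOMONADOTA_RIBOSWITCHES = 17_605

#: contiguous riboswitch aptamers and inter-aptamer sequences with a
#: detected intrinsic terminator (tandem evidence)
SURVEY_CONTIGUOUS_RIBOSWITCHES = 2_944
SURVEY_INTERAPTAMER_SEQUENCES = 1_442
SURVEY_TERMINATOR_POSITIVE = 805


def riboswitch_prevalence_pct(n_riboswitches: int, n_genes: int) -> float:
    """Riboswitches per gene, as a percentage."""
    if n_genes <= 0:
        raise ValueError("gene count must be positive")
    return 100.0 * n_riboswitches / n_genes
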