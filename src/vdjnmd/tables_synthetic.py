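"""Synthetic reconstructions of the study's count tables.

The underlying sequencing and hybridoma counts were published only as
low-resolution images, so the exact tallies are not machine-readable.  The
tables here are *synthetic stand-ins*: counts constructed to reproduce the
summary statistics the study's text reports — 1592 junction sequences in
total, roughly two thirds PTC+ in genomic DNA, pre-mRNA fractions matching
DNA, a twelve-fold odds reduction of PTC+ mature mRNA for the intron-bearing
(A) genotype versus three-fold for the exon-fused (F) genotype, and 32% /
35% of A/A and F/F hybridomas carrying two complete VDJ rearrangements.
They exercise the same code paths real count tables would and must not be
mistaken for the original data.
"""

from __future__ import annotations

import pandas as pd

from .decay_pools import COUNT_COLUMNS

#: Sequence-pool counts (published-table shape): per genotype x molecule,
#: total sequences and PTC+/PTC- tallies.  DNA odds are 2 (two thirds PTC+);
#: mRNA odds are 1/6 (A: fold 12) and 2/3 (F: fold 3); pre-mRNA odds ~2.
#: Grand total 1592 sequences.
SEQUENCE_POOL_COUNTS = pd.DataFrame(
    [
        ("A", "dna", 300, 200, 100),
        ("A", "pre_mrna", 240, 160, 80),
        ("A", "mrna", 280, 40, 240),
        ("F", "dna", 300, 200, 100),
        ("F", "pre_mrna", 232, 155, 77),
        ("F", "mrna", 240, 96, 144),
    ],
    columns=list(COUNT_COLUMNS),
)

#: Hybridoma allele-configuration counts (published-table shape): cells with
#: one (VDJ/DJ) or two (VDJ/VDJ) complete rearrangements, set so that 32% of
#: A/A and 35% of F/F hybridomas carry two VDJ alleles.
HYBRIDOMA_CONFIG_COUNTS = pd.DataFrame(
    [
        ("A/A", "VDJ", "DJ", 68),
        ("A/A", "VDJ", "VDJ", 32),
        ("F/F", "VDJ", "DJ", 65),
        ("F/F", "VDJ", "VDJ", 35),
    ],
    columns=["genotype", "allele1_state", "allele2_state", "count"],
)
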