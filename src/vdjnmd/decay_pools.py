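"""Synthetic sequence pools under per-class decay (survival) factors.

This stage emulates the sampling step of the experiment: from a simulated
thymocyte population, junction-spanning amplicons are drawn for three
molecule classes per genotype — genomic DNA, pre-mRNA and mature mRNA.
The DNA pool accepts every sampled VDJ allele; RNA pools accept a sampled
molecule with a survival probability that depends on genotype, molecule
class and the NMD class of the allele's junction (rejected draws are
redrawn, i.e. pools sample transcripts proportional to survival).  Under
this model the expected PTC+/PTC- odds of an RNA pool equal the DNA odds
times the survival factor, so the odds-based fold reduction estimates 1/s.

Surviving cells contribute every VDJ allele they carry — the productive
allele of every cell plus the non-productive first allele of two-VDJ cells
— at a 1:1 ratio per allele, matching a population whose out-of-frame
alleles remain actively transcribed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ptc_annotate import Annotator, PTC_NEG
from .vdj_sim import ALIVE_PRODUCTIVE, VDJ, CellRecord

MOLECULES = ("dna", "pre_mrna", "mrna")

COUNT_COLUMNS = ("genotype", "molecule", "n_total", "n_ptc_pos", "n_ptc_neg")


@dataclass(frozen=True)
class SurvivalParams:
    """Per-(genotype, molecule, NMD class) survival probabilities.

    Defaults: DNA and pre-mRNA survive for every class; PTC-negative mRNA
    survives; PTC-containing mRNA survives with a per-genotype factor
    (``s_mrna_ptc``), applied to both EJC-competent and fail-safe PTCs.
    Arbitrary overrides may be supplied keyed ``(genotype, molecule,
    nmd_class)``.
    """

    s_mrna_ptc: dict[str, float] = field(default_factory=lambda: {"A": 1 / 12, "F": 1 / 3})
    overrides: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for value in list(self.s_mrna_ptc.values()) + list(self.overrides.values()):
            if not 0.0 <= value <= 1.0:
                raise ValueError("survival probabilities must lie in [0, 1]")

    def survival(self, genotype: str, molecule: str, nmd_class: str) -> float:
        if molecule not in MOLECULES:
            raise ValueError(f"unknown molecule class {molecule!r}")
        key = (genotype, molecule, nmd_class)
        if key in self.overrides:
            return self.overrides[key]
        if molecule == "mrna" and nmd_class != PTC_NEG:
            return self.s_mrna_ptc.get(genotype, 1.0)
        return 1.0

    @classmethod
    def uniform(cls) -> "SurvivalParams":
        """No decay anywhere (survival 1 for every class)."""
        return cls(s_mrna_ptc={"A": 1.0, "F": 1.0})


@dataclass
class PoolSet:
    """Sampled pools keyed by (genotype, molecule), each with its truth table."""

    pools: dict[tuple[str, str], pd.DataFrame]

    def counts(self) -> pd.DataFrame:
        """PTC+/PTC- tallies per pool, in the published count-table shape."""
        rows = []
        for (genotype, molecule), df in sorted(self.pools.items()):
            n_pos = int((df["nmd_class"] != PTC_NEG).sum())
            n_neg = int((df["nmd_class"] == PTC_NEG).sum())
            rows.append((genotype, molecule, len(df), n_pos, n_neg))
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)

    def write(self, out_dir) -> None:
        """Write one FASTA plus one truth TSV per pool."""
        os.makedirs(out_dir, exist_ok=True)
        for (genotype, molecule), df in sorted(self.pools.items()):
            stem = os.path.join(str(out_dir), f"pool_{genotype}_{molecule}")
            with open(stem + ".fasta", "w") as fh:
                for row in df.itertuples(index=False):
                    fh.write(f">{row.id}\n{row.junction_seq}\n")
            df.to_csv(stem + "_truth.tsv", sep="\t", index=False)


def _allele_table_from_cells(cells: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(cells):
        if c.fate != ALIVE_PRODUCTIVE:
            continue
        for k, a in enumerate(c.alleles):
            if a.state != VDJ:
                continue
            if a.junction is None or a.annotation is None:
                raise ValueError(
                    "pool generation needs sequence-mode cells "
                    "(junction and annotation per VDJ allele)"
                )
            rows.append((i, k, a.genotype, a.junction.junction_seq, a.annotation.nmd_class))
    return pd.DataFrame(
        rows, columns=["cell_id", "allele_index", "genotype", "junction_seq", "nmd_class"]
    )


def alive_allele_table(
    cells, annotators: dict[str, Annotator] | None = None
) -> pd.DataFrame:
    """Per-allele table of every VDJ allele carried by a surviving cell.

    Accepts a list of :class:`CellRecord` or an already-flat DataFrame with
    columns ``genotype``, ``junction_seq``, ``nmd_class``.  Missing NMD
    classes are filled by annotating the junction when annotators are given.
    """
    if isinstance(cells, pd.DataFrame):
        table = cells.copy()
        required = {"genotype", "junction_seq", "nmd_class"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"allele table missing columns: {sorted(missing)}")
    else:
        table = _allele_table_from_cells(cells)
    empty = table["nmd_class"] == ""
    if empty.any():
        if annotators is None:
            raise ValueError("allele table has unannotated junctions and no annotators")
        table.loc[empty, "nmd_class"] = [
            annotators[g].annotate_junction(s).nmd_class
            for g, s in zip(table.loc[empty, "genotype"], table.loc[empty, "junction_seq"])
        ]
    return table


def generate_pools(
    cells,
    survival: SurvivalParams,
    depth: int | dict,
    rng: np.random.Generator,
    molecules: tuple[str, ...] = MOLECULES,
    annotators: dict[str, Annotator] | None = None,
) -> PoolSet:
    """Sample DNA / pre-mRNA / mRNA pools from surviving cells.

    ``depth`` is either a single per-pool depth or a mapping keyed
    ``(genotype, molecule)``.  Sampling is with replacement; an RNA draw is
    accepted with the survival probability of its NMD class and redrawn
    otherwise.
    """
    table = alive_allele_table(cells, annotators)
    if table.empty:
        raise ValueError("no surviving VDJ alleles to sample from")
    pools: dict[tuple[str, str], pd.DataFrame] = {}
    for genotype, group in table.groupby("genotype", sort=True):
        seqs = group["junction_seq"].to_numpy()
        classes = group["nmd_class"].to_numpy()
        n = len(group)
        for molecule in molecules:
            d = depth[(genotype, molecule)] if isinstance(depth, dict) else int(depth)
            if d < 0:
                raise ValueError("pool depth must be >= 0")
            weights = np.array(
                [survival.survival(genotype, molecule, c) for c in classes]
            )
            if d > 0 and weights.max() == 0.0:
                raise ValueError(
                    f"pool ({genotype}, {molecule}): every molecule has survival 0"
                )
            chosen: list[np.ndarray] = []
            n_chosen = 0
            while n_chosen < d:
                batch = max(2 * (d - n_chosen), 64)
                idx = rng.integers(0, n, size=batch)
                keep = idx[rng.random(batch) < weights[idx]][: d - n_chosen]
                chosen.append(keep)
                n_chosen += len(keep)
            idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
            pools[(genotype, molecule)] = pd.DataFrame(
                {
                    "id": [f"{genotype}_{molecule}_{i:06d}" for i in range(d)],
                    "junction_seq": seqs[idx],
                    "nmd_class": classes[idx],
                    "cell_id": group["cell_id"].to_numpy()[idx]
                    if "cell_id" in group
                    else idx,
                }
            )
    return PoolSet(pools)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_pool(annotations: pd.DataFrame) -> tuple[int, int]:
    """(n PTC+, n PTC-) from an annotation or truth table."""
    if annotations.empty:
        raise ValueError("cannot count an empty annotation table")
    if "nmd_class" not in annotations.columns:
        raise ValueError("annotation table lacks an nmd_class column")
    n_pos = int((annotations["nmd_class"] != PTC_NEG).sum())
    return n_pos, len(annotations) - n_pos


def counts_table(annotation_sets: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-pool annotation tables into the published count-table shape."""
    if not annotation_sets:
        raise ValueError("no pools to count")
    rows = []
    for (genotype, molecule), df in sorted(annotation_sets.items()):
        if molecule not in MOLECULES:
            raise ValueError(f"unknown molecule label {molecule!r}")
        n_pos, n_neg = count_pool(df)
        rows.append((genotype, molecule, n_pos + n_neg, n_pos, n_neg))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def pool_counts(counts: pd.DataFrame, genotype: str, molecule: str) -> tuple[int, int]:
    """Extract (n PTC+, n PTC-) for one pool from a counts table."""
    sel = counts[(counts["genotype"] == genotype) & (counts["molecule"] == molecule)]
    if sel.empty:
        raise ValueError(f"counts table has no ({genotype}, {molecule}) pool")
    row = sel.iloc[0]
    return int(row["n_ptc_pos"]), int(row["n_ptc_neg"])
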