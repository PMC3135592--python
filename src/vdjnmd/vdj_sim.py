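"""V(D)J junction simulation and the allelic-exclusion developmental model.

Junction formation is imprecise: each joining end loses a geometric number
of template nucleotides and each joint gains a Poisson number of uniform
non-templated (N) bases.  The net length change mod 3 (``net_shift``)
determines the reading frame of everything downstream of the assembled
second exon; with the default distributions the net shift is uniform over
{0, 1, 2}, so two thirds of completed junctions are out of frame.

Cell fate follows sequential rearrangement with feedback (allelic
exclusion): the first allele rearranges to VDJ; if productive, the second
allele is frozen at DJ; otherwise the second allele rearranges and the cell
dies if that junction is also non-productive.  Among surviving cells the
fraction carrying two complete VDJ rearrangements is (1-p)/(2-p) for
per-junction productive probability p — 40% at p = 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import AlleleModel, GeneSegment
from .ptc_annotate import Annotator, EjcParams, PTCAnnotation

GERMLINE = "GERMLINE"
DJ = "DJ"
VDJ = "VDJ"
ALIVE_PRODUCTIVE = "ALIVE_PRODUCTIVE"
DEAD = "DEAD"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Rearrangement-simulation parameters.

    ``p_if`` is the probability that a completed junction is productive
    (abstract mode); 1/3 reflects one in-frame outcome among three equally
    likely frame shifts.  ``trim_mean`` is the mean of the geometric
    per-end trim; ``n_mean`` the mean of the Poisson N-addition length.
    """

    p_if: float = 1.0 / 3.0
    trim_mean: float = 2.0
    n_mean: float = 3.0
    n_cells: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_if <= 1.0:
            raise ValueError("p_if must lie in [0, 1]")
        if self.trim_mean < 0 or self.n_mean < 0:
            raise ValueError("trim_mean and n_mean must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


@dataclass(frozen=True)
class JunctionEvent:
    """One imprecise V(D)J joining event."""

    v_trim: int
    d5_trim: int
    d3_trim: int
    j_trim: int
    n1: str
    n2: str
    junction_seq: str
    net_shift: int


@dataclass(frozen=True)
class AlleleCall:
    """State of one allele in one cell."""

    state: str  # GERMLINE, DJ or VDJ
    genotype: str
    junction: JunctionEvent | None = None
    annotation: PTCAnnotation | None = None
    productive: bool | None = None


@dataclass(frozen=True)
class CellRecord:
    """One simulated thymocyte: two allele states and a fate."""

    alleles: tuple[AlleleCall, AlleleCall]
    fate: str
    productive_allele: int | None

    @property
    def n_vdj(self) -> int:
        return sum(a.state == VDJ for a in self.alleles)


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0, 1, ...} with the given mean."""
    if mean == 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def sample_junction(
    v: GeneSegment,
    d: GeneSegment,
    j: GeneSegment,
    params: SimParams,
    rng: np.random.Generator,
) -> JunctionEvent:
    """Draw one junction: geometric trims, Poisson N additions, uniform N bases.

    Trims that exceed the available segment length are resampled.  The
    junction sequence is trimmed-V + N1 + trimmed-D + N2 + trimmed-J and the
    net shift is its length change relative to precise joining, mod 3.
    """
    if v.kind != "V" or d.kind != "D" or j.kind != "J":
        raise ValueError("segments must be passed in V, D, J order")
    v_trim = _geometric0(rng, params.trim_mean)
    while v_trim > len(v.seq):
        v_trim = _geometric0(rng, params.trim_mean)
    j_trim = _geometric0(rng, params.trim_mean)
    while j_trim > len(j.seq):
        j_trim = _geometric0(rng, params.trim_mean)
    d5, d3 = _geometric0(rng, params.trim_mean), _geometric0(rng, params.trim_mean)
    while d5 + d3 > len(d.seq):
        d5, d3 = _geometric0(rng, params.trim_mean), _geometric0(rng, params.trim_mean)
    n1 = "".join(_BASES[rng.integers(0, 4, size=rng.poisson(params.n_mean))])
    n2 = "".join(_BASES[rng.integers(0, 4, size=rng.poisson(params.n_mean))])
    junction_seq = (
        v.seq[: len(v.seq) - v_trim]
        + n1
        + d.seq[d5: len(d.seq) - d3]
        + n2
        + j.seq[j_trim:]
    )
    reference_len = len(v.seq) + len(d.seq) + len(j.seq)
    net_shift = (len(junction_seq) - reference_len) % 3
    return JunctionEvent(v_trim, d5, d3, j_trim, n1, n2, junction_seq, net_shift)


def simulate_population(
    params: SimParams,
    rng: np.random.Generator,
    genotypes: tuple[str, str] = ("A", "A"),
    mode: str = "abstract",
    models: dict[str, AlleleModel] | None = None,
    segments: tuple[GeneSegment, GeneSegment, GeneSegment] | None = None,
    ejc_params: EjcParams | None = None,
    annotators: dict[str, Annotator] | None = None,
) -> list[CellRecord]:
    """Simulate ``params.n_cells`` cells under sequential rearrangement.

    In ``abstract`` mode productivity is a Bernoulli(p_if) draw and no
    sequences are produced.  In ``sequence`` mode each rearrangement samples
    a junction and productivity is decided by annotating the instantiated
    transcript (in-frame and stop-free up to the canonical stop).  The
    allele rearranged first is chosen uniformly at random, so heterozygous
    simulations are symmetric between genotypes.
    """
    if mode not in ("abstract", "sequence"):
        raise ValueError("mode must be 'abstract' or 'sequence'")
    if mode == "sequence":
        if models is None or segments is None:
            raise ValueError("sequence mode requires models and segments")
        if annotators is None:
            annotators = {
                g: Annotator(models[g], ejc_params) for g in set(genotypes)
            }
        v, d, j = segments

    n = params.n_cells
    first_allele = rng.integers(0, 2, size=n)
    if mode == "abstract":
        productive_draws = rng.random(size=(n, 2)) < params.p_if

    cells: list[CellRecord] = []
    for i in range(n):
        order = (int(first_allele[i]), 1 - int(first_allele[i]))
        calls: dict[int, AlleleCall] = {
            k: AlleleCall(state=DJ, genotype=genotypes[k]) for k in (0, 1)
        }
        productive_allele: int | None = None
        for attempt, k in enumerate(order):
            genotype = genotypes[k]
            if mode == "abstract":
                productive = bool(productive_draws[i, attempt])
                calls[k] = AlleleCall(
                    state=VDJ, genotype=genotype, productive=productive
                )
            else:
                event = sample_junction(v, d, j, params, rng)
                ann = annotators[genotype].annotate_junction(event.junction_seq)
                productive = ann.productive
                calls[k] = AlleleCall(
                    state=VDJ,
                    genotype=genotype,
                    junction=event,
                    annotation=ann,
                    productive=productive,
                )
            if productive:
                productive_allele = k
                break
        fate = ALIVE_PRODUCTIVE if productive_allele is not None else DEAD
        cells.append(
            CellRecord(
                alleles=(calls[0], calls[1]),
                fate=fate,
                productive_allele=productive_allele,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Configuration tallies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfigTally:
    """Allele-configuration tally among surviving cells."""

    n_alive: int
    n_one_vdj: int
    n_two_vdj: int
    pct_two_vdj: float
    single_vdj_by_genotype: dict[str, int]

    @property
    def pct_one_vdj(self) -> float:
        return 100.0 - self.pct_two_vdj


def two_vdj_fraction_expected(p_if: float) -> float:
    """Closed-form two-VDJ fraction among alive cells: (1-p)/(2-p)."""
    return (1.0 - p_if) / (2.0 - p_if)


def tally_configs(cells) -> ConfigTally:
    """Count one- vs two-VDJ configurations among surviving cells.

    Accepts a list of :class:`CellRecord` or a hybridoma-style table
    (DataFrame with columns ``genotype``, ``allele1_state``,
    ``allele2_state``, ``count``; for heterozygous rows the allele columns
    follow the order of the genotype label, e.g. ``A/F`` puts the A allele
    first).  For single-VDJ cells the tally also records which genotype
    carries the VDJ allele.
    """
    if isinstance(cells, pd.DataFrame):
        return _tally_from_table(cells)
    if not cells:
        raise ValueError("empty cell list")
    alive = [c for c in cells if c.fate == ALIVE_PRODUCTIVE]
    if not alive:
        raise ValueError("no surviving cells to tally")
    n_two = sum(c.n_vdj == 2 for c in alive)
    n_one = sum(c.n_vdj == 1 for c in alive)
    if n_one + n_two != len(alive):
        raise ValueError("surviving cell without a VDJ allele")
    by_genotype: dict[str, int] = {}
    for c in alive:
        if c.n_vdj == 1:
            g = next(a.genotype for a in c.alleles if a.state == VDJ)
            by_genotype[g] = by_genotype.get(g, 0) + 1
    return ConfigTally(
        n_alive=len(alive),
        n_one_vdj=n_one,
        n_two_vdj=n_two,
        pct_two_vdj=100.0 * n_two / len(alive),
        single_vdj_by_genotype=by_genotype,
    )


def _tally_from_table(table: pd.DataFrame) -> ConfigTally:
    required = {"genotype", "allele1_state", "allele2_state", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"configuration table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("empty configuration table")
    n_one = n_two = 0
    by_genotype: dict[str, int] = {}
    for _, row in table.iterrows():
        states = (row["allele1_state"], row["allele2_state"])
        n_vdj = sum(s == VDJ for s in states)
        count = int(row["count"])
        if count < 0:
            raise ValueError("negative count in configuration table")
        if n_vdj == 2:
            n_two += count
        elif n_vdj == 1:
            n_one += count
            allele_genotypes = str(row["genotype"]).split("/")
            if len(allele_genotypes) == 2:
                g = allele_genotypes[0 if states[0] == VDJ else 1]
            else:
                g = str(row["genotype"])
            by_genotype[g] = by_genotype.get(g, 0) + count
        else:
            raise ValueError(f"row without a VDJ allele: {dict(row)}")
    total = n_one + n_two
    if total == 0:
        raise ValueError("no VDJ-bearing rows to tally")
    return ConfigTally(
        n_alive=total,
        n_one_vdj=n_one,
        n_two_vdj=n_two,
        pct_two_vdj=100.0 * n_two / total,
        single_vdj_by_genotype=by_genotype,
    )


# ---------------------------------------------------------------------------
# Population I/O
# ---------------------------------------------------------------------------

_POP_COLUMNS = (
    "cell_id",
    "fate",
    "productive_allele",
    "allele1_genotype",
    "allele1_state",
    "allele1_junction",
    "allele1_productive",
    "allele1_nmd_class",
    "allele2_genotype",
    "allele2_state",
    "allele2_junction",
    "allele2_productive",
    "allele2_nmd_class",
)


def population_table(cells: list[CellRecord]) -> pd.DataFrame:
    """One row per cell: allele states, junction sequences, classes, fate."""
    rows = []
    for i, c in enumerate(cells):
        row: list = [i, c.fate, c.productive_allele if c.productive_allele is not None else ""]
        for a in c.alleles:
            row.extend(
                [
                    a.genotype,
                    a.state,
                    a.junction.junction_seq if a.junction else "",
                    "" if a.productive is None else a.productive,
                    a.annotation.nmd_class if a.annotation else "",
                ]
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=_POP_COLUMNS)


def write_population_tsv(cells: list[CellRecord], path) -> None:
    population_table(cells).to_csv(path, sep="\t", index=False)


def read_population_alleles(path) -> pd.DataFrame:
    """Read a population TSV back as a per-allele table for pool sampling.

    Returns one row per VDJ allele of each surviving cell with columns
    ``cell_id``, ``allele_index``, ``genotype``, ``junction_seq``,
    ``nmd_class``, ``productive``.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    rows = []
    for row in df.itertuples(index=False):
        if row.fate != ALIVE_PRODUCTIVE:
            continue
        for k in (1, 2):
            if getattr(row, f"allele{k}_state") != VDJ:
                continue
            rows.append(
                (
                    row.cell_id,
                    k - 1,
                    getattr(row, f"allele{k}_genotype"),
                    getattr(row, f"allele{k}_junction"),
                    getattr(row, f"allele{k}_nmd_class"),
                    str(getattr(row, f"allele{k}_productive")) == "True",
                )
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "allele_index", "genotype", "junction_seq", "nmd_class", "productive"],
    )
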