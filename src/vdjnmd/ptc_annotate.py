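"""Premature-termination-codon annotation and NMD-class calling.

A transcript is scanned from its CDS start in frame 0; the first stop codon
is either the canonical termination codon (PTC-negative, productive) or a
premature termination codon.  A PTC is *EJC-competent* when at least one
exon-exon junction lies downstream of it by more than a threshold distance
(the 50-55 nt rule for exon-junction-complex-dependent NMD); a PTC without
such a junction can only be sensed by the intron-independent fail-safe
pathway (poly(A)-distance sensing), giving three classes:

* ``PTC_NEG`` — in-frame, no premature stop;
* ``PTC_EJC`` — premature stop with an EJC-competent downstream junction;
* ``PTC_FAILSAFE`` — premature stop reachable only by fail-safe NMD.

The distance is measured by default from the last base of the stop codon to
the junction position (index of the first base of the downstream exon), with
strict inequality against the threshold; measuring from the first base of
the stop instead is exposed via :class:`EjcParams.measure_from` since the
two conventions differ by 2 nt.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .gene_models import AlleleModel, MatureTranscript, _DNA, _STOP_SET, splice

logger = logging.getLogger(__name__)

PTC_NEG = "PTC_NEG"
PTC_EJC = "PTC_EJC"
PTC_FAILSAFE = "PTC_FAILSAFE"
NMD_CLASSES = (PTC_NEG, PTC_EJC, PTC_FAILSAFE)


@dataclass(frozen=True)
class EjcParams:
    """EJC-rule parameters.

    ``threshold_nt`` is the minimum PTC-to-junction distance for EJC
    competence (default 55, the conservative end of the 50-55 nt rule);
    ``deposit_offset_nt`` records the assumed EJC deposition point upstream
    of a junction (annotation metadata only, default 22 of the ~20-24 nt
    range); ``measure_from`` selects the stop-codon base the distance is
    measured from (``"last"`` or ``"first"``).
    """

    threshold_nt: int = 55
    deposit_offset_nt: int = 22
    measure_from: str = "last"

    def __post_init__(self) -> None:
        if self.threshold_nt < 0:
            raise ValueError("threshold_nt must be >= 0")
        if self.measure_from not in ("last", "first"):
            raise ValueError("measure_from must be 'last' or 'first'")


@dataclass(frozen=True)
class PTCAnnotation:
    """Productivity and NMD classification of one transcript."""

    productive: bool
    ptc_pos: int | None
    ptc_exon_index: int | None
    dist_next_junction: int | None
    dist_polyA: int | None
    ejc_competent: bool
    nmd_class: str


def find_first_stop(mature: MatureTranscript, frame_offset: int) -> int | None:
    """Position of the first stop codon scanning from ``cds_start + frame_offset``.

    Returns ``None`` if no stop is encountered.  The caller decides whether a
    frame-0 hit at the canonical stop offset is canonical rather than
    premature.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seq = mature.seq
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"transcript contains non-ACGT characters: {sorted(bad)}")
    start = mature.cds_start + frame_offset
    if start >= len(seq):
        raise ValueError("scan start beyond transcript end")
    for i in range(start, len(seq) - 2, 3):
        if seq[i: i + 3] in _STOP_SET:
            return i
    return None


def _junction_distances(
    ptc_pos: int, exon_junctions, params: EjcParams
) -> tuple[int | None, bool]:
    """(distance to nearest downstream junction, EJC competence)."""
    js = list(exon_junctions)
    if any(b <= a for a, b in zip(js, js[1:])):
        raise ValueError("exon junction list must be sorted strictly increasing")
    origin = ptc_pos + 2 if params.measure_from == "last" else ptc_pos
    downstream = [j - origin for j in js if j >= ptc_pos + 3]
    if not downstream:
        return None, False
    return min(downstream), any(d > params.threshold_nt for d in downstream)


def classify_ejc(ptc_pos: int, exon_junctions, params: EjcParams | None = None) -> bool:
    """True iff some exon junction lies downstream of the PTC by more than the threshold."""
    params = params or EjcParams()
    if ptc_pos < 0:
        raise ValueError("ptc_pos must be a valid mRNA coordinate")
    return _junction_distances(ptc_pos, exon_junctions, params)[1]


_NEGATIVE = PTCAnnotation(
    productive=True,
    ptc_pos=None,
    ptc_exon_index=None,
    dist_next_junction=None,
    dist_polyA=None,
    ejc_competent=False,
    nmd_class=PTC_NEG,
)


def annotate(mature: MatureTranscript, params: EjcParams | None = None) -> PTCAnnotation:
    """Annotate one mature transcript.

    Productivity is decided by the frame-0 scan; a first stop at the
    canonical stop offset (or no stop at all) is productive.  For PTCs the
    downstream-junction geometry and poly(A) distance are recorded and the
    NMD class assigned.
    """
    params = params or EjcParams()
    if mature.cds_start >= len(mature.seq):
        raise ValueError("cds_start beyond transcript end")
    pos = find_first_stop(mature, 0)
    if pos is None or pos == mature.canonical_stop_offset:
        return _NEGATIVE
    exon_index = bisect_right(mature.exon_junctions, pos)
    dist_next, competent = _junction_distances(pos, mature.exon_junctions, params)
    return PTCAnnotation(
        productive=False,
        ptc_pos=pos,
        ptc_exon_index=exon_index,
        dist_next_junction=dist_next,
        dist_polyA=mature.polyA_pos - pos,
        ejc_competent=competent,
        nmd_class=PTC_EJC if competent else PTC_FAILSAFE,
    )


def annotate_junction(
    model: AlleleModel, junction_seq: str, params: EjcParams | None = None
) -> PTCAnnotation:
    """Instantiate ``junction_seq`` into the model's second exon and annotate."""
    return annotate(splice(model.with_junction(junction_seq)), params)


class Annotator:
    """Cached junction annotator for one allele model.

    Junction sequences repeat heavily in sampled pools; annotation depends
    only on the junction sequence given a fixed model, so results are
    memoised.
    """

    def __init__(self, model: AlleleModel, params: EjcParams | None = None):
        self.model = model
        self.params = params or EjcParams()
        self._cache: dict[str, PTCAnnotation] = {}

    def annotate_junction(self, junction_seq: str) -> PTCAnnotation:
        ann = self._cache.get(junction_seq)
        if ann is None:
            ann = annotate_junction(self.model, junction_seq, self.params)
            self._cache[junction_seq] = ann
        return ann

    __call__ = annotate_junction


ANNOTATION_COLUMNS = (
    "id",
    "genotype",
    "productive",
    "ptc_pos",
    "ptc_exon",
    "dist_next_junction",
    "dist_polyA",
    "nmd_class",
)


def annotate_fasta(
    source,
    model: AlleleModel,
    params: EjcParams | None = None,
    mode: str = "junction",
    annotator: Annotator | None = None,
) -> tuple[pd.DataFrame, int]:
    """Annotate every record of a FASTA file against one allele model.

    ``mode="junction"`` treats each record as a junction sequence to be
    instantiated into the model's second exon; ``mode="transcript"`` treats
    it as a full spliced mRNA of the model (second-exon length inferred from
    the record length).  Returns the annotation table and the number of
    rejected (non-ACGT) records, which are logged rather than silently
    dropped.
    """
    params = params or EjcParams()
    if mode not in ("junction", "transcript"):
        raise ValueError("mode must be 'junction' or 'transcript'")
    if annotator is None:
        annotator = Annotator(model, params)
    reference = splice(model)
    rows = []
    n_rejected = 0
    n_seen = 0
    for record in SeqIO.parse(source, "fasta"):
        n_seen += 1
        seq = str(record.seq).upper()
        if not seq or set(seq) - _DNA:
            n_rejected += 1
            logger.warning("rejected record %s: non-ACGT or empty sequence", record.id)
            continue
        if mode == "junction":
            ann = annotator.annotate_junction(seq)
        else:
            delta = len(seq) - len(reference.seq)
            junctions = tuple(
                j + delta if j > reference.exon_junctions[model.junction_exon - 1] else j
                for j in reference.exon_junctions
            )
            mature = MatureTranscript(
                seq=seq,
                exon_junctions=junctions,
                cds_start=reference.cds_start,
                polyA_pos=len(seq) - 1,
                canonical_stop_offset=reference.canonical_stop_offset + delta,
            )
            ann = annotate(mature, params)
        rows.append(
            (
                record.id,
                model.genotype,
                ann.productive,
                ann.ptc_pos,
                ann.ptc_exon_index,
                ann.dist_next_junction,
                ann.dist_polyA,
                ann.nmd_class,
            )
        )
    if n_seen == 0:
        raise ValueError("empty FASTA input")
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).astype(
        {
            "ptc_pos": "Int64",
            "ptc_exon": "Int64",
            "dist_next_junction": "Int64",
            "dist_polyA": "Int64",
        }
    )
    return df, n_rejected
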