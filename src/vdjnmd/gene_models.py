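"""Gene models for an engineered antigen-receptor locus.

This module represents the exon/intron architecture of a T-cell-receptor-beta-
like locus in two paired, engineered forms:

* genotype ``A`` — the intron-bearing allele: six exons (non-coding leader,
  the V(D)J-assembled second exon, and four constant-region exons) separated
  by five introns;
* genotype ``F`` — the exon-fused allele: identical to ``A`` except that the
  four constant-region exons are fused into a single final exon, removing the
  three downstream introns while retaining the two upstream ones.

The spliced mRNA of an F model is base-for-base identical to that of its
paired A model; the two differ only in where exon junctions fall.  A
frameshifted reading of the constant region (reading-frame offset +1 or +2)
encounters its first stop codon inside the third exon of either allele, at
the same mRNA coordinate for both genotypes.  In the A form that premature
termination codon (PTC) has downstream introns; in the F form the third exon
is the last, so it does not.  Both PTCs sit a configurable distance
(default 0.7 kb) upstream of the poly(A) attachment point.

Coordinates are 0-based and half-open throughout.  An *exon junction* is the
index of the first base of the downstream exon in the spliced mRNA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")
_STOP_SET = frozenset(STOP_CODONS)
_DNA = frozenset("ACGT")
# Every stop codon starts with T, so sequence drawn from this alphabet is
# stop-free in all three frames; stops are then placed explicitly.
_STOPFREE_ALPHABET = np.array(list("ACG"))
_FULL_ALPHABET = np.array(list("ACGT"))


class FixtureDesignError(ValueError):
    """A reference-fixture constraint could not be satisfied."""


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class GeneSegment:
    """One V, D or J gene segment.

    ``kind`` determines which end(s) may be trimmed during joining:
    V loses bases from its 3' end, J from its 5' end, D from both.
    """

    name: str
    kind: str  # "V", "D" or "J"
    seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("V", "D", "J"):
            raise ValueError(f"segment kind must be V, D or J, got {self.kind!r}")
        _check_dna(self.seq, f"segment {self.name}")


@dataclass(frozen=True)
class MatureTranscript:
    """A spliced mRNA with its exon-junction map.

    ``exon_junctions[i]`` is the index of the first base of exon ``i+1``;
    ``polyA_pos`` is the index of the last transcribed base.
    """

    seq: str
    exon_junctions: tuple[int, ...]
    cds_start: int
    polyA_pos: int
    canonical_stop_offset: int

    def __post_init__(self) -> None:
        js = self.exon_junctions
        if any(b <= a for a, b in zip(js, js[1:])):
            raise ValueError("exon junctions must be strictly increasing")
        if js and js[-1] >= len(self.seq):
            raise ValueError("exon junction beyond transcript end")
        if self.polyA_pos != len(self.seq) - 1:
            raise ValueError("polyA_pos must be the last transcribed base")


@dataclass
class AlleleModel:
    """Exon/intron table plus CDS landmarks for one engineered allele.

    The second exon (index ``junction_exon``) is composed as
    ``v_part + junction + j_part``; :meth:`with_junction` swaps in a new
    junction sequence and shifts downstream mRNA landmarks accordingly.
    """

    allele_id: str
    genotype: str  # "A" or "F"
    exons: list[tuple[str, str]]  # (name, sequence)
    introns: list[str]
    cds_start: int
    canonical_stop_offset: int
    v_part: str = ""
    j_part: str = ""
    junction_exon: int = 1

    # -- structure -------------------------------------------------------
    def exon_seqs(self) -> list[str]:
        return [seq for _, seq in self.exons]

    def exon_lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.exons]

    def mrna_length(self) -> int:
        return sum(self.exon_lengths())

    def junction_seq(self) -> str:
        """The junction portion of the second exon."""
        name, seq = self.exons[self.junction_exon]
        core = seq[len(self.v_part): len(seq) - len(self.j_part)]
        return core

    def validate(self, reference: bool = True) -> None:
        """Check structural invariants.

        ``reference=True`` additionally enforces the reference-frame
        invariants (canonical stop in frame with the CDS start and an actual
        stop codon), which instantiated frameshifted models need not satisfy.
        """
        if self.genotype not in ("A", "F"):
            raise ValueError(f"genotype must be A or F, got {self.genotype!r}")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError("intron count must be exon count - 1")
        expected = {"A": 6, "F": 3}[self.genotype]
        if len(self.exons) != expected:
            raise ValueError(
                f"genotype {self.genotype} requires {expected} exons, "
                f"got {len(self.exons)}"
            )
        for name, seq in self.exons:
            _check_dna(seq, f"exon {name}")
        for i, intron in enumerate(self.introns):
            if intron:
                _check_dna(intron, f"intron {i}")
        ex2 = self.exons[self.junction_exon][1]
        if not (ex2.startswith(self.v_part) and ex2.endswith(self.j_part)):
            raise ValueError("second exon inconsistent with v_part/j_part flanks")
        n = self.mrna_length()
        if not 0 <= self.cds_start < n:
            raise ValueError("cds_start outside spliced mRNA")
        if reference:
            if (self.canonical_stop_offset - self.cds_start) % 3 != 0:
                raise ValueError("canonical stop not in frame with cds_start")
            mrna = "".join(self.exon_seqs())
            codon = mrna[self.canonical_stop_offset: self.canonical_stop_offset + 3]
            if codon not in _STOP_SET:
                raise ValueError(
                    f"no stop codon at canonical_stop_offset (found {codon!r})"
                )

    # -- instantiation ---------------------------------------------------
    def with_junction(self, junction_seq: str) -> "AlleleModel":
        """Return a copy whose second exon carries ``junction_seq``.

        Downstream landmarks (here only the canonical stop) shift by the
        length difference of the second exon.
        """
        _check_dna(junction_seq, "junction")
        name, old = self.exons[self.junction_exon]
        new_exon = self.v_part + junction_seq + self.j_part
        delta = len(new_exon) - len(old)
        exons = list(self.exons)
        exons[self.junction_exon] = (name, new_exon)
        return replace(
            self,
            exons=exons,
            canonical_stop_offset=self.canonical_stop_offset + delta,
        )

    # -- sequence forms --------------------------------------------------
    def pre_mrna(self) -> str:
        """Unspliced transcript: exons interleaved with introns."""
        parts: list[str] = []
        for i, (_, exon) in enumerate(self.exons):
            parts.append(exon)
            if i < len(self.introns):
                parts.append(self.introns[i])
        return "".join(parts)

    def exon_table(self) -> pd.DataFrame:
        """BED-like exon/intron table in pre-mRNA coordinates (0-based, half-open)."""
        rows = []
        pos = 0
        for i, (name, exon) in enumerate(self.exons):
            rows.append((self.allele_id, pos, pos + len(exon), name, "exon"))
            pos += len(exon)
            if i < len(self.introns):
                intron = self.introns[i]
                rows.append((self.allele_id, pos, pos + len(intron), f"intron{i + 1}", "intron"))
                pos += len(intron)
        return pd.DataFrame(rows, columns=["allele", "start", "end", "name", "kind"])


def splice(model: AlleleModel) -> MatureTranscript:
    """Concatenate exons into the mature transcript.

    Exon junctions are the cumulative exon lengths (index of the first base
    of each downstream exon).
    """
    seqs = model.exon_seqs()
    if any(not s for s in seqs):
        raise ValueError("cannot splice a model with an empty exon")
    junctions = tuple(itertools.accumulate(len(s) for s in seqs[:-1]))
    seq = "".join(seqs)
    return MatureTranscript(
        seq=seq,
        exon_junctions=junctions,
        cds_start=model.cds_start,
        polyA_pos=len(seq) - 1,
        canonical_stop_offset=model.canonical_stop_offset,
    )


def fuse_constant_exons(model_a: AlleleModel) -> AlleleModel:
    """Fuse the four constant exons of an A model into one, yielding the F model.

    Exons 3..6 are concatenated into a single final exon and introns 3..5
    removed; the two upstream introns are retained, so the spliced mRNA is
    unchanged.
    """
    if model_a.genotype != "A":
        raise ValueError("fuse_constant_exons requires a genotype-A model")
    head = model_a.exons[:2]
    tail = model_a.exons[2:]
    fused_name = "+".join(name for name, _ in tail)
    fused_seq = "".join(seq for _, seq in tail)
    model_f = replace(
        model_a,
        allele_id=model_a.allele_id.replace("A", "F")
        if "A" in model_a.allele_id
        else model_a.allele_id + "_F",
        genotype="F",
        exons=head + [(fused_name, fused_seq)],
        introns=list(model_a.introns[:2]),
    )
    return model_f


# ---------------------------------------------------------------------------
# Reference fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureParams:
    """Parameters of the default paired A/F reference fixture.

    ``target_ptc_polya_distance`` is the designed distance (nt) from each
    frameshift PTC to the poly(A) attachment point (both alleles place their
    PTCs at the same mRNA coordinates, so the distance is shared).  Exon
    lengths are mRNA lengths of the six A-model exons; the second entry is
    the length of the *reference* (trimless, addition-less) second exon.
    """

    target_ptc_polya_distance: int = 700
    exon_lengths: tuple[int, ...] = (60, 150, 200, 150, 150, 260)
    intron_lengths: tuple[int, ...] = (90, 90, 90, 90, 90)
    utr3_length: int = 55
    v_len: int = 21
    d_len: int = 12
    j_len: int = 21
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if len(self.exon_lengths) != 6:
            raise ValueError("fixture requires six exon lengths")
        if len(self.intron_lengths) != 5:
            raise ValueError("fixture requires five intron lengths")
        if any(n <= 0 for n in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if any(n < 4 for n in self.intron_lengths):
            raise ValueError("intron lengths must be >= 4 (GT...AG)")
        if self.target_ptc_polya_distance <= 0:
            raise ValueError("target PTC-to-poly(A) distance must be positive")
        flank = self.exon_lengths[1] - (self.v_len + self.d_len + self.j_len)
        if flank < 0:
            raise ValueError("second exon shorter than V+D+J reference junction")


@dataclass(frozen=True)
class Fixture:
    """Paired reference models plus the gene segments that fill exon 2."""

    model_a: AlleleModel
    model_f: AlleleModel
    v_segment: GeneSegment
    d_segment: GeneSegment
    j_segment: GeneSegment
    params: FixtureParams

    @property
    def models(self) -> dict[str, AlleleModel]:
        return {"A": self.model_a, "F": self.model_f}

    @property
    def segments(self) -> tuple[GeneSegment, GeneSegment, GeneSegment]:
        return (self.v_segment, self.d_segment, self.j_segment)


def _rand_seq(rng: np.random.Generator, n: int, alphabet: np.ndarray) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), size=n)])


def _design_positions(params: FixtureParams) -> tuple[int, int, int]:
    """Choose the mRNA coordinates of the two frameshift PTCs and the canonical stop.

    The frame +1 and +2 stops must occupy distinct, in-frame, non-overlapping
    codons; placing them 4 nt apart centres their poly(A) distances on the
    target (within one codon each).
    """
    lengths = params.exon_lengths
    total = sum(lengths)
    polya = total - 1
    cds = lengths[0]
    target = params.target_ptc_polya_distance
    r1 = (cds + 1) % 3
    upper = polya - target - 1
    if upper < 0:
        raise FixtureDesignError("ptc-to-polyA distance exceeds transcript length")
    p1 = upper - ((upper - r1) % 3)
    p2 = p1 + 4
    utr_budget = total - params.utr3_length - 3
    canonical = utr_budget - ((utr_budget - cds % 3) % 3)
    return p1, p2, canonical


def _verify_fixture(fix: Fixture, p1: int, p2: int) -> None:
    """Independent verification of the fixture's design constraints."""
    params = fix.params
    a, f = fix.model_a, fix.model_f
    ta, tf = splice(a), splice(f)
    if ta.seq != tf.seq:
        raise FixtureDesignError("spliced mRNA of A and F differ")

    def first_stop(t: MatureTranscript, offset: int) -> int | None:
        for i in range(t.cds_start + offset, len(t.seq) - 2, 3):
            if t.seq[i: i + 3] in _STOP_SET:
                return i
        return None

    stop0 = first_stop(ta, 0)
    if stop0 != a.canonical_stop_offset:
        raise FixtureDesignError(
            f"frame 0 not stop-free before the canonical stop (first stop {stop0})"
        )
    exon3_start, exon3_end = ta.exon_junctions[1], ta.exon_junctions[2]
    threshold = 55  # conservative end of the 50-55 nt EJC rule
    for offset, expected in ((1, None), (2, None)):
        pos = first_stop(ta, offset)
        if pos is None:
            raise FixtureDesignError(f"frame +{offset} has no stop codon")
        if pos not in (p1, p2):
            raise FixtureDesignError(
                f"frame +{offset} first stop at {pos}, not a designed PTC"
            )
        if not (exon3_start <= pos and pos + 3 <= exon3_end):
            raise FixtureDesignError(f"frame +{offset} PTC not inside exon 3")
        if exon3_end - (pos + 3) <= threshold:
            raise FixtureDesignError(
                f"frame +{offset} PTC within {threshold} nt of the exon 3/4 junction"
            )
        dist = ta.polyA_pos - pos
        if abs(dist - params.target_ptc_polya_distance) > 3:
            raise FixtureDesignError(
                f"frame +{offset} PTC-to-poly(A) distance {dist} off target"
            )
    # F: both PTCs must lie in the final exon (no downstream junction)
    if tf.exon_junctions[-1] > p1:
        raise FixtureDesignError("F-model PTC not in final exon")


def make_reference_fixture(params: FixtureParams | None = None) -> Fixture:
    """Design the default paired A/F fixture (models + gene segments).

    Background sequence is drawn from the stop-free alphabet {A,C,G} so that
    no spurious stop exists in any frame; the two frameshift PTCs and the
    canonical termination codon are then placed at designed coordinates, and
    the result is verified against every constraint.  Construction is
    deterministic given ``params.seed``.
    """
    params = params or FixtureParams()
    p1, p2, canonical = _design_positions(params)
    lengths = params.exon_lengths
    cum = list(itertools.accumulate(lengths))
    exon3_start = cum[1]
    cds = lengths[0]
    # deterministic geometry checks (sequence randomness cannot fix these)
    if not (exon3_start <= p1 and p2 + 3 <= cum[2]):
        raise FixtureDesignError(
            "designed PTCs do not fall inside constant exon 3; adjust exon "
            "lengths or the target PTC-to-poly(A) distance"
        )
    if cum[2] - (p2 + 3) <= 55:
        raise FixtureDesignError(
            "designed PTCs lie within 55 nt of the exon 3/4 junction"
        )
    if not cum[4] <= canonical <= sum(lengths) - 3:
        raise FixtureDesignError("canonical stop does not fall in the last exon")
    if canonical <= p2 + 2:
        raise FixtureDesignError("canonical stop upstream of the designed PTCs")

    rng = np.random.default_rng(params.seed)
    last_error: Exception | None = None
    for _ in range(max(1, params.max_attempts)):
        exon1 = _rand_seq(rng, lengths[0], _STOPFREE_ALPHABET)
        v = GeneSegment("V1", "V", _rand_seq(rng, params.v_len, _STOPFREE_ALPHABET))
        d = GeneSegment("D1", "D", _rand_seq(rng, params.d_len, _STOPFREE_ALPHABET))
        j = GeneSegment("J1", "J", _rand_seq(rng, params.j_len, _STOPFREE_ALPHABET))
        flank = lengths[1] - (params.v_len + params.d_len + params.j_len)
        v_part = _rand_seq(rng, flank // 2, _STOPFREE_ALPHABET)
        j_part = _rand_seq(rng, flank - flank // 2, _STOPFREE_ALPHABET)
        exon2 = v_part + v.seq + d.seq + j.seq + j_part

        const_len = sum(lengths[2:])
        const = np.array(list(_rand_seq(rng, const_len, _STOPFREE_ALPHABET)))
        for pos in (p1, p2, canonical):
            codon = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
            const[pos - exon3_start: pos - exon3_start + 3] = list(codon)
        const_str = "".join(const)
        const_exons = []
        offset = 0
        for i, n in enumerate(lengths[2:], start=1):
            const_exons.append((f"C{i}", const_str[offset: offset + n]))
            offset += n

        introns = []
        for n in params.intron_lengths:
            introns.append("GT" + _rand_seq(rng, n - 4, _FULL_ALPHABET) + "AG")

        model_a = AlleleModel(
            allele_id="alleleA",
            genotype="A",
            exons=[("L", exon1), ("VDJ", exon2)] + const_exons,
            introns=introns,
            cds_start=cds,
            canonical_stop_offset=canonical,
            v_part=v_part,
            j_part=j_part,
        )
        model_a.validate()
        model_f = fuse_constant_exons(model_a)
        model_f.validate()
        fix = Fixture(model_a, model_f, v, d, j, params)
        try:
            _verify_fixture(fix, p1, p2)
        except FixtureDesignError as exc:  # pragma: no cover - defensive
            last_error = exc
            continue
        return fix
    raise FixtureDesignError(
        f"no valid fixture after {params.max_attempts} attempts: {last_error}"
    )


def make_reference_models(
    params: FixtureParams | None = None,
) -> tuple[AlleleModel, AlleleModel]:
    """Return the paired (A, F) reference allele models."""
    fix = make_reference_fixture(params)
    return fix.model_a, fix.model_f


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_models_config(path, fixture: Fixture) -> None:
    """Serialize a fixture to a flat key-value config file (sequences inline)."""
    lines = ["# vdjnmd allele models"]
    for key, model in (("a", fixture.model_a), ("f", fixture.model_f)):
        lines.append(f"{key}.allele_id = {model.allele_id}")
        lines.append(f"{key}.genotype = {model.genotype}")
        lines.append(f"{key}.cds_start = {model.cds_start}")
        lines.append(f"{key}.canonical_stop_offset = {model.canonical_stop_offset}")
        lines.append(f"{key}.v_part = {model.v_part}")
        lines.append(f"{key}.j_part = {model.j_part}")
        for i, (name, seq) in enumerate(model.exons):
            lines.append(f"{key}.exon.{i}.name = {name}")
            lines.append(f"{key}.exon.{i}.seq = {seq}")
        for i, intron in enumerate(model.introns):
            lines.append(f"{key}.intron.{i} = {intron}")
    for seg in fixture.segments:
        lines.append(f"segment.{seg.kind} = {seg.name}:{seg.seq}")
    lines.append(f"fixture.target_ptc_polya_distance = {fixture.params.target_ptc_polya_distance}")
    lines.append(f"fixture.seed = {fixture.params.seed}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_models_config(path) -> Fixture:
    """Read a fixture back from :func:`write_models_config` output."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

    def build(prefix: str) -> AlleleModel:
        exons = []
        for i in itertools.count():
            name_key = f"{prefix}.exon.{i}.name"
            if name_key not in kv:
                break
            exons.append((kv[name_key], kv[f"{prefix}.exon.{i}.seq"]))
        introns = []
        for i in itertools.count():
            key = f"{prefix}.intron.{i}"
            if key not in kv:
                break
            introns.append(kv[key])
        return AlleleModel(
            allele_id=kv[f"{prefix}.allele_id"],
            genotype=kv[f"{prefix}.genotype"],
            exons=exons,
            introns=introns,
            cds_start=int(kv[f"{prefix}.cds_start"]),
            canonical_stop_offset=int(kv[f"{prefix}.canonical_stop_offset"]),
            v_part=kv.get(f"{prefix}.v_part", ""),
            j_part=kv.get(f"{prefix}.j_part", ""),
        )

    segments = {}
    for kind in ("V", "D", "J"):
        name, _, seq = kv[f"segment.{kind}"].partition(":")
        segments[kind] = GeneSegment(name, kind, seq)
    params = FixtureParams(
        target_ptc_polya_distance=int(kv.get("fixture.target_ptc_polya_distance", 700)),
        seed=int(kv.get("fixture.seed", 0)),
    )
    model_a = build("a")
    model_f = build("f")
    model_a.validate()
    model_f.validate()
    return Fixture(model_a, model_f, segments["V"], segments["D"], segments["J"], params)
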