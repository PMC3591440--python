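"""Mapping homolog coordinates onto the human NOX2 reference.

Signature positions in this superfamily are conventionally quoted in human
NOX2 numbering (His-101, His-115, ..., His-222). To read those positions off
an arbitrary homolog we globally align it to the NOX2 reference
(Needleman-Wunsch, BLOSUM62, affine gaps) and keep the monotone set of
match-column position pairs as a :class:`PositionMap`.

A Kyte-Doolittle hydropathy scan provides a light-weight stand-in for
transmembrane-segment prediction; TM windows are only reported as context and
never used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
import logging

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import AMBIGUOUS_AA, CANONICAL_AA, GAP_CHAR, ProteinRecord, read_fasta

logger = logging.getLogger(__name__)

_ALIGN_ALPHABET = CANONICAL_AA + AMBIGUOUS_AA


@lru_cache(maxsize=4)
def _extended_matrix(name: str):
    """A named substitution matrix extended so ambiguity letters score 0."""
    base = substitution_matrices.load(name)
    ext = substitution_matrices.Array(alphabet=_ALIGN_ALPHABET, dims=2)
    for a in CANONICAL_AA:
        for b in CANONICAL_AA:
            ext[a, b] = base[a, b]
    return ext


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST-style
    convention). Defaults: BLOSUM62, open 11, extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        return _extended_matrix(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two gapped strings plus its score."""

    aligned_query: str
    aligned_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")


@dataclass
class PositionMap:
    """Monotone pairing of 1-based query and reference positions.

    Only columns where both rows carry a residue contribute a pair, so the
    pairs are strictly increasing in both coordinates.
    """

    pairs: list[tuple[int, int]]
    query_length: int = 0
    ref_length: int = 0
    _ref_to_query: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for (q0, r0), (q1, r1) in zip(self.pairs, self.pairs[1:]):
            if not (q1 > q0 and r1 > r0):
                raise ValueError("position map is not strictly monotone")
        self._ref_to_query = {r: q for q, r in self.pairs}

    def to_query(self, ref_pos: int) -> int | None:
        return self._ref_to_query.get(ref_pos)


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix
    # first gap position costs open+extend, each further one costs extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def global_align(
    query: str | ProteinRecord,
    ref: str | ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``ref``.

    Ambiguity letters (X/B/Z/U) score 0 against everything. Among co-optimal
    tracebacks the first one reported by the dynamic program is taken, which
    is deterministic for fixed inputs.
    """
    qseq = query.sequence if isinstance(query, ProteinRecord) else str(query).upper()
    rseq = ref.sequence if isinstance(ref, ProteinRecord) else str(ref).upper()
    if not qseq or not rseq:
        raise ValueError("cannot align an empty sequence")
    for name, seq in (("query", qseq), ("ref", rseq)):
        bad = set(seq) - set(_ALIGN_ALPHABET)
        if bad:
            raise ValueError(f"{name} contains unalignable letters {sorted(bad)!r}")
    aligner = _make_aligner(scheme)
    alignment = aligner.align(qseq, rseq)[0]
    return PairwiseAlignment(
        aligned_query=alignment[0], aligned_ref=alignment[1], score=alignment.score
    )


def build_position_map(aln: PairwiseAlignment) -> PositionMap:
    """Extract the monotone (query_pos, ref_pos) pairs of the match columns."""
    pairs: list[tuple[int, int]] = []
    q = r = 0
    for cq, cr in zip(aln.aligned_query, aln.aligned_ref):
        if cq != GAP_CHAR:
            q += 1
        if cr != GAP_CHAR:
            r += 1
        if cq != GAP_CHAR and cr != GAP_CHAR:
            pairs.append((q, r))
    return PositionMap(pairs=pairs, query_length=q, ref_length=r)


def ref_to_query(pmap: PositionMap, ref_pos: int) -> int | None:
    """Query position paired with ``ref_pos``, or None if it falls in a gap."""
    if ref_pos < 1:
        raise ValueError("reference positions are 1-based")
    return pmap.to_query(ref_pos)


#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_tm_scan(
    seq: str | ProteinRecord, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Putative transmembrane segments from windowed Kyte-Doolittle means.

    Window means are computed at every center where the (odd-sized) window
    fits; maximal runs of centers above ``threshold`` are expanded to the
    window extent, overlapping segments merged, and returned as 1-based
    inclusive intervals. Sequences shorter than the window yield an empty
    list with a warning.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd count >= 3")
    s = seq.sequence if isinstance(seq, ProteinRecord) else str(seq).upper()
    if len(s) < window:
        logger.warning("sequence shorter than window (%d < %d)", len(s), window)
        return []
    values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in s])
    half = window // 2
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    # means[i] is the mean for 1-based center i + half + 1
    above = means > threshold
    intervals: list[tuple[int, int]] = []
    run_start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            first_center = run_start + half + 1
            last_center = i - 1 + half + 1
            intervals.append(
                (max(1, first_center - half), min(len(s), last_center + half))
            )
            run_start = None
    merged: list[tuple[int, int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


#: Signature positions in NOX2 numbering and the residues of the reference.
CANONICAL_HEME_POSITIONS = (101, 115, 209, 222)
SIGNATURE_POSITIONS = (101, 115, 119, 178, 179, 209, 222)
_REFERENCE_RESIDUES = {
    101: "H", 115: "H", 119: "H", 178: "T", 179: "G", 209: "H", 222: "H",
}


@dataclass
class ReferenceAnnotation:
    """The NOX2 reference sequence plus its annotated landmark positions.

    tm_windows holds hydropathy-derived intervals labelled TM3/TM4/TM5 for
    reporting context only; classification never consults them.
    """

    reference: ProteinRecord
    canonical_positions: tuple[int, ...] = CANONICAL_HEME_POSITIONS
    signature_positions: tuple[int, ...] = SIGNATURE_POSITIONS
    tm_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, expected in _REFERENCE_RESIDUES.items():
            observed = self.reference.residue(pos)
            if observed != expected:
                raise ValueError(
                    f"reference residue at {pos} is {observed}, expected {expected}"
                )


def _name_tm_windows(
    intervals: list[tuple[int, int]]
) -> dict[str, tuple[int, int]]:
    """Attach TM3/TM4/TM5 labels to the hydropathy intervals nearest the
    landmark positions (101/115 -> TM3, 178/179 -> TM4, 209/222 -> TM5)."""
    anchors = {"TM3": 108, "TM4": 178, "TM5": 215}
    named: dict[str, tuple[int, int]] = {}
    for label, anchor in anchors.items():
        best = None
        for start, end in intervals:
            dist = 0 if start <= anchor <= end else min(abs(start - anchor), abs(end - anchor))
            if best is None or dist < best[0]:
                best = (dist, (start, end))
        if best is not None:
            named[label] = best[1]
    return named


NOX2_FIXTURE = "nox2_human.fasta"
NOX5_FIXTURE = "nox5_like_synthetic.fasta"


def _load_fixture_record(name: str) -> ProteinRecord:
    with resources.as_file(resources.files("frdsig") / "fixtures" / name) as path:
        return read_fasta(path)[0]


@lru_cache(maxsize=1)
def load_nox2_reference() -> ReferenceAnnotation:
    """Load the bundled human NOX2 reference and validate its landmarks."""
    record = _load_fixture_record(NOX2_FIXTURE)
    annotation = ReferenceAnnotation(reference=record)
    annotation.tm_windows = _name_tm_windows(hydropathy_tm_scan(record))
    return annotation


@lru_cache(maxsize=1)
def load_nox5_fixture() -> ProteinRecord:
    """Load the bundled synthetic NOX5-like EF-hand construct.

    This is a synthetic stand-in (four canonical EF-hand loops fused to the
    NOX2 core), not the UniProtKB Q96PH1 sequence.
    """
    return _load_fixture_record(NOX5_FIXTURE)
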