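"""Signature-motif tables, residue-vector extraction and clade classification.

The classifier encodes the residue signatures that separate the major FRD
superfamily clades when read in human NOX2 coordinates:

* four canonical heme-coordinating histidines at 101/115 (TM3) and 209/222
  (TM5), shared by all long forms;
* the NOX motif His-101 / His-119 / Thr-178 / Gly-179 that distinguishes
  ROS-generating NADPH oxidases from metalloreductases, with the Thr-Gly
  dipeptide conserved in all probable ROS generators;
* replacement of the first heme histidine (101) by a conserved arginine in
  YedZ/STEAP proteins, with a conserved glutamine at the 209-equivalent site
  marking the STEAP2-4 subtype;
* preNOX-like sequences that keep the Thr-Gly dipeptide but lack His-119
  (green-algal members additionally lack His-115).

Classification is a total, deterministic rule cascade over the residues
observed at the seven reference positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .conservation import ConservationProfile
from .core import CANONICAL_AA, ProteinRecord

CANONICAL_LETTERS = frozenset(CANONICAL_AA)
from .refmap import (
    CANONICAL_HEME_POSITIONS,
    DEFAULT_SCHEME,
    PositionMap,
    ReferenceAnnotation,
    ScoringScheme,
    SIGNATURE_POSITIONS,
    build_position_map,
    global_align,
    load_nox2_reference,
    ref_to_query,
)

#: Wildcard / negation markers used in clade profiles.
ANY = "*"


def _not(residue: str) -> str:
    return "!" + residue


@dataclass(frozen=True)
class SignatureTable:
    """Expected residues per clade at the seven NOX2 reference positions.

    Profile entries are a residue letter, ``"*"`` (unconstrained) or
    ``"!X"`` (any residue except X).
    """

    positions: tuple[int, ...] = SIGNATURE_POSITIONS
    clade_profiles: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: dict(_DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        for clade, profile in self.clade_profiles.items():
            if set(profile) != set(self.positions):
                raise ValueError(f"profile {clade!r} does not cover all positions")

    def expected(self, clade: str, pos: int) -> str:
        return self.clade_profiles[clade][pos]

    @staticmethod
    def matches(expected: str, observed: str | None) -> bool:
        """Whether an observed residue satisfies a profile entry."""
        if observed is None:
            return False
        if expected == ANY:
            return True
        if expected.startswith("!"):
            return observed != expected[1:]
        return observed == expected


_DEFAULT_PROFILES: dict[str, dict[int, str]] = {
    "NOX": {101: "H", 115: "H", 119: "H", 178: "T", 179: "G", 209: "H", 222: "H"},
    "preNOX": {101: "H", 115: "H", 119: _not("H"), 178: "T", 179: "G", 209: "H", 222: "H"},
    "FRE": {101: "H", 115: "H", 119: ANY, 178: ANY, 179: ANY, 209: "H", 222: "H"},
    "YedZ/STEAP1": {101: "R", 115: "H", 119: ANY, 178: ANY, 179: ANY, 209: "H", 222: "H"},
    "STEAP2-4": {101: "R", 115: "H", 119: ANY, 178: ANY, 179: ANY, 209: "Q", 222: "H"},
}


def default_signature_table() -> SignatureTable:
    return SignatureTable()


@dataclass
class ResidueVector:
    """Residues a query shows at the reference positions (None = unaligned)."""

    query_id: str
    residues: dict[int, str | None]

    def __post_init__(self) -> None:
        if tuple(sorted(self.residues)) != tuple(sorted(SIGNATURE_POSITIONS)):
            raise ValueError("residue vector keys must equal the signature positions")


@dataclass
class ClassificationResult:
    """Clade call for one query with per-position evidence."""

    query_id: str
    label: str
    subtype: str | None
    heme_histidine_count: int
    evidence: dict[str, str | None]

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationResult":
        return cls(
            query_id=d["query_id"],
            label=d["label"],
            subtype=d["subtype"],
            heme_histidine_count=int(d["heme_histidine_count"]),
            evidence=dict(d["evidence"]),
        )


def extract_residue_vector(
    query: ProteinRecord,
    pmap: PositionMap,
    table: SignatureTable | None = None,
    reference: ProteinRecord | None = None,
) -> ResidueVector:
    """Read the query residues at the table's reference positions off a map.

    When ``reference`` is given, the map must have been built against a
    reference of that length.
    """
    table = table or default_signature_table()
    if reference is not None and pmap.ref_length != len(reference.sequence):
        raise ValueError(
            f"position map covers a reference of length {pmap.ref_length}, "
            f"expected {len(reference.sequence)}"
        )
    residues: dict[int, str | None] = {}
    for pos in table.positions:
        qpos = ref_to_query(pmap, pos)
        residues[pos] = query.residue(qpos) if qpos is not None else None
    return ResidueVector(query_id=query.id, residues=residues)


LABEL_NOX = "NOX-group"
LABEL_PRENOX = "preNOX-like"
LABEL_FRE = "FRE-group"
LABEL_YEDZ_STEAP = "YedZ/STEAP"
LABEL_AMBIGUOUS = "ambiguous"
SUBTYPE_YEDZ_STEAP1 = "YedZ/STEAP1-like"
SUBTYPE_STEAP24 = "STEAP2-4-like"


def heme_histidine_count(vector: ResidueVector) -> int:
    """Number of canonical heme positions (101/115/209/222) occupied by His."""
    return sum(
        1 for pos in CANONICAL_HEME_POSITIONS if vector.residues.get(pos) == "H"
    )


def classify(
    vector: ResidueVector, table: SignatureTable | None = None
) -> ClassificationResult:
    """Assign a clade label to a residue vector (total, deterministic).

    Cascade:

    1. Arg at 101 -> YedZ/STEAP; His at 209 -> YedZ/STEAP1-like subtype,
       otherwise STEAP2-4-like (the arginine replacement is the sharpest
       single diagnostic, so it is tested first).
    2. Thr-178/Gly-179 dipeptide intact and His at 101: His-119 present ->
       NOX-group (His-115 may be missing, tolerating one mutated heme site);
       His-119 absent -> preNOX-like (covers the green-algal variant that
       additionally lacks His-115).
    3. Dipeptide intact without His-101/His-119 -> preNOX-like.
    4. Otherwise, >=3 canonical heme histidines -> FRE-group.
    5. Total fallback: ambiguous.
    """
    table = table or default_signature_table()
    res = vector.residues
    heme = heme_histidine_count(vector)
    dipeptide = res.get(178) == "T" and res.get(179) == "G"

    label: str
    subtype: str | None = None
    if res.get(101) == "R":
        label = LABEL_YEDZ_STEAP
        subtype = SUBTYPE_YEDZ_STEAP1 if res.get(209) == "H" else SUBTYPE_STEAP24
    elif dipeptide and res.get(101) == "H" and res.get(119) == "H":
        label = LABEL_NOX
    elif dipeptide and (res.get(101) == "H" or res.get(115) == "H"):
        label = LABEL_PRENOX
    elif heme >= 3:
        label = LABEL_FRE
    else:
        label = LABEL_AMBIGUOUS

    evidence: dict[str, str | None] = {
        f"pos{pos}": res.get(pos) for pos in table.positions
    }
    return ClassificationResult(
        query_id=vector.query_id,
        label=label,
        subtype=subtype,
        heme_histidine_count=heme,
        evidence=evidence,
    )


def nox_call_positions(table: SignatureTable | None = None) -> tuple[int, ...]:
    """Reference positions whose single mutation breaks the NOX call.

    Computed by perturbing the NOX consensus vector one position at a time
    and recording which mutations flip the label away from NOX-group; this
    recovers the NOX-distinguishing motif without restating it as a constant.
    """
    table = table or default_signature_table()
    base = {pos: table.expected("NOX", pos) for pos in table.positions}
    required = []
    for pos in table.positions:
        mutated = dict(base)
        # alanine never appears in any clade profile, a neutral disruption
        mutated[pos] = "A"
        result = classify(ResidueVector(query_id="probe", residues=mutated), table)
        if result.label != LABEL_NOX:
            required.append(pos)
    return tuple(required)


@dataclass
class DiscoveredSignature:
    """A reference position that discriminates clade A from clade B."""

    ref_pos: int
    residue_a: str
    freq_a: float
    freq_b_of_residue_a: float
    delta: float


def discover_signatures(
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    map_a: PositionMap,
    map_b: PositionMap,
    f_cons: float = 0.8,
    f_bg: float = 0.3,
) -> list[DiscoveredSignature]:
    """Reference positions where clade A is conserved and clade B differs.

    A position is reported when clade A's consensus residue reaches frequency
    >= ``f_cons`` in A while that same residue stays at frequency <= ``f_bg``
    in B. The maps translate reference positions into each profile's column
    space (identity when the alignments are already in reference coordinates).
    """
    if f_cons <= f_bg:
        raise ValueError("thresholds not separating (f_cons must exceed f_bg)")
    found: list[DiscoveredSignature] = []
    for ref_pos in range(1, max(map_a.ref_length, map_b.ref_length) + 1):
        col_a = map_a.to_query(ref_pos)
        col_b = map_b.to_query(ref_pos)
        if col_a is None or col_b is None:
            continue
        if not (1 <= col_a <= profile_a.n_columns and 1 <= col_b <= profile_b.n_columns):
            continue
        column_a = profile_a.columns[col_a - 1]
        if column_a.consensus is None:
            continue
        residue = column_a.consensus
        freq_a = column_a.frequencies.get(residue, 0.0)
        if freq_a < f_cons:
            continue
        freq_b = profile_b.columns[col_b - 1].frequencies.get(residue, 0.0)
        if freq_b > f_bg:
            continue
        found.append(
            DiscoveredSignature(
                ref_pos=ref_pos,
                residue_a=residue,
                freq_a=freq_a,
                freq_b_of_residue_a=freq_b,
                delta=freq_a - freq_b,
            )
        )
    found.sort(key=lambda s: s.ref_pos)
    return found


def identity_position_map(n: int) -> PositionMap:
    """Identity map over ``n`` positions (column i == reference position i)."""
    return PositionMap(
        pairs=[(i, i) for i in range(1, n + 1)], query_length=n, ref_length=n
    )


def map_profile_to_reference(
    profile: ConservationProfile,
    annotation: ReferenceAnnotation | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PositionMap:
    """Align a profile's consensus to the NOX2 reference to get a column map."""
    annotation = annotation or load_nox2_reference()
    consensus = profile.consensus_sequence(placeholder="X")
    aln = global_align(consensus, annotation.reference.sequence, scheme)
    return build_position_map(aln)


def classify_record(
    record: ProteinRecord,
    annotation: ReferenceAnnotation | None = None,
    table: SignatureTable | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ClassificationResult:
    """Full single-sequence pipeline: align to NOX2, extract, classify."""
    annotation = annotation or load_nox2_reference()
    table = table or default_signature_table()
    query = record.degapped()
    aln = global_align(query, annotation.reference, scheme)
    pmap = build_position_map(aln)
    vector = extract_residue_vector(query, pmap, table, reference=annotation.reference)
    return classify(vector, table)


def classify_msa(
    msa,
    table: SignatureTable | None = None,
    offset: int = 0,
) -> list[ClassificationResult]:
    """Classify rows of an alignment whose columns are reference coordinates.

    Used for clade alignments already numbered in NOX2 coordinates (for
    instance generator output, where column i is reference position i once
    ``offset`` accounts for any N-terminal extension). Gap or ambiguity
    letters at a signature position count as absent. This bypasses pairwise
    realignment, which cannot recover residue register against sequences
    whose background shares no homology with the reference.
    """
    table = table or default_signature_table()
    results = []
    for record in msa.records:
        residues: dict[int, str | None] = {}
        for pos in table.positions:
            col = pos + offset
            letter = record.sequence[col - 1] if col <= len(record.sequence) else None
            residues[pos] = letter if letter in CANONICAL_LETTERS else None
        vector = ResidueVector(query_id=record.id, residues=residues)
        results.append(classify(vector, table))
    return results


def classify_fasta(
    records: Iterable[ProteinRecord],
    annotation: ReferenceAnnotation | None = None,
    table: SignatureTable | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[ClassificationResult]:
    """Classify every record against the NOX2 reference."""
    annotation = annotation or load_nox2_reference()
    table = table or default_signature_table()
    return [classify_record(r, annotation, table, scheme) for r in records]
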