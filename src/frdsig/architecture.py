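"""EF-hand detection and domain-architecture categorisation.

Long-form superfamily members share a structural core of the transmembrane
ferric reductase domain followed by cytoplasmic FAD- and NADPH-binding
domains; accessory modules (EF-hands, peroxidase-like domain, DOMON, extra
TM segments, organiser domains) are generally fused N-terminally of that
core. The rule cascade below reproduces that architecture taxonomy at a
coarse nine-category level.

EF-hands are found with a transparent positional rule over the canonical
12-residue Ca2+-binding loop: position 1 = D, 3 in {D,N,S}, 5 in
{D,E,N,S,T,G}, 6 in {D,N,Q,G,H,R,K}, 9 in {D,E,N,Q,S,T,A,G,C}, 12 in {D,E},
no proline at 7. A loop matching all six residue classes is flagged
canonical; one matching five of six is reported as a relaxed (non-canonical)
hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import DomainHit, ProteinRecord

logger = logging.getLogger(__name__)

EF_LOOP_LENGTH = 12

#: Constrained loop positions (1-based within the loop) and allowed residues.
EF_LOOP_CLASSES: dict[int, frozenset[str]] = {
    1: frozenset("D"),
    3: frozenset("DNS"),
    5: frozenset("DENSTG"),
    6: frozenset("DNQGHRK"),
    9: frozenset("DENQSTAGC"),
    12: frozenset("DE"),
}


@dataclass
class EFHandHit:
    """One 12-residue Ca-binding loop (1-based inclusive coordinates)."""

    start: int
    end: int
    canonical: bool

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != EF_LOOP_LENGTH:
            raise ValueError("EF-hand loop must span exactly 12 residues")


def _loop_class_matches(window: str) -> int:
    return sum(1 for pos, allowed in EF_LOOP_CLASSES.items() if window[pos - 1] in allowed)


def detect_ef_hands(seq: str | ProteinRecord) -> list[EFHandHit]:
    """Scan for Ca-binding loops, greedily and non-overlapping left-to-right."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else str(seq).upper()
    hits: list[EFHandHit] = []
    i = 0
    while i + EF_LOOP_LENGTH <= len(s):
        window = s[i : i + EF_LOOP_LENGTH]
        if window[6] != "P":  # no proline at loop position 7
            matches = _loop_class_matches(window)
            if matches >= 5:
                hits.append(
                    EFHandHit(
                        start=i + 1,
                        end=i + EF_LOOP_LENGTH,
                        canonical=matches == len(EF_LOOP_CLASSES),
                    )
                )
                i += EF_LOOP_LENGTH
                continue
        i += 1
    return hits


CATEGORY_FRD_ONLY = "FRD-only"
CATEGORY_CORE_TRIAD = "bacterial-long/core-triad"
CATEGORY_STEAP24 = "STEAP2-4-like"
CATEGORY_NOX_EF = "NOX-EF"
CATEGORY_DUOX = "DUOX-like"
CATEGORY_RBOH = "RBOH-like"
CATEGORY_FRE_DOMON = "FRE+DOMON"
CATEGORY_FUFRE = "fuFRE-like"
CATEGORY_NOVEL = "unclassified-novel"

CORE_DOMAINS = ("FRD", "FAD_binding", "NADPH_binding")


@dataclass
class ArchitectureCall:
    """Architecture category for one sequence, with the ordered domain list."""

    seq_id: str
    category: str
    evidence: list[str]
    ef_hand_count: int

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureCall":
        return cls(
            seq_id=d["seq_id"],
            category=d["category"],
            evidence=list(d["evidence"]),
            ef_hand_count=int(d["ef_hand_count"]),
        )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def classify_architecture(
    hits: list[DomainHit],
    ef: list[EFHandHit] | None = None,
    seq_length: int | None = None,
) -> ArchitectureCall:
    """Assign one of nine architecture categories from N-to-C domain order.

    ``hits`` must all belong to one sequence. EF-hand evidence can come from
    ``EF_hand`` domain hits, from ``ef`` (sequence-scan hits), or both;
    overlapping EF intervals are merged before counting. Only canonical EF
    evidence (domain hits, or scan hits matching all six loop classes) drives
    the category rules — relaxed scan hits contribute to ``ef_hand_count``
    but are too unspecific to re-route an architecture. Predicted extra TM
    segments lying inside the NADPH-binding domain are ignored (such
    predictions are artifacts of the hydrophobic sheet core of that domain).
    """
    ef = ef or []
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits belong to multiple sequences: {sorted(seq_ids)}")
    seq_id = hits[0].seq_id if hits else "unknown"

    nadph_intervals = [
        (h.start, h.end) for h in hits if h.domain_name == "NADPH_binding"
    ]
    elements: list[tuple[int, str]] = []
    for h in hits:
        if h.domain_name == "EF_hand":
            continue  # folded into the merged EF intervals below
        if h.domain_name == "TM_extra" and any(
            s <= h.start and h.end <= e for s, e in nadph_intervals
        ):
            continue
        elements.append((h.start, h.domain_name))
    domain_ef = [(h.start, h.end) for h in hits if h.domain_name == "EF_hand"]
    canonical_ef = _merge_intervals(
        domain_ef + [(h.start, h.end) for h in ef if h.canonical]
    )
    all_ef = _merge_intervals(domain_ef + [(h.start, h.end) for h in ef])
    ef_count = len(all_ef)
    elements.extend((start, "EF_hand") for start, _ in canonical_ef)
    elements.sort()
    names = [name for _, name in elements]

    def first_start(name: str) -> int | None:
        for start, n in elements:
            if n == name:
                return start
        return None

    frd = first_start("FRD")
    category = CATEGORY_NOVEL
    warning = None

    core_ordered = _core_triad_ordered(elements)
    if names == ["FRD"]:
        category = CATEGORY_FRD_ONLY
    elif frd is not None and _before(elements, "NADP_F420", frd):
        category = CATEGORY_STEAP24
    elif core_ordered:
        perox = first_start("peroxidase_like")
        tm_extra = first_start("TM_extra")
        sh3 = first_start("SH3")
        ef_first = first_start("EF_hand")
        pre_core_anchor = ef_first if ef_first is not None else frd
        if (
            perox is not None
            and tm_extra is not None
            and perox < tm_extra < pre_core_anchor
        ):
            category = CATEGORY_DUOX
        elif sh3 is not None and ef_first is not None and sh3 < ef_first < frd:
            category = CATEGORY_RBOH
        elif ef_first is not None and ef_first < frd:
            category = CATEGORY_NOX_EF
        elif _before(elements, "DOMON", frd):
            category = CATEGORY_FRE_DOMON
        elif names == list(CORE_DOMAINS):
            category = CATEGORY_CORE_TRIAD
        elif (
            ef_first is None
            and names.index("FRD") > 0
            and names[names.index("FRD") - 1] == "TM_extra"
        ):
            category = CATEGORY_FUFRE
    elif _core_contradictory(elements):
        warning = "overlapping core domains in contradictory order"

    if warning:
        logger.warning("%s: %s", seq_id, warning)
    return ArchitectureCall(
        seq_id=seq_id, category=category, evidence=names, ef_hand_count=ef_count
    )


def _before(elements: list[tuple[int, str]], name: str, position: int) -> bool:
    return any(n == name and start < position for start, n in elements)


def _core_triad_ordered(elements: list[tuple[int, str]]) -> bool:
    """True when FRD, FAD_binding, NADPH_binding occur in N->C order."""
    pos = -1
    for domain in CORE_DOMAINS:
        starts = [s for s, n in elements if n == domain and s > pos]
        if not starts:
            return False
        pos = min(starts)
    return True


def _core_contradictory(elements: list[tuple[int, str]]) -> bool:
    present = {n for _, n in elements if n in CORE_DOMAINS}
    return len(present) >= 2 and not _core_triad_ordered(elements)


def annotate_architecture(
    record: ProteinRecord, hits: list[DomainHit]
) -> ArchitectureCall:
    """Run the EF-hand scan on a sequence and classify its architecture."""
    ef = detect_ef_hands(record)
    return classify_architecture(hits, ef=ef, seq_length=len(record.sequence))
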