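"""Domain types and readers/writers shared by the whole toolkit.

Sequence containers (:class:`ProteinRecord`, :class:`Msa`), Pfam-style domain-hit
tables (:class:`DomainHit`) and the result serialisation helpers live here.
Coordinates are 1-based and inclusive throughout the package, matching the
His-101-style residue numbering used for the human NOX2 reference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/rare letters retained in sequences but excluded from frequency counts.
AMBIGUOUS_AA = "XBZU"
GAP_CHAR = "-"
VALID_LETTERS = frozenset(CANONICAL_AA + AMBIGUOUS_AA + GAP_CHAR)

#: Controlled vocabulary for domain-hit names (Pfam-scan-shaped tables).
DOMAIN_VOCABULARY = frozenset(
    {
        "FRD",
        "FAD_binding",
        "NADPH_binding",
        "EF_hand",
        "peroxidase_like",
        "DOMON",
        "NADP_F420",
        "TM_extra",
        "SH3",
        "other",
    }
)

#: Pfam accessions of the superfamily's recurring domains mapped to the vocabulary.
PFAM_ALIASES = {
    "PF01794": "FRD",
    "PF08022": "FAD_binding",
    "PF08030": "NADPH_binding",
    "PF03807": "NADP_F420",
    "PF03098": "peroxidase_like",
    "PF03351": "DOMON",
    "PF00018": "SH3",
}


@dataclass
class ProteinRecord:
    """One identified amino-acid sequence, optionally with a clade truth label.

    The sequence is upper-cased on construction and terminal ``*`` stop symbols
    are stripped; letters outside the canonical 20 + X/B/Z/U + gap raise.
    """

    id: str
    sequence: str
    description: str = ""
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty without whitespace: {self.id!r}")
        seq = self.sequence.upper().strip("*")
        if not seq:
            raise ValueError(f"record {self.id!r}: sequence is empty")
        bad = set(seq) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid letters {sorted(bad)!r} in sequence"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    def degapped(self) -> "ProteinRecord":
        """Return a copy with all gap characters removed."""
        return dataclasses.replace(self, sequence=self.sequence.replace(GAP_CHAR, ""))

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]


@dataclass
class Msa:
    """A multiple sequence alignment: equally long rows with unique ids."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        n = len(self.records[0].sequence)
        if n < 1:
            raise ValueError("alignment has zero columns")
        for rec in self.records:
            if len(rec.sequence) != n:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.sequence)}, expected {n}"
                )
        _check_unique_ids(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Letters of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(rec.sequence[col - 1] for rec in self.records)


@dataclass
class DomainHit:
    """One domain hit on a named sequence (1-based inclusive coordinates)."""

    seq_id: str
    domain_name: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain_name not in DOMAIN_VOCABULARY:
            raise ValueError(f"unknown domain name {self.domain_name!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for {self.seq_id!r}"
            )


def _check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path, aligned: bool = False) -> list[ProteinRecord] | Msa:
    """Read a FASTA file into records (or an :class:`Msa` when ``aligned``).

    Records are returned in file order; lower-case letters are upper-cased and
    terminal ``*`` stripped. An empty file raises ``ValueError("no records")``;
    a ragged aligned file raises naming the offending id.
    """
    path = Path(path)
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in {path}")
    _check_unique_ids(records)
    if aligned:
        return Msa(records)
    return records


def write_fasta(records: Iterable[ProteinRecord] | Msa, path: str | Path) -> Path:
    """Write records (or an alignment's rows) as FASTA."""
    if isinstance(records, Msa):
        records = records.records
    records = list(records)
    if not records:
        raise ValueError("nothing to write")
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    SeqIO.write(seqs, str(path), "fasta")
    return path


DOMAIN_TSV_COLUMNS = ["seq_id", "domain_name", "start", "end", "source"]


def read_domain_hits(
    path: str | Path,
    sequence_lengths: dict[str, int] | None = None,
) -> list[DomainHit]:
    """Read a domain-hit TSV (header seq_id, domain_name, start, end, source).

    Pfam accessions from the alias table are translated to the controlled
    vocabulary; other unknown names map to ``"other"`` with a logged warning.
    Hits are returned sorted by (seq_id, start). When ``sequence_lengths`` is
    given, hits extending past the named sequence raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in DOMAIN_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain TSV missing columns: {missing}")
    hits: list[DomainHit] = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-integer coordinates for {row.seq_id!r}: "
                f"{row.start!r}..{row.end!r}"
            ) from exc
        name = row.domain_name
        if name not in DOMAIN_VOCABULARY:
            mapped = PFAM_ALIASES.get(name)
            if mapped is None:
                logger.warning(
                    "unknown domain name %r on %r mapped to 'other'", name, row.seq_id
                )
                mapped = "other"
            name = mapped
        hit = DomainHit(
            seq_id=row.seq_id, domain_name=name, start=start, end=end, source=row.source
        )
        if sequence_lengths is not None:
            length = sequence_lengths.get(hit.seq_id)
            if length is not None and hit.end > length:
                raise ValueError(
                    f"hit {hit.domain_name} {hit.start}..{hit.end} exceeds length "
                    f"{length} of {hit.seq_id!r}"
                )
        hits.append(hit)
    hits.sort(key=lambda h: (h.seq_id, h.start))
    return hits


def write_domain_hits(hits: Sequence[DomainHit], path: str | Path) -> Path:
    """Write domain hits as a TSV with the canonical header."""
    if not hits:
        raise ValueError("nothing to write")
    df = pd.DataFrame([dataclasses.asdict(h) for h in hits], columns=DOMAIN_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_results(results: Sequence, path: str | Path, format: str = "tsv") -> Path:
    """Write a non-empty list of result dataclasses as TSV or JSON.

    Column order is the dataclass field order, so output is deterministic.
    JSON output round-trips through :func:`read_results`.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to write")
    dicts = [_result_to_dict(r) for r in results]
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(dicts, columns=list(dicts[0].keys()))
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dicts, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_results(path: str | Path, cls=None) -> list:
    """Read a JSON result file back; with ``cls`` given, rebuild dataclasses.

    ``cls`` must offer a ``from_dict`` classmethod (the result types in this
    package all do).
    """
    with open(path, encoding="utf-8") as fh:
        dicts = json.load(fh)
    if cls is None:
        return dicts
    return [cls.from_dict(d) for d in dicts]


def _result_to_dict(result) -> dict:
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    if isinstance(result, dict):
        return dict(result)
    raise TypeError(f"cannot serialise result of type {type(result)!r}")
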