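"""Per-column conservation statistics for clade alignments.

For every alignment column we compute residue frequencies over the 20
canonical letters (gaps and ambiguity letters X/B/Z/U are excluded from the
counts but gaps are tracked as a separate fraction), the Shannon entropy H of
that distribution, and the sequence-logo information content

    R = log2(20) - H            (bits, in [0, log2 20])

which is the stack height of a standard protein sequence logo. An optional
small-sample correction e(n) = 19 / (2 ln 2 n) may be subtracted. Columns in
which more than half of the rows are gaps are flagged low-confidence but
retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CANONICAL_AA, GAP_CHAR, Msa

MAX_BITS = math.log2(20.0)


@dataclass
class ColumnProfile:
    """Residue distribution of one alignment column.

    frequencies map canonical residues to fractions of the counted (non-gap,
    non-ambiguous) letters and sum to 1 when anything was counted; consensus
    is the most frequent residue with alphabetical tie-break, or None for an
    all-gap/all-ambiguous column.
    """

    frequencies: dict[str, float]
    gap_fraction: float
    n_effective: int
    consensus: str | None


@dataclass
class ConservationProfile:
    """Column-wise conservation summary of one clade alignment."""

    clade: str
    columns: list[ColumnProfile]
    information: list[float]
    low_confidence: list[bool] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def consensus_sequence(self, placeholder: str = "X") -> str:
        """Consensus residue per column; ``placeholder`` where none exists."""
        return "".join(c.consensus or placeholder for c in self.columns)


def column_frequencies(msa: Msa, col: int) -> ColumnProfile:
    """Profile 1-based column ``col``: frequencies over canonical letters only."""
    letters = msa.column(col)
    n_rows = len(letters)
    counts: dict[str, int] = {}
    gaps = 0
    for letter in letters:
        if letter == GAP_CHAR:
            gaps += 1
        elif letter in CANONICAL_AA:
            counts[letter] = counts.get(letter, 0) + 1
        # ambiguity letters are treated as missing
    n_eff = sum(counts.values())
    if n_eff:
        freqs = {aa: counts[aa] / n_eff for aa in sorted(counts)}
        top = max(freqs.values())
        consensus = min(aa for aa, f in freqs.items() if f == top)
    else:
        freqs, consensus = {}, None
    return ColumnProfile(
        frequencies=freqs,
        gap_fraction=gaps / n_rows,
        n_effective=n_eff,
        consensus=consensus,
    )


def information_content(
    profile: ColumnProfile, small_sample_correction: bool = False
) -> float:
    """Logo information content of a column, in bits.

    R = log2(20) - H over the observed frequencies; 0 for an empty column.
    With ``small_sample_correction`` the estimator bias term
    e(n) = 19/(2 ln 2 n) is subtracted as well (clamped at 0).
    """
    if profile.n_effective == 0:
        return 0.0
    entropy = -sum(p * math.log2(p) for p in profile.frequencies.values() if p > 0)
    bits = MAX_BITS - entropy
    if small_sample_correction:
        bits -= (len(CANONICAL_AA) - 1) / (2 * math.log(2) * profile.n_effective)
    return max(0.0, bits)


LOW_CONFIDENCE_GAP_FRACTION = 0.5


def profile_msa(
    msa: Msa, clade: str, small_sample_correction: bool = False
) -> ConservationProfile:
    """Profile every column of a clade alignment (requires >= 2 rows).

    Columns with gap fraction above 0.5 are flagged low-confidence but kept,
    mirroring how unreliable alignment regions are down-weighted rather than
    re-scored.
    """
    if msa.n_rows < 2:
        raise ValueError("profile requires >=2 sequences")
    columns = [column_frequencies(msa, c) for c in range(1, msa.n_columns + 1)]
    information = [
        information_content(c, small_sample_correction=small_sample_correction)
        for c in columns
    ]
    low_conf = [c.gap_fraction > LOW_CONFIDENCE_GAP_FRACTION for c in columns]
    return ConservationProfile(
        clade=clade, columns=columns, information=information, low_confidence=low_conf
    )


_LOGO_META_COLUMNS = ["column", "information", "gap_fraction", "low_confidence"]


def export_logo_data(profile: ConservationProfile, path: str | Path) -> Path:
    """Write per-column logo data (frequencies, IC, gap fraction, flag) as TSV."""
    if not profile.columns:
        raise ValueError("nothing to write")
    rows = []
    for i, (col, ic, flag) in enumerate(
        zip(profile.columns, profile.information, profile.low_confidence), start=1
    ):
        row: dict[str, object] = {"column": i}
        for aa in CANONICAL_AA:
            row[aa] = col.frequencies.get(aa, 0.0)
        row["information"] = ic
        row["gap_fraction"] = col.gap_fraction
        row["low_confidence"] = flag
        rows.append(row)
    df = pd.DataFrame(rows, columns=["column", *CANONICAL_AA, "information", "gap_fraction", "low_confidence"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def parse_logo_data(path: str | Path, clade: str = "") -> ConservationProfile:
    """Read a logo-data TSV back into a :class:`ConservationProfile`.

    Consensus and n_effective are not stored in the TSV; consensus is rebuilt
    from the frequencies and n_effective is left at 0.
    """
    df = pd.read_csv(path, sep="\t")
    columns: list[ColumnProfile] = []
    for _, row in df.iterrows():
        freqs = {aa: float(row[aa]) for aa in CANONICAL_AA if float(row[aa]) > 0}
        if freqs:
            top = max(freqs.values())
            consensus = min(aa for aa, f in freqs.items() if f == top)
        else:
            consensus = None
        columns.append(
            ColumnProfile(
                frequencies=freqs,
                gap_fraction=float(row["gap_fraction"]),
                n_effective=0,
                consensus=consensus,
            )
        )
    return ConservationProfile(
        clade=clade,
        columns=columns,
        information=[float(v) for v in df["information"]],
        low_confidence=[bool(v) for v in df["low_confidence"]],
    )
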