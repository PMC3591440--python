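"""Seeded generator of clade-structured protein families with planted signatures.

Each clade is generated from a :class:`CladeTemplate`: a shared random
scaffold (uniform canonical background, hydrophobic alphabet inside the TM
windows), the clade's expected residues planted at the NOX2 reference
positions, optional canonical EF-hand loops on an N-terminal extension, and
a domain layout used to emit a matching domain-hit table. Per-site
substitution noise and deletion-style indels are then applied row by row.

The planted residues are drawn from the same signature table the classifier
uses, so generator truth and classification rules share one source. A single
integer seed drives everything; per-clade noise streams are sub-seeded
(seed + clade index) so adding a clade does not perturb earlier clades.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CANONICAL_AA,
    DomainHit,
    GAP_CHAR,
    Msa,
    ProteinRecord,
    write_domain_hits,
    write_fasta,
)
from .signatures import (
    ANY,
    LABEL_FRE,
    LABEL_NOX,
    LABEL_PRENOX,
    LABEL_YEDZ_STEAP,
    SUBTYPE_STEAP24,
    SUBTYPE_YEDZ_STEAP1,
    default_signature_table,
)

#: Hydrophobic alphabet used inside transmembrane windows.
TM_ALPHABET = "ILVFAM"

#: Default TM windows (NOX2-like coordinates) covering the planted positions.
DEFAULT_TM_WINDOWS = ((96, 121), (168, 193), (202, 228))

#: Canonical 12-residue Ca-binding loops planted as EF-hands (calmodulin-type).
EF_LOOP_SEQUENCES = (
    "DKDGDGTITTKE",
    "DADGNGTIDFPE",
    "DKDGNGYISAAE",
    "DIDGDGQVNYEE",
)


@dataclass
class CladeTemplate:
    """Blueprint for one synthetic clade."""

    name: str
    planted: dict[int, str]
    scaffold_length: int = 570
    tm_windows: tuple[tuple[int, int], ...] = DEFAULT_TM_WINDOWS
    ef_loops: tuple[int, ...] = ()  # loop start positions (absolute, 1-based)
    domain_layout: tuple[tuple[str, int, int], ...] = ()
    nterm_extension: int = 0

    @property
    def total_length(self) -> int:
        return self.scaffold_length + self.nterm_extension

    def __post_init__(self) -> None:
        for pos in self.planted:
            if not 1 <= pos + self.nterm_extension <= self.total_length:
                raise ValueError(f"planted position {pos} outside template")
        starts = [s for _, s, _ in self.domain_layout]
        ends = [e for _, _, e in self.domain_layout]
        for (s1, e1), (s2, _) in zip(zip(starts, ends), zip(starts[1:], ends[1:])):
            if s2 <= e1:
                raise ValueError("domain layout intervals overlap or are unordered")

    def planted_columns(self) -> dict[int, str]:
        """Planted residues keyed by absolute scaffold column."""
        return {
            pos + self.nterm_extension: residue for pos, residue in self.planted.items()
        }


@dataclass
class GeneratorConfig:
    """Noise model and size of a generated family; the seed is mandatory."""

    seed: int
    n_per_clade: int = 200
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    protect_planted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise ValueError("substitution_rate outside [0, 0.2]")
        if not 0.0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate outside [0, 0.05]")
        if self.n_per_clade < 1:
            raise ValueError("n_per_clade must be >= 1")


def _planted_from_table(clade: str) -> dict[int, str]:
    """Concrete planted residues for a signature-table clade profile.

    Wildcards and negations are instantiated once with fixed representative
    residues (the non-NOX triplet of the metalloreductase-like clades), so
    the generated truth stays aligned with the classifier's rule table.
    """
    table = default_signature_table()
    fallback = {119: "F", 178: "S", 179: "A"}
    if clade == "preNOX":
        fallback = {119: "Y"}
    if clade.startswith("YedZ") or clade.startswith("STEAP"):
        fallback = {119: "L", 178: "S", 179: "A"}
    planted: dict[int, str] = {}
    for pos in table.positions:
        expected = table.expected(clade, pos)
        if expected == ANY or expected.startswith("!"):
            planted[pos] = fallback[pos]
        else:
            planted[pos] = expected
    return planted


_CORE_TRIAD_LAYOUT = (
    ("FRD", 46, 300),
    ("FAD_binding", 320, 430),
    ("NADPH_binding", 440, 560),
)


def default_templates() -> list[CladeTemplate]:
    """The five benchmark clades: NOX, preNOX, FRE, YedZ/STEAP1, STEAP2-4."""
    return [
        CladeTemplate(
            name="NOX", planted=_planted_from_table("NOX"), domain_layout=_CORE_TRIAD_LAYOUT
        ),
        CladeTemplate(
            name="preNOX",
            planted=_planted_from_table("preNOX"),
            domain_layout=_CORE_TRIAD_LAYOUT,
        ),
        CladeTemplate(
            name="FRE", planted=_planted_from_table("FRE"), domain_layout=_CORE_TRIAD_LAYOUT
        ),
        CladeTemplate(
            name="YedZ_STEAP1",
            planted=_planted_from_table("YedZ/STEAP1"),
            domain_layout=(("FRD", 46, 300),),
        ),
        CladeTemplate(
            name="STEAP2_4",
            planted=_planted_from_table("STEAP2-4"),
            domain_layout=(("NADP_F420", 2, 44), ("FRD", 46, 300)),
        ),
    ]


def nox_ef_template(n_loops: int = 2) -> CladeTemplate:
    """A NOX-EF clade: EF-hand loops on a 120-residue N-terminal extension."""
    if not 1 <= n_loops <= len(EF_LOOP_SEQUENCES):
        raise ValueError("n_loops outside the available loop set")
    loop_starts = tuple(20 + 30 * i for i in range(n_loops))
    layout = tuple(
        [("EF_hand", s, s + 11) for s in loop_starts]
        + [(name, start + 120, end + 120) for name, start, end in _CORE_TRIAD_LAYOUT]
    )
    return CladeTemplate(
        name="NOX_EF",
        planted=_planted_from_table("NOX"),
        nterm_extension=120,
        ef_loops=loop_starts,
        domain_layout=layout,
    )


#: Expected classifier output per default template name.
EXPECTED_LABELS: dict[str, tuple[str, str | None]] = {
    "NOX": (LABEL_NOX, None),
    "preNOX": (LABEL_PRENOX, None),
    "FRE": (LABEL_FRE, None),
    "YedZ_STEAP1": (LABEL_YEDZ_STEAP, SUBTYPE_YEDZ_STEAP1),
    "STEAP2_4": (LABEL_YEDZ_STEAP, SUBTYPE_STEAP24),
    "NOX_EF": (LABEL_NOX, None),
}


def build_scaffold(template: CladeTemplate, rng: np.random.Generator) -> str:
    """Draw the clade scaffold: uniform background, hydrophobic TM windows,
    EF loops written at their insertion sites, planted residues set last.

    The random draws depend only on the scaffold geometry (length and TM
    windows), so clades sharing that geometry share their background.
    """
    length = template.total_length
    letters = list(rng.choice(list(CANONICAL_AA), size=length))
    offset = template.nterm_extension
    for start, end in template.tm_windows:
        lo, hi = start + offset, min(end + offset, length)
        tm = rng.choice(list(TM_ALPHABET), size=hi - lo + 1)
        letters[lo - 1 : hi] = list(tm)
    for i, loop_start in enumerate(template.ef_loops):
        loop = EF_LOOP_SEQUENCES[i % len(EF_LOOP_SEQUENCES)]
        letters[loop_start - 1 : loop_start - 1 + len(loop)] = list(loop)
    for col, residue in template.planted_columns().items():
        letters[col - 1] = residue
    return "".join(letters)


def _protected_columns(template: CladeTemplate) -> set[int]:
    cols = set(template.planted_columns())
    for loop_start in template.ef_loops:
        cols.update(range(loop_start, loop_start + 12))
    return cols


def generate_family(
    template: CladeTemplate,
    config: GeneratorConfig,
    stream_offset: int = 0,
    scaffold: str | None = None,
) -> tuple[Msa, list[dict]]:
    """Generate one clade family as an alignment plus truth rows.

    Substitutions replace a residue by a uniformly chosen different canonical
    residue with probability ``substitution_rate``; deletions (gap characters)
    occur at ``indel_rate``. Planted residues and EF loops are skipped when
    ``protect_planted`` is set, and deletions never open at planted columns.
    Fully reproducible from the seed; ``stream_offset`` sub-seeds the noise
    stream (benchmarks use seed + clade index).
    """
    if scaffold is None:
        scaffold = build_scaffold(template, np.random.default_rng(config.seed))
    noise_rng = np.random.default_rng(config.seed + stream_offset)
    protected = _protected_columns(template)
    length = len(scaffold)
    planted_str = ",".join(
        f"{pos}={res}" for pos, res in sorted(template.planted.items())
    )
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    aa = np.array(list(CANONICAL_AA))
    for i in range(config.n_per_clade):
        letters = np.array(list(scaffold))
        sub_mask = noise_rng.random(length) < config.substitution_rate
        del_mask = noise_rng.random(length) < config.indel_rate
        replacements = aa[noise_rng.integers(0, len(aa), size=length)]
        shifts = noise_rng.integers(1, len(aa), size=length)
        for col in np.nonzero(sub_mask)[0]:
            if config.protect_planted and (col + 1) in protected:
                continue
            current = letters[col]
            idx = CANONICAL_AA.find(current)
            if idx < 0:
                letters[col] = replacements[col]
            else:
                letters[col] = aa[(idx + shifts[col]) % len(aa)]
        for col in np.nonzero(del_mask)[0]:
            if (col + 1) in protected:
                continue
            letters[col] = GAP_CHAR
        seq_id = f"{template.name}_{i:04d}"
        records.append(
            ProteinRecord(
                id=seq_id,
                sequence="".join(letters),
                truth_label=template.name,
            )
        )
        truth_rows.append(
            {"seq_id": seq_id, "clade": template.name, "planted": planted_str}
        )
    return Msa(records), truth_rows


def domain_hits_for(template: CladeTemplate, seq_id: str) -> list[DomainHit]:
    """Domain hits matching a template's layout, for one generated sequence."""
    return [
        DomainHit(seq_id=seq_id, domain_name=name, start=start, end=end, source="template")
        for name, start, end in template.domain_layout
    ]


def generate_benchmark(
    config: GeneratorConfig,
    clades: list[CladeTemplate] | None = None,
    outdir: str | Path = ".",
) -> dict[str, Path]:
    """Write a complete clade benchmark to ``outdir``.

    Outputs per-clade aligned FASTA, a pooled degapped FASTA, a truth TSV, a
    domain-hit TSV consistent with each template's layout, and a manifest
    JSON recording the configuration. Identical configs give identical bytes.
    """
    clades = clades if clades is not None else default_templates()
    if len(clades) < 2:
        raise ValueError("benchmark needs >= 2 clades")
    names = [t.name for t in clades]
    if len(set(names)) != len(names):
        raise ValueError("duplicate clade names")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    pooled: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    domain_rows: list[DomainHit] = []
    for index, template in enumerate(clades):
        msa, rows = generate_family(template, config, stream_offset=index + 1)
        truth_rows.extend(rows)
        path = outdir / f"{template.name}.aln.fasta"
        write_fasta(msa, path)
        paths[f"msa:{template.name}"] = path
        for rec in msa.records:
            pooled.append(rec.degapped())
            domain_rows.extend(domain_hits_for(template, rec.id))

    paths["pool"] = write_fasta(pooled, outdir / "pool.fasta")
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows, columns=["seq_id", "clade", "planted"]).to_csv(
        truth_path, sep="\t", index=False
    )
    paths["truth"] = truth_path
    paths["domains"] = write_domain_hits(domain_rows, outdir / "domains.tsv")

    manifest = {
        "tool": "frdsig",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "clades": [
            {
                "name": t.name,
                "scaffold_length": t.scaffold_length,
                "nterm_extension": t.nterm_extension,
                "n_planted": len(t.planted),
                "ef_loops": list(t.ef_loops),
            }
            for t in clades
        ],
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths
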