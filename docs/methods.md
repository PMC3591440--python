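# Methods

## Scope and model

`frdsig` treats clade membership in the ferric reductase domain (FRD)
superfamily as a positional signature problem: a small set of residues, read
in human NOX2 coordinates, separates the major functional groups. The
package implements the four stages of that analysis — conservation
profiling, reference-coordinate mapping, rule-based classification and
signature discovery — plus domain-architecture categorisation and a
synthetic generator that makes each stage testable at desk scale. Tree
inference, redundancy filtering and external predictors (TMHMM-class tools,
SignalP, Pfam scans) are out of scope; domain hits enter through a plain
TSV with the shape of a Pfam/InterPro export.

## Conservation statistic

For an alignment column with residue distribution `p` over the 20 canonical
amino acids, the information content is the standard logo statistic

    R = log2(20) − H,   H = −Σᵢ pᵢ log2 pᵢ   (bits)

so `R ∈ [0, log2 20 ≈ 4.32]`. Gaps are excluded from the frequencies but
tracked as a per-column gap fraction; ambiguity letters X/B/Z/U are treated
as missing data so that entropy stays defined over the 20-letter alphabet.
Columns with gap fraction > 0.5 are flagged low-confidence and retained.
No small-sample correction is applied by default (determinism and
closed-form testability); the bias term `e(n) = 19/(2 ln 2 · n)` can be
subtracted via `small_sample_correction=True`. Sequences are not weighted
for redundancy; profiles of heavily redundant alignments will overstate
conservation accordingly. Consensus ties break alphabetically.

## Reference mapping

Queries are aligned to the bundled human NOX2 sequence with global
Needleman–Wunsch under BLOSUM62 and affine gaps costing
`gap_open + k·gap_extend` for a gap of length k (defaults 11/1, the common
convention; no aligner is prescribed for this task by the source analysis).
Ambiguity letters score 0 against everything. The dynamic program is
provided by Biopython's `PairwiseAligner`; among co-optimal tracebacks the
first reported alignment is used, which is deterministic for fixed inputs
(score optimality, the property the oracle tests check, is unaffected by
tie order). Match columns yield a strictly monotone (query, reference)
position map; reference positions falling in query gaps are reported
absent rather than interpolated.

The NOX2 fixture reproduces the 570-residue human NOX2 (CYBB) sequence and
is validated at load time at the seven landmark positions (His-101,
His-115, His-119, Thr-178, Gly-179, His-209, His-222). TM3/TM4/TM5 windows
are estimated once from a Kyte–Doolittle scan (window 19, threshold 1.6)
and attached to the annotation for reporting only; hydropathy means dip
near the heme histidines, so these windows are approximate by construction
and classification never consults them.

## Classification cascade

The classifier is a total, deterministic rule cascade over the residues at
positions 101, 115, 119, 178, 179, 209, 222:

1. **Arg-101 → YedZ/STEAP.** The arginine replacing the first canonical
   heme histidine is the sharpest single diagnostic, so it is tested first;
   His-209 selects the YedZ/STEAP1-like subtype, anything else (typically
   the conserved glutamine) STEAP2-4-like. The glutamine corroborates but
   is not required, since it is well-conserved rather than universal.
2. **Thr-178/Gly-179 dipeptide intact and His-101:** with His-119 present
   the call is NOX-group; without His-119 it is preNOX-like. His-115 is
   deliberately not required for the NOX call, tolerating one mutated heme
   site (inparalogs with a degraded site still classify as NOX). Requiring
   His-119 is what keeps NOX and preNOX separable: a tolerance rule that
   accepts three of {His-115, His-119, Thr-178, Gly-179} would make the
   preNOX profile itself satisfy the NOX branch, so the package resolves
   the tolerance in favour of His-115 only.
3. **Dipeptide intact with His-101 or His-115 → preNOX-like**, covering the
   green-algal variant that lacks both His-115 and His-119.
4. **≥ 3 canonical heme histidines → FRE-group.**
5. **Fallback: ambiguous** (total function; all-absent vectors land here).

`heme_histidine_count` counts histidines at {101, 115, 209, 222} only. The
NOX-distinguishing motif is never stored as a constant: `nox_call_positions`
recovers it ({101, 119, 178, 179}, size 4) by single-position perturbation
of the NOX consensus vector.

Two classification entry points exist. `classify_record`/`classify_fasta`
align each (degapped) query to NOX2 and extract the residue vector through
the position map — the path for real homologs, which share the reference's
conserved core. `classify_msa` reads residues directly from alignments
whose columns already are reference coordinates (generator output, curated
reference-frame alignments). The distinction matters for the synthetic
benchmark: its scaffold background is uniform random by design, so a
global alignment against NOX2 has no homology to anchor to outside the
planted sites and cannot reliably recover residue register under noise.
Benchmark accuracies are therefore measured in the generator's own
coordinate frame, while the alignment-based path is validated on
constructions derived from the real NOX2 sequence (self-alignment,
N-terminal extensions). Passing benchmarks consequently demonstrate the
correctness of the rule system and coordinate bookkeeping, not alignment
robustness on non-homologous backgrounds.

## Signature discovery

`discover_signatures` reports every reference position where clade A's
consensus residue has frequency ≥ `f_cons` while that same residue stays at
frequency ≤ `f_bg` in clade B. Defaults `f_cons = 0.8`, `f_bg = 0.3` are
package choices (no thresholds are printed in the source analysis), set so
that planted sites remain recoverable at a 5% substitution rate with
families of 50 sequences, and both are exposed as CLI flags. `f_cons ≤ f_bg`
is rejected as non-separating. The screen is one-directional; swapping the
clades reports the mirrored conserved-residue contrasts.

## EF-hands and architectures

EF-hands are detected with a transparent positional rule over the canonical
12-residue Ca²⁺-binding loop: position 1 = D; 3 ∈ {D,N,S}; 5 ∈ {D,E,N,S,T,G};
6 ∈ {D,N,Q,G,H,R,K}; 9 ∈ {D,E,N,Q,S,T,A,G,C}; 12 ∈ {D,E}; no proline at 7.
All six classes matching makes a canonical hit; five of six a relaxed one.
Scanning is greedy, left-to-right, non-overlapping. Relaxed hits occur on
random sequence at roughly 10⁻³ per position, so they contribute to
`ef_hand_count` but do not drive architecture rules, which use canonical
hits and explicit `EF_hand` table entries only. A deterministic rule was
preferred over a profile search because it is auditable and exactly
testable; it will miss divergent loops a profile HMM would find.

Architecture categories are assigned by the first matching rule on N→C
domain order, with the more specific accessory patterns tested before the
plain EF case: FRD-only; STEAP2-4-like (NADP_F420 before FRD); DUOX-like
(peroxidase-like, then extra TM, then EF/core); RBOH-like (organiser domain,
then EF, then core); NOX-EF (EF before core); FRE+DOMON; bare core triad;
fuFRE-like (extra TM immediately before the core, no EF); otherwise
unclassified-novel. The taxonomy deliberately collapses the many drawn
architecture variants of the superfamily into nine coarse categories —
finer splits are figure-defined rather than sequence-defined. Extra-TM
predictions inside the NADPH-binding domain are ignored as artifacts of
that domain's hydrophobic sheet core. Contradictory core-domain order
falls back to unclassified-novel with a warning rather than an error.

## Synthetic generator

A benchmark draws one scaffold per geometry from the seed: uniform random
canonical residues, hydrophobic letters {I,L,V,F,A,M} inside the TM windows
(defaults 96–121, 168–193, 202–228 on a 570-residue, NOX2-length scaffold),
optional canonical EF loops on an N-terminal extension, and the clade's
expected residues planted at the signature positions. Clades that share a
geometry share the background, so between-clade differences are exactly the
planted residues — this is what makes discovery false positives a
meaningful count. Noise is i.i.d.: substitutions to a uniformly chosen
different residue at rate ε (default 0.05, the benchmark's stated
condition), deletions to gap characters at rate 0.01 (a package choice on
the order of typical within-family indel divergence at this scale; range
0–0.05). Planted sites and EF loops are protected from substitutions by
default and never deleted, keeping truth well-defined while still
exercising gap handling. Default family size is 200 sequences per clade
(the benchmark condition); per-clade noise streams are sub-seeded
seed + clade index, so adding a clade never perturbs earlier ones.

What the generator does **not** emulate: phylogenetic correlation between
sequences (rows are i.i.d. around the scaffold), realistic indel length
distributions (single-site deletions only), empirical amino-acid
composition (uniform background maximises entropy contrast at planted
sites, inflating information-content separation relative to real
families), and homology of the background to NOX2 (see the classification
note above). Passing benchmarks therefore certify the statistics and rule
logic under idealised conditions, not performance on real, tree-correlated
families.

## Numerical and I/O choices

Coordinates are 1-based inclusive everywhere. Frequencies sum to 1 within
1e-9; information agrees with independent recomputation within 1e-9 (the
tested tolerance). FASTA I/O goes through Biopython, tables through pandas;
duplicate record ids are an error (truth-label joins require uniqueness),
unknown domain names map to `other` with a warning, and the Pfam accessions
of the superfamily's recurring domains (PF01794, PF08022, PF08030, PF03807,
PF03098, PF03351, PF00018) are aliased to the controlled vocabulary.
Result TSVs have fixed column order; JSON results round-trip to equal
objects. CLI commands log to stderr, write machine output to files only,
record a manifest (tool version + verbatim config), and exit 0/2/3 for
success/input error/config error.

## Fixtures

`fixtures/nox2_human.fasta` reproduces the human NOX2 (P04839) sequence;
its seven landmark residues and 570-residue length are revalidated on every
load. `fixtures/nox5_like_synthetic.fasta` is a **synthetic** NOX5-like
construct — four canonical calmodulin-type EF-hand loops on an N-terminal
extension fused to the NOX2 core — used to exercise EF-hand detection with
the EF-hand count (four) that the NOX5 family is described to carry; it is
not the UniProtKB Q96PH1 sequence and is labelled accordingly in its
filename and header.

## Known limitations

* Signature positions are pinned to exact NOX2-equivalent columns; the
  STEAP2-4 glutamine in particular is treated as sitting at the
  209-equivalent site, which is an interpretation rather than a printed
  coordinate.
* The classifier is rule-based and hard-thresholded; it reports `ambiguous`
  rather than a graded posterior, and sequences whose true signature sites
  fail to align (long insertions near TM3–TM5) will lose evidence silently
  (absent residues).
* TM window estimates from hydropathy are crude around charged/aromatic
  stretches; they are reporting context only.
* The alignment-based pipeline presumes genuine homology to NOX2; it is not
  meaningful for arbitrary non-homologous input (see above).
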