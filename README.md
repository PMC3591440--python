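# frdsig — signature-motif analysis for the ferric reductase domain superfamily

The ferric reductase domain (FRD) superfamily comprises the heme-containing
six-transmembrane proteins behind two ancient chemistries: metalloreductases
(FRE; Fe³⁺ + e⁻ → Fe²⁺) and ROS-generating NADPH oxidases (NOX;
O₂ + e⁻ → O₂⁻), plus the short bacterial YedZ and metazoan STEAP forms that
consist of little more than the transmembrane domain itself. Because the
clades are distinguished by a handful of residues rather than by overall
similarity, clade membership can be read off a sequence once its positions
are expressed in a common coordinate system — conventionally the numbering
of human NOX2 (cytochrome b-245 heavy chain).

`frdsig` is a toolkit for molecular evolutionists working with this
superfamily (or using it as a case study in rule-based function prediction).
It provides:

* **Conservation profiling** of clade alignments: per-column residue
  frequencies, gap fractions and sequence-logo information content
  `R = log2(20) − H`, where `H = −Σᵢ pᵢ log2 pᵢ` is the Shannon entropy of
  the column's residue distribution (bits; stack height of a logo).
* **Reference mapping**: Needleman–Wunsch global alignment (BLOSUM62,
  affine gaps 11/1) of any homolog against the bundled human NOX2 sequence,
  giving a monotone position map so that "His-119" means the same site in
  every sequence. A Kyte–Doolittle hydropathy scan supplies approximate
  transmembrane windows for reporting context.
* **Rule-based clade classification** from the seven signature positions
  (NOX2 numbering 101, 115, 119, 178, 179, 209, 222): the four canonical
  heme-coordinating histidines (101/115 in TM3, 209/222 in TM5), the NOX
  motif His-101/His-119/Thr-178/Gly-179 with its conserved Thr-Gly
  dipeptide, the YedZ/STEAP arginine that replaces His-101, and the
  STEAP2-4 glutamine at the 209-equivalent site.
* **Signature discovery** between two clade profiles: positions where one
  clade's consensus residue is frequent (≥ 0.8 by default) while the same
  residue is rare in the other clade (≤ 0.3).
* **Domain-architecture categorisation** (FRD-only, core triad, STEAP2-4,
  NOX-EF, DUOX-like, RBOH-like, FRE+DOMON, fuFRE-like, unclassified) from
  Pfam-style domain-hit tables, including a positional EF-hand loop scan.
* **A seeded synthetic-family generator** that plants these signatures on a
  shared random scaffold, producing labelled benchmarks for every stage.

## Worked example

Classify the bundled human NOX2 reference against itself:

```python
>>> from frdsig import load_nox2_reference, classify_record
>>> annotation = load_nox2_reference()
>>> result = classify_record(annotation.reference)
>>> (result.label, result.subtype, result.heme_histidine_count)
('NOX-group', None, 4)
>>> result.evidence
{'pos101': 'H', 'pos115': 'H', 'pos119': 'H', 'pos178': 'T', 'pos179': 'G', 'pos209': 'H', 'pos222': 'H'}
```

The evidence row is the residue vector at the seven reference positions:
histidines at all four heme-coordinating sites (hence `heme_histidine_count
= 4`) and the intact His-119 / Thr-178 / Gly-179 signature that marks a
ROS-generating NADPH oxidase, so the cascade returns `NOX-group`. An
arginine at position 101 would instead have routed the sequence to
`YedZ/STEAP` (subtype by the residue at 209), and a broken Thr-Gly
dipeptide with ≥ 3 heme histidines to `FRE-group`.

EF-hand content of the bundled NOX5-like construct (a synthetic stand-in
carrying four canonical Ca²⁺-binding loops, see `docs/methods.md`):

```python
>>> from frdsig import load_nox5_fixture, detect_ef_hands
>>> [(h.start, h.end, h.canonical) for h in detect_ef_hands(load_nox5_fixture())]
[(9, 20, True), (39, 50, True), (69, 80, True), (99, 110, True)]
```

The same pipelines are available from the shell:

```bash
frdsig simulate --seed 7 -o bench/          # 5-clade labelled benchmark
frdsig classify bench/pool.fasta -o calls/  # clade calls vs the NOX2 reference
frdsig discover bench/NOX.aln.fasta bench/FRE.aln.fasta -o sig/
frdsig architecture bench/pool.fasta bench/domains.tsv -o arch/
frdsig profile bench/NOX.aln.fasta --clade NOX -o logo/
```

`discover` on the benchmark's NOX and FRE families reports exactly the
positions 119, 178 and 179 — the planted NOX-distinguishing sites.

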