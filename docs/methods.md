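# Methods

## Peptide model and notation

A mature peptide is a residue string plus two terminal-modification
flags: N-terminal pyroglutamate (pQ, a cyclized Gln; Glu cyclization is
available behind `cyclize_e`) and C-terminal amide. The field notation
`pQVSFSTNWGSamide` / `...-NH2` round-trips losslessly; the cyclized
residue is stored as plain `Q`, so positions are 1-based with pQ at
position 1 and the amide contributing no residue (the 10-mer above has
length 10).

## Hallmark rules and classification

The six hallmarks are evaluated literally (length ∈ {8,9,10}; pQ;
position 2 in {A,V,L,I} ∪ {F,Y,W}; positions 4–5 in {FS, FT, YS}; W at
position 8; amidated terminus ending `W`, `WG`, or `W G X`). Positional
tests beyond the peptide's length are false. Decision precedence:

1. all six hallmarks **and** `RD` at positions 6–7 → `ACP`;
2. all six hallmarks → `true_AKH`;
3. exactly 10 residues, amidated, `W` at 8 and `G`/`P` at 10 → `AKH_like`;
4. more than 10 residues with 2–4 hallmarks → `proto_AKH`;
5. otherwise → `non_family`.

Choices made where the rules leave room: "aliphatic" = {A,V,L,I} and
"aromatic" = {F,Y,W}, which covers every position-2 residue seen in the
family (V, I, L, F) without admitting G or P; `AKH_like` requires the
amide, since the defining termini are written as amides; `proto_AKH`
counts all six hallmarks (the length hallmark is automatically false
above 10 residues, so counting only the other five gives identical
labels on all known examples); ACP takes precedence over true AKH
because the RD dipeptide is its sole distinguishing feature. Note that
ACPs whose C terminus fails hallmark 6 (e.g. `WNAamide`) fall through to
`non_family` under these literal rules — the classifier flags `acp_rd`
in the profile either way.

In position-wise comparison, a position is *identical* only when both
residue and terminal chemistry match; equal residues with mismatched
pQ/amide state count as *conserved* (chemically nonequivalent), as do
substitutions within the groups {I,L,V,M,A}, {S,T}, {F,Y,W}, {D,E},
{K,R}, {N,Q}. The group table is a declared convention chosen to
reproduce the family's published V~L, T~S, S~T calls; equal-length input
is required — no implicit alignment.

## Precursor processing

Signal peptides are never predicted: the boundary comes from a
`signal_end=N` FASTA header tag, a sidecar mapping, or a fixed-trim
default. Downstream of the signal, cleavage occurs at dibasic motifs
(KR, RR, KK, RK; monobasic R opt-in), consumed greedily left to right.
A fragment-terminal `G` plus up to two basic residues is an amidation
signal: it is stripped and sets the amide flag. An N-terminal Q (or E
with `cyclize_e`) sets the pQ flag. Fragments are reported only when
flanked by at least one processing signal — an intact chain with no
motifs and no amide glycine yields nothing — and only within
`[min_len, max_len]` (defaults 5–20: generous around the 8–14-residue
family range while discarding long prohormone domains). The full
segmentation (signal / bodies / amide signals / motifs / stop) is
exposed via `fragment_precursor` and reconstructs the precursor exactly
when concatenated, which the property tests exercise.

## Database mining

TBLASTN screening is replaced by an exhaustive, deterministic window
scan: every window starting at `Q` (candidate pQ; anchorless scanning is
a config flag) and of length 8–14 (configurable) is evaluated as a
candidate mature peptide. A window is accepted as a candidate terminus
in precursor context only — it must end either at an amidation signal
(`G` + 0–2 basics that is itself immediately followed by a cleavage
motif, a stop, or the frame end) or directly at a cleavage motif / frame
end. Anchoring the amidation signal terminally is what keeps a single
true AKH in `QVSFSTNWGSGKR` from also being reported as a spurious
8-mer ending at its internal `WGS` glycine. Windows containing `*` or
`X` are invalid. Candidates classifying as `true_AKH`, `AKH_like` or
`ACP` are reported (`proto_AKH` behind a flag, since 12–14-mers with few
hallmarks are common in random sequence). Nucleotide input is scanned
in all six frames (standard code, stops as `*`, N→X) via Biopython.
No similarity statistics or E-values are computed.

## Gene architecture

Intron phase = (cumulative coding nucleotides before the intron) mod 3;
the protein position is the residue after which (phase 0) or within
whose codon (phase 1/2) the intron falls. GFF3 CDS features are 1-based
inclusive, grouped by `Parent`, and minus-strand features are reversed
into coding order; coding lengths not divisible by 3 warn and proceed.
Two introns are *shared* when they map to the same protein-alignment
column (tolerance 0 by default, configurable single-linkage) with the
same phase. The exact-column default is the conservative reading of
"same location"; the tolerance is exposed for sensitivity analysis.

## Neighbor joining and bootstrap

Distances are uncorrected p-distances with pairwise deletion of columns
containing gaps, `X` or `*`; a pair with no comparable sites is an
error. NJ is the Saitou–Nei agglomeration on the Q-criterion with fully
specified determinism: ties break toward the lowest insertion-order
pair, and negative branch lengths are clamped to zero with the raw
value retained on the node. p-distance (rather than a corrected model)
is the default because only the tree method, not the substitution
model, is part of the reproduced analysis; the distance function is a
hook. The unrooted tree is held as a basal trifurcation; Newick output
carries bootstrap supports as internal-node labels. Bootstrap resamples
alignment columns with replacement; support is the percentage of
replicate NJ trees containing each internal bipartition of the
full-data tree. An all-zero distance matrix triggers a "star-like"
warning rather than an error.

## Synthetic data

Precursors are built as Met + hydrophobic signal stretch (from
{A,L,V,I,F,M,W}; signal prediction is out of scope, so realism beyond
hydrophobicity is not attempted), one embedded class peptide, a
`G`+KR amidation/cleavage context (bare KR for the unamidated decoys),
and a 30-residue C-terminal prohormone spacer drawn from an alphabet
without K, R, G, Q or W so it can neither cleave, amidate, nor anchor a
mining window; its length exceeds the default `max_len`, so clean
processing recovers exactly the planted peptide. Templates are real
family peptides where available (oyster, locust, fruit-fly, hornworm
AKHs; the annelid proto-AKH) and rule-exact constructions otherwise;
the generator asserts at run time that every template classifies to its
own label. Decoys violate at least two hallmarks. The default class mix
(0.30 true AKH, 0.15 AKH-like, 0.20 proto-AKH, 0.15 ACP, 0.20 decoy)
keeps every class populated at the benchmark sizes. `mutation_rate`
applies uniform per-position substitutions to the finished precursor
while ground truth keeps the unmutated peptide, which is what makes
degradation measurable.

Gene models split a random CDS (50–120 codons) at 0–3 uniform
coding-nucleotide cuts with random intron lengths (50–200 nt), random
strand, and GFF3 phase columns computed independently of the parser
under test. The family generator plants one conserved intron (same
protein position and phase in every gene) plus one private intron per
gene at mutually distinct positions. Alignments evolve an ungapped
random protein down a random binary tree (exponential branch factors ×
`branch_scale`, per-site substitution probability capped at 0.7); the
true tree is emitted as Newick.

Each output type draws from its own RNG stream derived from the master
seed (`default_rng([seed, stream])`), so outputs are byte-identical
under a fixed seed and independent across types. What the generator does
*not* emulate: realistic codon usage, indels and gapped alignments,
signal-peptide sequence statistics, multi-copy precursors, or
genome-scale negative background — so perfect benchmark scores show the
pipeline's rules are implemented self-consistently, not that real-data
screening is error-free.

## Benchmark and problem sizes

The packaged benchmarks use 500 precursors for processing/classification
precision–recall and miner recall, 100 genes for intron-phase recovery,
an 8-gene family for shared-intron detection, and 4–5-taxon additive
matrices (checked against an exhaustive least-squares topology search)
plus simulated alignments for NJ. The rule oracle cross-checks the
classifier against an independently written transcription of the class
definitions over all 160 000 amidated `pQ x x x x W` 6-mers and seeded
random peptides at lengths 7–13.

## Known limitations

- Convertase and amidation rules are declared conventions; the source
  analyses assumed standard prohormone processing without stating rules,
  so unusual precursors (monobasic-only sites, non-Gly amide donors) need
  the config switches or will be missed.
- The miner is rule-exact, not similarity-based: divergent peptides that
  break a hallmark are invisible to it, unlike to a permissive TBLASTN.
- Published receptor-tree topologies are not reproduced: the underlying
  alignments and program settings are not recoverable from the text, so
  tree code is validated on additive matrices and synthetic alignments
  instead.
- Greedy left-to-right motif consumption resolves overlapping dibasic
  sites (e.g. `KRR`) deterministically but is a convention, not biology.
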