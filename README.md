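# akhtrace

Trace adipokinetic-hormone (AKH) family signaling across protostomes from
sequence data alone: process neuropeptide precursors into mature peptides,
classify them by the family's structural hallmarks, mine protein and
nucleotide databases for new candidates, compare gene architectures by
intron position and phase, and build bootstrap neighbor-joining trees.

## The scientific problem

AKH is the insect counterpart of vertebrate gonadotropin-releasing hormone
(GnRH): a short amidated neuropeptide acting through a rhodopsin-family
GPCR. Whether AKH signaling extends beyond insects — to molluscs, annelids
and the rest of the protostomes — is an evolutionary question that can be
attacked in silico, because mature AKHs obey a compact set of structural
hallmarks:

1. a length of 8, 9 or 10 residues;
2. a pyroglutamate (pQ) at position 1;
3. an aliphatic or aromatic residue at position 2;
4. `FS`, `FT` or `YS` at positions 4–5;
5. tryptophan at position 8;
6. an amidated C terminus ending `W`, `WG` or `WGX`.

A peptide satisfying all six is a **true AKH** — unless it carries the
`RD` dipeptide at positions 6–7, the signature of the arthropod
**ACP** (AKH/corazonin-related peptide). A 10-residue amidated peptide
with a `WXG`/`WXP` C terminus is **AKH-like**, and peptides longer than
10 residues with only 2–4 hallmarks are **proto-AKHs**, candidate
ancestral forms found in annelids and brachiopods. `akhtrace` implements
these rules exactly, together with the precursor-processing conventions
needed to read mature peptides out of preprohormones (dibasic convertase
cleavage, C-terminal glycine amidation, N-terminal glutamine
cyclization), an exhaustive hallmark-window miner that stands in for
TBLASTN screening, intron-phase comparison of gene models (phase =
cumulative coding nucleotides before the intron, mod 3), and Saitou–Nei
neighbor joining on p-distances with nonparametric bootstrap.

A synthetic-data module generates precursors, ESTs, gene models and
alignments with known ground truth, so every stage is benchmarked
without downloads.

## Worked example

Classify the oyster AKH, an AKH-like peptide, an ACP and the annelid
proto-AKH:

```console
$ akhtrace classify pQVSFSTNWGSamide pQLNFSTGWNGamide pQVTFSRDWGAamide pQFSFSLPGKWGNamide
pQVSFSTNWGSamide        true_AKH        6/6 hallmarks
pQLNFSTGWNGamide        AKH_like        5/6 hallmarks
pQVTFSRDWGAamide        ACP             6/6 hallmarks
pQFSFSLPGKWGNamide      proto_AKH       4/6 hallmarks
```

The oyster peptide (`pQVSFSTNWGSamide`) carries all six hallmarks and no
`RD`, hence *true AKH*; the last peptide is 12 residues long with only
four hallmarks (pQ, F at position 2, `FS` at 4–5, `WGNamide` terminus),
hence *proto-AKH*. Compare the oyster AKH with the classical locust
AKH-1 position by position:

```console
$ akhtrace compare pQVSFSTNWGSamide pQLNFTPNWGTamide
identical (5): [1, 4, 7, 8, 9]
conserved (3): [2, 5, 10]
different: [3, 6]
```

Five identical positions and three conservative substitutions (V~L,
T~S, S~T) out of ten — the similarity that first suggested the oyster
peptide is a genuine AKH. The same checks run as a batch via
`akhtrace worked-examples`, and `akhtrace run --seed 42 --outdir out/`
executes the full synthetic pipeline (generate → process → classify →
mine → introns → tree) and writes a JSON summary whose per-class
precision and recall are 1.0 on clean data.

Other subcommands: `process` (cleave precursor FASTA), `mine` (scan
protein or six-frame-translated nucleotide FASTA), `introns` (phases
from GFF3), `tree` (bootstrap NJ from aligned FASTA, Newick out).

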