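"""Synthetic ground-truth data for every pipeline stage.

Generates (1) preprohormones embedding hallmark-defined peptide classes
plus decoys, (2) gene models with known intron phases as GFF3, and (3)
ungapped protein alignments simulated down a known tree — so that
processing, classification, mining, intron-phase recovery, and tree
building can all be benchmarked without downloads.

Determinism: every output type draws from its own RNG stream derived
from the master seed, so e.g. adding genes never perturbs precursor
sequences, and a fixed seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hallmarks import classify
from .peptides import MaturePeptide
from .phylo import Node, TreeResult
from .processing import Precursor

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "ALVIFMW"  # crude signal-peptide alphabet
SPACER_ALPHABET = "STNAPDEH"  # no K/R/G/Q/W: creates no processing signals

#: class templates; every family peptide is amidated with pQ, decoys are not.
#: true AKHs and the 12-mer proto-AKH are peptides reported from real species
#: (oyster, locust, fruit fly, tobacco hornworm, annelids); the rest are
#: constructed to satisfy their class rule exactly.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "true_AKH": (
        "QVSFSTNWGS",   # Crassostrea gigas AKH
        "QLNFTPNWGT",   # Locusta migratoria AKH-1
        "QIHFSPTWGS",   # Lottia gigantea AKH
        "QLTFSPDW",     # Drosophila melanogaster AKH
        "QLTFTSSWG",    # Manduca sexta AKH
    ),
    "AKH_like": (
        "QLNFSTGWNG",
        "QVNFSPSWTP",
    ),
    "proto_AKH": (
        "QFSFSLPGKWGN",  # Capitella teleta GnRH-2 / Platynereis proto-AKH-1
        "QLSFSTNNKAWGG",
        "QFPSSDNNKAFSDA",
    ),
    "ACP": (
        "QVTFSRDWGA",
        "QITFSRDWGG",
    ),
    "decoy": (
        "SDPTNALHES",
        "APDESSTNHL",
        "TNSHPDAELS",
    ),
}

CLASS_ORDER = ("true_AKH", "AKH_like", "proto_AKH", "ACP", "decoy")

#: one fixed codon per residue for reverse translation of synthetic ESTs
CODON: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_precursors: int = 50
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "true_AKH": 0.30,
            "AKH_like": 0.15,
            "proto_AKH": 0.20,
            "ACP": 0.15,
            "decoy": 0.20,
        }
    )
    signal_len: int = 22
    mutation_rate: float = 0.0
    amide_context: str = "GKR"  # one of G, GK, GR, GKR, GRR
    spacer_len: int = 30
    n_genes: int = 20
    n_taxa: int = 8
    aln_len: int = 200
    branch_scale: float = 0.08  # mean branch length, substitutions/site
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_mix) - set(CLASS_ORDER):
            raise ConfigError(f"unknown classes {set(self.class_mix) - set(CLASS_ORDER)}")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigError("negative class proportion")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class proportions must sum to 1")
        if min(self.n_precursors, self.signal_len, self.n_genes) < 0:
            raise ConfigError("counts must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")
        if self.amide_context[0] != "G" or any(
            c not in "KR" for c in self.amide_context[1:]
        ) or len(self.amide_context) > 3:
            raise ConfigError("amide_context must be G plus 0-2 basic residues")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# precursors


@dataclass(frozen=True)
class PrecursorTruth:
    record_id: str
    template_class: str  # generator vocabulary, includes "decoy"
    expected_label: str  # classification vocabulary ("non_family" for decoys)
    mature: MaturePeptide  # expected processing outcome (span in precursor)


@dataclass(frozen=True)
class PrecursorSet:
    precursors: tuple[Precursor, ...]
    truth: tuple[PrecursorTruth, ...]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.precursors:
                fh.write(f">{p.id} signal_end={p.signal_end}\n{p.residues}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "record_id\ttemplate_class\texpected_label\tmature\t"
                "start\tend\tpyroglutamate\tamidated\n"
            )
            for t in self.truth:
                s, e = t.mature.source_span
                fh.write(
                    f"{t.record_id}\t{t.template_class}\t{t.expected_label}\t"
                    f"{t.mature.residues}\t{s}\t{e}\t"
                    f"{int(t.mature.pyroglutamate)}\t{int(t.mature.amidated)}\n"
                )


def _class_counts(config: GeneratorConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_precursors over the class mix."""
    n = config.n_precursors
    raw = {c: config.class_mix.get(c, 0.0) * n for c in CLASS_ORDER}
    counts = {c: int(v) for c, v in raw.items()}
    rest = n - sum(counts.values())
    for c in sorted(CLASS_ORDER, key=lambda c: raw[c] - counts[c], reverse=True)[:rest]:
        counts[c] += 1
    for c, k in counts.items():
        if k > 0 and config.class_mix.get(c, 0.0) == 0.0:
            raise ConfigError(f"class {c!r} has zero probability but count {k}")
    return counts


def generate_precursors(config: GeneratorConfig) -> PrecursorSet:
    """Synthesize preprohormones with one embedded class peptide each.

    Layout: Met + hydrophobic signal stretch, the template peptide, an
    amidation/cleavage context (``G``+basics for amidated classes, a
    bare dibasic site for decoys), then a long C-terminal prohormone
    spacer free of processing signals.  Ground truth records the exact
    mature peptide, its precursor span, and its class.
    """
    rng = config.rng(0)
    labels = [c for c, k in _class_counts(config).items() for _ in range(k)]
    rng.shuffle(labels)
    precursors, truths = [], []
    for idx, cls in enumerate(labels, 1):
        template = TEMPLATES[cls][rng.integers(len(TEMPLATES[cls]))]
        amidated = cls != "decoy"
        expected = classify(
            MaturePeptide(template, pyroglutamate=template[0] == "Q", amidated=amidated)
        ).label
        want = "non_family" if cls == "decoy" else cls
        assert expected == want, f"template {template} classifies as {expected}"
        signal = "M" + "".join(
            rng.choice(list(HYDROPHOBIC), size=config.signal_len - 1)
        )
        context = (config.amide_context if amidated else "") + "KR"
        spacer = "".join(rng.choice(list(SPACER_ALPHABET), size=config.spacer_len))
        seq = signal + template + context + spacer
        if config.mutation_rate > 0:
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < config.mutation_rate:
                    chars[i] = AA20[rng.integers(20)]
            seq = "".join(chars)
        rid = f"syn{idx:04d}"
        precursors.append(Precursor(rid, seq, signal_end=config.signal_len))
        truths.append(
            PrecursorTruth(
                rid,
                cls,
                want,
                MaturePeptide(
                    template,
                    pyroglutamate=template[0] == "Q",
                    amidated=amidated,
                    source_id=rid,
                    source_span=(
                        config.signal_len + 1,
                        config.signal_len + len(template),
                    ),
                ),
            )
        )
    return PrecursorSet(tuple(precursors), tuple(truths))


def reverse_translate(protein: str) -> str:
    return "".join(CODON[c] for c in protein)


def est_database(pset: PrecursorSet, seed: int = 0) -> list[tuple[str, str]]:
    """Reverse-translate precursors into a synthetic EST set, with a random
    half of the records emitted as reverse complements to exercise the
    negative reading frames."""
    comp = str.maketrans("ACGT", "TGCA")
    rng = np.random.default_rng([seed, 3])
    out = []
    for p in pset.precursors:
        nt = reverse_translate(p.residues) + "TAA"
        if rng.random() < 0.5:
            nt = nt.translate(comp)[::-1]
        out.append((f"est_{p.id}", nt))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    introns: tuple[tuple[int, int], ...]  # (protein_position, phase)
    conserved_index: int | None = None  # ordinal of the planted shared intron


@dataclass(frozen=True)
class GeneModelSet:
    gff3: str
    proteins: dict[str, str]
    truth: tuple[GeneTruth, ...]

    def write(self, gff_path: str | Path, fasta_path: str | Path) -> None:
        Path(gff_path).write_text(self.gff3)
        write_fasta(list(self.proteins.items()), fasta_path)


def _emit_gene(
    gene_id: str,
    protein: str,
    cut_nts: list[int],
    strand: str,
    rng: np.random.Generator,
) -> tuple[list[str], tuple[tuple[int, int], ...]]:
    """GFF3 CDS lines for one gene whose CDS is split at the given
    coding-nucleotide offsets; returns lines and (protein_pos, phase) truth."""
    cds_len = 3 * len(protein)
    bounds = [0] + sorted(cut_nts) + [cds_len]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    truth = tuple(
        (c // 3 + (1 if c % 3 else 0), c % 3) for c in sorted(cut_nts)
    )
    offset = int(rng.integers(1, 1000))
    lines = []
    coords = []
    pos = offset
    for L in exon_lens:
        coords.append((pos, pos + L - 1))
        pos += L + int(rng.integers(50, 200))  # intron length
    if strand == "-":
        # mirror so ascending genomic order corresponds to reversed coding order
        span_end = coords[-1][1]
        coords = [(span_end - e + offset, span_end - s + offset) for s, e in coords]
        coords.reverse()
    cum = 0
    phases = []
    for L in exon_lens:
        phases.append((3 - cum % 3) % 3)
        cum += L
    order = range(len(exon_lens))
    for i in order:
        s, e = coords[i] if strand == "+" else coords[len(exon_lens) - 1 - i]
        lines.append(
            f"ctg_{gene_id}\takhtrace\tCDS\t{s}\t{e}\t.\t{strand}\t{phases[i]}\t"
            f"ID=cds_{gene_id}.{i + 1};Parent={gene_id}"
        )
    lines.sort(key=lambda l: int(l.split("\t")[3]))
    return lines, truth


def generate_gene_models(config: GeneratorConfig) -> GeneModelSet:
    """Independent genes with 0-3 random introns each; truth stores
    (protein_position, phase) computed from the planted cut points."""
    if config.n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    rng = config.rng(1)
    lines = ["##gff-version 3"]
    proteins: dict[str, str] = {}
    truths = []
    for g in range(1, config.n_genes + 1):
        gid = f"gene{g:03d}"
        plen = int(rng.integers(50, 121))
        protein = "".join(rng.choice(list(AA20), size=plen))
        n_introns = int(rng.integers(0, 4))
        cuts = sorted(
            int(c) for c in rng.choice(
                np.arange(1, 3 * plen), size=n_introns, replace=False
            )
        )
        strand = "+-"[int(rng.integers(2))]
        gl, truth = _emit_gene(gid, protein, cuts, strand, rng)
        lines.extend(gl)
        proteins[gid] = protein
        truths.append(GeneTruth(gid, truth))
    return GeneModelSet("\n".join(lines) + "\n", proteins, tuple(truths))


def generate_gene_family(config: GeneratorConfig) -> tuple[GeneModelSet, dict[str, str]]:
    """A gene family sharing one protein, one conserved intron (same
    protein position and phase in every gene) and one private intron per
    gene; returns the model set and the (trivial, ungapped) alignment."""
    if config.n_genes < 2:
        raise ConfigError("a family needs >= 2 genes")
    rng = config.rng(2)
    plen = int(rng.integers(80, 121))
    protein = "".join(rng.choice(list(AA20), size=plen))
    conserved_cut = int(rng.integers(3 * 10, 3 * 30))  # early in the CDS
    lines = ["##gff-version 3"]
    proteins: dict[str, str] = {}
    truths = []
    # private cuts: distinct late positions, one per gene, all differing in
    # protein position from each other and from the conserved intron
    private_pp = rng.choice(np.arange(40, plen - 5), size=config.n_genes, replace=False)
    for g in range(1, config.n_genes + 1):
        gid = f"fam{g:03d}"
        private_cut = int(private_pp[g - 1]) * 3 + int(rng.integers(0, 3))
        strand = "+-"[int(rng.integers(2))]
        gl, truth = _emit_gene(
            gid, protein, [conserved_cut, private_cut], strand, rng
        )
        lines.extend(gl)
        proteins[gid] = protein
        truths.append(GeneTruth(gid, truth, conserved_index=1))
    aln = dict(proteins)  # identical rows: already an ungapped alignment
    return GeneModelSet("\n".join(lines) + "\n", proteins, tuple(truths)), aln


# ---------------------------------------------------------------------------
# alignments down a known tree


def _random_topology(n_taxa: int, rng: np.random.Generator) -> Node:
    nodes = [Node(name=f"t{i + 1}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la = float(rng.exponential(1.0))
        lb = float(rng.exponential(1.0))
        nodes.append(Node(children=[(a, la), (b, lb)]))
    return nodes[0]


@dataclass(frozen=True)
class AlignmentSet:
    rows: dict[str, str]
    true_tree_newick: str

    def write(self, fasta_path: str | Path, newick_path: str | Path) -> None:
        write_fasta(list(self.rows.items()), fasta_path)
        Path(newick_path).write_text(self.true_tree_newick + "\n")


def generate_alignment(config: GeneratorConfig) -> AlignmentSet:
    """Simulate an ungapped protein alignment down a random binary tree.

    Each branch substitutes every site independently with probability
    ``branch_scale`` × (exponential branch factor), capped at 0.7; the
    substitution target is uniform over the other 19 residues.
    """
    if config.n_taxa < 3:
        raise ConfigError("n_taxa must be >= 3")
    if config.aln_len < 1:
        raise ConfigError("aln_len must be >= 1")
    rng = config.rng(4)
    tree = _random_topology(config.n_taxa, rng)
    root_seq = rng.choice(list(AA20), size=config.aln_len)
    rows: dict[str, str] = {}
    scaled: dict[int, float] = {}

    def evolve(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            rows[node.name] = "".join(seq)
            return
        for child, length in node.children:
            p = min(0.7, config.branch_scale * length)
            scaled[id(child)] = p
            s = seq.copy()
            for i in range(len(s)):
                if rng.random() < p:
                    choices = [c for c in AA20 if c != s[i]]
                    s[i] = choices[rng.integers(19)]
            evolve(child, s)

    evolve(tree, root_seq)

    def newick(node: Node) -> str:
        if node.is_leaf:
            return node.name
        return (
            "("
            + ",".join(
                f"{newick(c)}:{scaled[id(c)]:.6f}" for c, _ in node.children
            )
            + ")"
        )

    ordered = {t: rows[t] for t in sorted(rows)}
    return AlignmentSet(ordered, newick(tree) + ";")
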