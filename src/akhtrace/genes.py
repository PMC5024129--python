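"""Intron positions and phases from gene models; shared-intron detection.

The phase of an intron is its position relative to the reading frame:
phase 0 falls between codons, phases 1 and 2 after the first or second
base of a codon.  Two genes "share" an intron when the introns map to
the same protein-alignment column with identical phase — the criterion
used to argue common ancestry of peptide and receptor genes across
insects, molluscs and annelids.

GFF3 coordinates are 1-based inclusive; internal arithmetic is 0-based
half-open, converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO


class GeneModelError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Ordered coding exons of one gene, strand-normalized to coding direction."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, coding order
    strand: str = "+"
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: no CDS exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise GeneModelError(f"{self.gene_id}: overlapping CDS segments")
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"{self.gene_id}: exon start > end")

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)


@dataclass(frozen=True)
class IntronRecord:
    """One intron with its protein-level position and phase.

    ``protein_position`` is the 1-based residue after which (phase 0) or
    within whose codon (phase 1/2) the intron falls; ``phase`` is the
    cumulative number of coding nucleotides before the intron mod 3.
    """

    gene_id: str
    index: int  # ordinal, 1-based, 5'->3' in coding direction
    protein_position: int
    phase: int


def introns_of(model: GeneModel) -> list[IntronRecord]:
    """Enumerate introns with phase and protein position from exon lengths."""
    if model.coding_length % 3 != 0:
        warnings.warn(
            f"{model.gene_id}: coding length {model.coding_length} not divisible "
            "by 3; analysing covered prefix",
            stacklevel=2,
        )
    out = []
    cum = 0
    for idx, length in enumerate(model.exon_lengths[:-1], 1):
        cum += length
        phase = cum % 3
        protein_position = cum // 3 + (1 if phase else 0)
        out.append(IntronRecord(model.gene_id, idx, protein_position, phase))
    return out


def parse_gff3_cds(source: str | Path) -> dict[str, GeneModel]:
    """Read CDS features from GFF3 (path or literal text) into gene models.

    CDS features are grouped by their ``Parent`` (falling back to ``ID``)
    attribute; minus-strand genes are reversed into coding order.
    """
    text: str
    p = Path(str(source))
    if "\n" not in str(source) and p.exists():
        text = p.read_text()
    else:
        text = str(source)
    by_gene: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].strip().split(";") if "=" in kv
        )
        gene = attrs.get("Parent", attrs.get("ID", "unknown"))
        by_gene.setdefault(gene, []).append((int(cols[3]), int(cols[4])))
        strands[gene] = cols[6]
    models = {}
    for gene, exons in by_gene.items():
        exons.sort()
        if strands[gene] == "-":
            exons.reverse()
        models[gene] = GeneModel(gene, tuple(exons), strands[gene])
    return models


def introns_from_gff(gff3: str | Path, gene_id: str) -> list[IntronRecord]:
    """Intron records for one gene of a GFF3 file (or literal GFF3 text)."""
    models = parse_gff3_cds(gff3)
    if gene_id not in models:
        raise GeneModelError(f"no CDS features for gene {gene_id!r}")
    return introns_of(models[gene_id])


# ---------------------------------------------------------------------------
# shared-intron analysis on a protein alignment

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class MappedIntron:
    gene_id: str
    index: int
    column: int  # 1-based alignment column
    phase: int


@dataclass(frozen=True)
class SharedIntronReport:
    """Clusters of introns mapping to the same alignment column and phase."""

    shared: tuple[tuple[MappedIntron, ...], ...]  # clusters spanning >=2 genes
    unshared: tuple[MappedIntron, ...]

    def shared_for(self, gene_id: str) -> list[MappedIntron]:
        return [m for grp in self.shared for m in grp if m.gene_id == gene_id]


def _column_of(row: str, protein_position: int) -> int:
    seen = 0
    for col, c in enumerate(row, 1):
        if c not in GAP_CHARS:
            seen += 1
            if seen == protein_position:
                return col
    raise GeneModelError(
        f"protein position {protein_position} beyond ungapped row length {seen}"
    )


def map_to_alignment(
    introns: Iterable[IntronRecord],
    alignment: Mapping[str, str],
    proteins: Mapping[str, str] | None = None,
    tolerance: int = 0,
) -> SharedIntronReport:
    """Map introns onto alignment columns and cluster shared ones.

    Two introns are shared when their column difference is at most
    ``tolerance`` (single-linkage within a phase class; default 0 =
    exact column match) and their phases are identical.  When
    ``proteins`` is given, each gene's ungapped alignment row must equal
    its protein sequence.
    """
    mapped: list[MappedIntron] = []
    for rec in introns:
        if rec.gene_id not in alignment:
            raise GeneModelError(f"gene {rec.gene_id!r} missing from alignment")
        row = alignment[rec.gene_id]
        if proteins is not None and rec.gene_id in proteins:
            ungapped = "".join(c for c in row if c not in GAP_CHARS)
            if ungapped != proteins[rec.gene_id]:
                raise GeneModelError(
                    f"alignment row for {rec.gene_id!r} does not match its protein"
                )
        mapped.append(
            MappedIntron(rec.gene_id, rec.index, _column_of(row, rec.protein_position), rec.phase)
        )

    shared: list[tuple[MappedIntron, ...]] = []
    unshared: list[MappedIntron] = []
    for phase in (0, 1, 2):
        cohort = sorted(
            (m for m in mapped if m.phase == phase), key=lambda m: (m.column, m.gene_id, m.index)
        )
        cluster: list[MappedIntron] = []
        for m in cohort + [None]:  # type: ignore[list-item]
            if cluster and (m is None or m.column - cluster[-1].column > tolerance):
                if len({c.gene_id for c in cluster}) >= 2:
                    shared.append(tuple(cluster))
                else:
                    unshared.extend(cluster)
                cluster = []
            if m is not None:
                cluster.append(m)
    shared.sort(key=lambda grp: (grp[0].column, grp[0].phase))
    return SharedIntronReport(tuple(shared), tuple(sorted(
        unshared, key=lambda m: (m.gene_id, m.index)
    )))


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len({len(r) for r in rows.values()}) > 1:
        raise GeneModelError("alignment rows have unequal lengths")
    return rows


def architecture_diagram(models: Mapping[str, GeneModel]) -> str:
    """Text diagram of exon boxes with intron phase labels."""
    lines = []
    for gene, model in models.items():
        parts = []
        for i, length in enumerate(model.exon_lengths):
            parts.append(f"[{length}nt]")
            if i < len(model.exon_lengths) - 1:
                rec = introns_of(model)[i]
                parts.append(f"--{rec.phase}--")
        lines.append(f"{gene:20s} " + "".join(parts))
    return "\n".join(lines)
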