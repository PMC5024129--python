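"""Published reference peptides and the worked-example checks.

The peptides below are the family's anchor sequences, as reported from
cloning and database mining: the oyster (*Crassostrea gigas*) AKH, the
classical locust AKH-1 standard, the limpet AKH recovered from a
contaminated annelid EST set, and the annelid proto-AKH shared by
*Capitella teleta* and *Platynereis dumerilii*.  ``worked_examples``
recomputes every desk-checkable claim about them — lengths, hallmark
counts, class labels, and the position-wise oyster/locust comparison —
and reports expected vs observed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hallmarks import classify, compare_positions, evaluate_hallmarks
from .peptides import MaturePeptide, parse_peptide_notation, peptide_length

CGIGAS_AKH = "pQVSFSTNWGSamide"
LOCUSTA_AKH1 = "pQLNFTPNWGTamide"
APOMPEJANA_AKH = "pQIHFSPTWGSamide"  # identical to the Lottia gigantea AKH
ANNELID_PROTO_AKH = "pQFSFSLPGKWGNamide"

#: peptides whose class is stated in running text
STATED_CLASSES = {
    CGIGAS_AKH: "true_AKH",
    APOMPEJANA_AKH: "true_AKH",
    ANNELID_PROTO_AKH: "proto_AKH",
}


def w_position(p: MaturePeptide) -> int:
    """1-based position of the first tryptophan (pQ counts as position 1)."""
    return p.residues.index("W") + 1


@dataclass(frozen=True)
class CheckRow:
    name: str
    expected: object
    observed: object

    @property
    def ok(self) -> bool:
        return self.expected == self.observed


def worked_examples() -> list[CheckRow]:
    """Recompute every in-text desk check; all rows should pass."""
    cg = parse_peptide_notation(CGIGAS_AKH)
    lo = parse_peptide_notation(LOCUSTA_AKH1)
    proto = parse_peptide_notation(ANNELID_PROTO_AKH)
    cmp_ = compare_positions(cg, lo)
    rows = [
        CheckRow(
            "oyster vs locust AKH-1: identical positions",
            frozenset({1, 4, 7, 8, 9}),
            cmp_.identical_positions,
        ),
        CheckRow(
            "oyster vs locust AKH-1: conserved positions",
            frozenset({2, 5, 10}),
            cmp_.conserved_positions,
        ),
        CheckRow("oyster AKH: residue count", 10, peptide_length(cg)),
        CheckRow(
            "oyster AKH: all six hallmarks", 6, evaluate_hallmarks(cg).n_hallmarks
        ),
        CheckRow("oyster AKH: class", "true_AKH", classify(cg).label),
        CheckRow("annelid proto-AKH: residue count", 12, peptide_length(proto)),
        CheckRow("annelid proto-AKH: W position", 10, w_position(proto)),
        CheckRow(
            "annelid proto-AKH: at most 4 hallmarks",
            True,
            evaluate_hallmarks(proto).n_hallmarks <= 4,
        ),
        CheckRow("annelid proto-AKH: class", "proto_AKH", classify(proto).label),
    ]
    for notation, label in STATED_CLASSES.items():
        rows.append(
            CheckRow(
                f"stated class of {notation}",
                label,
                classify(parse_peptide_notation(notation)).label,
            )
        )
    return rows
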