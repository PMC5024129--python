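"""Mature neuropeptides and the field's ``pQ...amide`` notation.

Mature AKH-family peptides carry two characteristic post-translational
modifications: an N-terminal pyroglutamate (a cyclized glutamine, written
``pQ``) that blocks the N terminus, and a C-terminal amide (written
``amide`` or ``-NH2``) derived from a precursor glycine.  This module
defines the in-memory representation and a lossless parser/renderer for
that notation, e.g. ``pQVSFSTNWGSamide``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_NOTATION_RE = re.compile(
    r"^(?P<pyro>p(?=[QE]))?(?P<body>[A-Za-z]+?)(?P<amide>amide|-NH2)?$"
)


class PeptideError(ValueError):
    """Raised for malformed peptide strings or invalid peptide operations."""


@dataclass(frozen=True)
class MaturePeptide:
    """A processed peptide: residue string plus terminal-modification flags.

    ``residues`` keeps the cyclized residue as plain ``Q`` (or ``E``); the
    ``p`` and ``amide`` markers live in the boolean flags.  Positions are
    1-based throughout: the pyroglutamate is position 1 and the amide
    contributes no residue.
    """

    residues: str
    pyroglutamate: bool = False
    amidated: bool = False
    source_id: str = ""
    source_span: tuple[int, int] | None = None  # 1-based inclusive

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError("peptide must have at least one residue")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise PeptideError(
                f"illegal residue letter(s) {sorted(bad)!r} in {self.residues!r}"
            )
        if self.pyroglutamate and self.residues[0] not in "QE":
            raise PeptideError(
                "pyroglutamate requires an N-terminal Q (or E), "
                f"got {self.residues[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def notation(self) -> str:
        """Render in ``pQ...amide`` notation (inverse of :func:`parse_peptide_notation`)."""
        return (
            ("p" if self.pyroglutamate else "")
            + self.residues
            + ("amide" if self.amidated else "")
        )


def parse_peptide_notation(text: str, source_id: str = "") -> MaturePeptide:
    """Parse a peptide written in ``pQ...amide`` / ``-NH2`` notation.

    >>> p = parse_peptide_notation("pQVSFSTNWGSamide")
    >>> p.residues, p.pyroglutamate, p.amidated
    ('QVSFSTNWGS', True, True)
    """
    m = _NOTATION_RE.match(text.strip())
    if not m:
        raise PeptideError(f"cannot parse peptide notation {text!r}")
    body = m.group("body").upper()
    bad = set(body) - AMINO_ACIDS
    if bad:
        raise PeptideError(
            f"illegal residue letter(s) {sorted(bad)!r} in {text!r}"
        )
    return MaturePeptide(
        residues=body,
        pyroglutamate=m.group("pyro") is not None,
        amidated=m.group("amide") is not None,
        source_id=source_id,
    )


def peptide_length(p: MaturePeptide) -> int:
    """Residue count: the cyclized pQ counts as one residue, the amide as zero."""
    return len(p.residues)
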