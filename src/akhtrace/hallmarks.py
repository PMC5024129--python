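"""Six-hallmark AKH classification and position-wise peptide comparison.

Insect adipokinetic hormones (AKHs) share six structural hallmarks:

(i)   a length of 8, 9, or 10 residues;
(ii)  a pyroglutamate (pQ) at position 1;
(iii) an aliphatic or aromatic residue at position 2;
(iv)  FS, FT, or YS at positions 4-5;
(v)   tryptophan at position 8;
(vi)  an amidated C terminus ending W, WG, or WGX.

These hallmarks also admit the AKH/corazonin-related peptides (ACPs),
which differ only by an RD dipeptide at positions 6-7.  The remaining
family labels are "AKH-like" (10 residues with a WXGamide or WXPamide
C terminus) and "proto-AKH" (longer than 10 residues, 2-4 hallmarks) —
candidate ancestral forms found in annelids and brachiopods.

Positions are 1-based with the pyroglutamate at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .peptides import MaturePeptide, PeptideError

ALIPHATIC = frozenset("AVLI")
AROMATIC = frozenset("FYW")
POS45_PAIRS = frozenset({"FS", "FT", "YS"})

#: residue groups treated as conservative substitutions in pairwise comparison
CONSERVED_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ILVMA"),
    frozenset("ST"),
    frozenset("FYW"),
    frozenset("DE"),
    frozenset("KR"),
    frozenset("NQ"),
)

LABELS = ("true_AKH", "AKH_like", "proto_AKH", "ACP", "non_family")


@dataclass(frozen=True)
class HallmarkProfile:
    """Outcome of the six hallmark tests plus the ACP RD flag."""

    h_length: bool
    h_pq: bool
    h_pos2: bool
    h_pos45: bool
    h_pos8: bool
    h_cterm: bool
    acp_rd: bool

    @property
    def n_hallmarks(self) -> int:
        return sum(
            (self.h_length, self.h_pq, self.h_pos2,
             self.h_pos45, self.h_pos8, self.h_cterm)
        )

    @property
    def all_six(self) -> bool:
        return self.n_hallmarks == 6


@dataclass(frozen=True)
class Classification:
    label: str
    profile: HallmarkProfile
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.label in LABELS


@dataclass(frozen=True)
class PositionComparison:
    """3-way partition of positions of two equal-length peptides."""

    identical_positions: frozenset[int]
    conserved_positions: frozenset[int]
    different_positions: frozenset[int]

    @property
    def n_identical(self) -> int:
        return len(self.identical_positions)

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_positions)


def evaluate_hallmarks(
    p: MaturePeptide,
    aliphatic: frozenset[str] = ALIPHATIC,
    aromatic: frozenset[str] = AROMATIC,
) -> HallmarkProfile:
    """Evaluate the six AKH hallmarks and the ACP RD test for a peptide.

    Positional tests referring to positions beyond the peptide's length
    are false.  The C-terminal test requires the amide: the last residue
    is W, the last two are WG, or the last three are W, G, anything.
    """
    s = p.residues
    n = len(s)
    h_length = n in (8, 9, 10)
    h_pq = p.pyroglutamate and s[0] in "QE"
    h_pos2 = n >= 2 and (s[1] in aliphatic or s[1] in aromatic)
    h_pos45 = n >= 5 and s[3:5] in POS45_PAIRS
    h_pos8 = n >= 8 and s[7] == "W"
    h_cterm = p.amidated and (
        s[-1] == "W"
        or s[-2:] == "WG"
        or (n >= 3 and s[-3] == "W" and s[-2] == "G")
    )
    acp_rd = n >= 7 and s[5:7] == "RD"
    return HallmarkProfile(h_length, h_pq, h_pos2, h_pos45, h_pos8, h_cterm, acp_rd)


def classify(p: MaturePeptide) -> Classification:
    """Assign one family label to a peptide by the hallmark decision rules.

    Precedence: ACP (all six hallmarks + RD at 6-7) > true AKH (all six)
    > AKH-like (10 residues, amidated, W-X-G or W-X-P at positions 8-10)
    > proto-AKH (>10 residues, 2-4 hallmarks) > non-family.
    """
    prof = evaluate_hallmarks(p)
    s = p.residues
    n = len(s)
    fired: list[str] = []
    if prof.all_six and prof.acp_rd:
        fired.append("all six hallmarks with RD at positions 6-7 -> ACP")
        return Classification("ACP", prof, tuple(fired))
    if prof.all_six:
        fired.append("all six hallmarks, no RD at 6-7 -> true AKH")
        return Classification("true_AKH", prof, tuple(fired))
    if (
        n == 10
        and p.amidated
        and s[7] == "W"
        and s[9] in "GP"
    ):
        fired.append(
            f"10 residues, amidated, W{s[8]}{s[9]} C terminus (WXG/WXP) -> AKH-like"
        )
        return Classification("AKH_like", prof, tuple(fired))
    if n > 10 and 2 <= prof.n_hallmarks <= 4:
        fired.append(
            f"{n} residues (>10) with {prof.n_hallmarks} hallmarks -> proto-AKH"
        )
        return Classification("proto_AKH", prof, tuple(fired))
    fired.append("no family rule fired -> non-family")
    return Classification("non_family", prof, tuple(fired))


def compare_positions(a: MaturePeptide, b: MaturePeptide) -> PositionComparison:
    """Position-wise identical / conserved / different partition.

    A position is *identical* when the residues are equal and, at a
    terminus, the modification state (pyroglutamate at position 1, amide
    at the last position) also matches; a residue-equal position with a
    terminal-modification mismatch is chemically nonequivalent and counts
    as *conserved*, as do different residues in the same substitution
    group.  Everything else is *different*.  Peptides must already be the
    same length — no implicit alignment is performed.
    """
    if len(a.residues) != len(b.residues):
        raise PeptideError(
            f"cannot compare peptides of lengths {len(a.residues)} and {len(b.residues)}"
        )
    n = len(a.residues)
    identical, conserved, different = set(), set(), set()
    for i in range(1, n + 1):
        ra, rb = a.residues[i - 1], b.residues[i - 1]
        mods_match = True
        if i == 1 and a.pyroglutamate != b.pyroglutamate:
            mods_match = False
        if i == n and a.amidated != b.amidated:
            mods_match = False
        if ra == rb and mods_match:
            identical.add(i)
        elif ra == rb or any(ra in g and rb in g for g in CONSERVED_GROUPS):
            conserved.add(i)
        else:
            different.add(i)
    return PositionComparison(
        frozenset(identical), frozenset(conserved), frozenset(different)
    )
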