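"""Derive mature peptides from neuropeptide preprohormones.

A preprohormone is processed in three conceptual steps that this module
reproduces in silico:

1. the signal peptide is removed (taken from annotation or configuration
   — never predicted here);
2. prohormone convertases cleave at basic motifs (dibasic KR/RR/KK/RK by
   default, monobasic R optionally);
3. a C-terminal glycine (optionally followed by up to two basic
   residues) on a fragment is converted into a C-terminal amide, and an
   N-terminal glutamine cyclizes to pyroglutamate.

The paper-facing entry point is :func:`cleave`; the lower-level
:func:`fragment_precursor` exposes the full segmentation, which
reconstructs the precursor exactly when concatenated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .peptides import AMINO_ACIDS, MaturePeptide, PeptideError

DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")

_AMIDE_TAIL = re.compile(r"G[KR]{0,2}$")
_SIGNAL_TAG = re.compile(r"signal_end=(\d+)")


@dataclass(frozen=True)
class Precursor:
    """A preprohormone sequence with an annotated signal-peptide boundary.

    ``signal_end`` is the 0-based exclusive index where the signal
    peptide ends (residues ``[0:signal_end]`` are signal); ``None``
    means unannotated.
    """

    id: str
    residues: str
    signal_end: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError(f"precursor {self.id!r}: empty residues")
        body = self.residues[:-1] if self.residues.endswith("*") else self.residues
        bad = set(body) - AMINO_ACIDS
        if bad:
            raise PeptideError(
                f"precursor {self.id!r}: illegal residue(s) {sorted(bad)!r}"
            )
        if self.signal_end is not None and not 0 <= self.signal_end <= len(body):
            raise PeptideError(
                f"precursor {self.id!r}: signal_end {self.signal_end} out of range"
            )


@dataclass(frozen=True)
class ProcessingParams:
    """Convertase and amidation conventions used by :func:`cleave`.

    The source literature assumes standard prohormone processing without
    stating rules; these defaults are a declared convention.
    """

    cleavage_motifs: tuple[str, ...] = DIBASIC_MOTIFS
    monobasic_r: bool = False
    min_len: int = 5
    max_len: int = 20
    cyclize_e: bool = False
    default_signal_end: int = 1  # fixed trim when signal_end is unannotated

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.min_len > self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class Segment:
    """One piece of the precursor: kind in {signal, body, amide, motif, stop}."""

    kind: str
    start0: int  # 0-based half-open in the precursor
    end0: int
    text: str


def fragment_precursor(
    precursor: Precursor, params: ProcessingParams = ProcessingParams()
) -> list[Segment]:
    """Segment a precursor into signal / peptide bodies / processing residues.

    Concatenating ``seg.text`` over the returned list reproduces
    ``precursor.residues`` exactly (conservation of sequence).  Cleavage
    motifs are found left-to-right and consumed greedily; dibasic motifs
    take precedence over monobasic R at the same position.
    """
    res = precursor.residues
    sig_end = (
        precursor.signal_end
        if precursor.signal_end is not None
        else min(params.default_signal_end, len(res))
    )
    segments: list[Segment] = []
    if sig_end:
        segments.append(Segment("signal", 0, sig_end, res[:sig_end]))

    chain_end = len(res)
    has_stop = res.endswith("*")
    if has_stop:
        chain_end -= 1

    # locate cleavage motifs downstream of the signal
    cuts: list[tuple[int, int]] = []  # (start0, end0) of removed motifs
    j = sig_end
    while j < chain_end:
        if res[j : j + 2] in params.cleavage_motifs and j + 2 <= chain_end:
            cuts.append((j, j + 2))
            j += 2
        elif params.monobasic_r and res[j] == "R":
            cuts.append((j, j + 1))
            j += 1
        else:
            j += 1

    # emit alternating fragment / motif segments
    pos = sig_end
    for cs, ce in cuts + [(chain_end, chain_end)]:
        if cs > pos:
            frag = res[pos:cs]
            m = _AMIDE_TAIL.search(frag)
            if m and m.start() > 0:
                segments.append(
                    Segment("body", pos, pos + m.start(), frag[: m.start()])
                )
                segments.append(
                    Segment("amide", pos + m.start(), cs, frag[m.start() :])
                )
            else:
                segments.append(Segment("body", pos, cs, frag))
        if ce > cs:
            segments.append(Segment("motif", cs, ce, res[cs:ce]))
        pos = ce
    if has_stop:
        segments.append(Segment("stop", chain_end, chain_end + 1, "*"))
    return segments


def cleave(
    precursor: Precursor, params: ProcessingParams = ProcessingParams()
) -> list[MaturePeptide]:
    """Predict the mature peptides released from a preprohormone.

    A fragment becomes a reported peptide only when it shows processing
    evidence — a flanking cleavage motif on either side or a C-terminal
    amidation signal; an intact chain bearing no signals yields nothing.
    Fragments outside ``[min_len, max_len]`` are dropped.  Spans are
    1-based inclusive over the retained residues.
    """
    segments = fragment_precursor(precursor, params)
    peptides: list[MaturePeptide] = []
    for i, seg in enumerate(segments):
        if seg.kind != "body":
            continue
        follows_motif = i > 0 and segments[i - 1].kind == "motif"
        nxt = segments[i + 1] if i + 1 < len(segments) else None
        amidated = nxt is not None and nxt.kind == "amide"
        precedes_motif = (
            nxt is not None
            and (nxt.kind == "motif"
                 or (amidated and i + 2 < len(segments)
                     and segments[i + 2].kind == "motif"))
        )
        if not (follows_motif or precedes_motif or amidated):
            continue
        if not params.min_len <= len(seg.text) <= params.max_len:
            continue
        pyro = seg.text[0] == "Q" or (params.cyclize_e and seg.text[0] == "E")
        peptides.append(
            MaturePeptide(
                residues=seg.text,
                pyroglutamate=pyro,
                amidated=amidated,
                source_id=precursor.id,
                source_span=(seg.start0 + 1, seg.end0),
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def read_precursor_fasta(
    path: str | Path, signal_ends: dict[str, int] | None = None
) -> list[Precursor]:
    """Read precursors from FASTA; ``signal_end=N`` header tags or a
    sidecar mapping supply signal-peptide boundaries."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sig = None
        m = _SIGNAL_TAG.search(rec.description)
        if m:
            sig = int(m.group(1))
        if signal_ends and rec.id in signal_ends:
            sig = signal_ends[rec.id]
        out.append(Precursor(rec.id, str(rec.seq).upper(), sig))
    return out


def write_peptides_tsv(peptides: Iterable[MaturePeptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tstart\tend\tsequence\tpyroglutamate\tamidated\tnotation\n")
        for p in peptides:
            s, e = p.source_span if p.source_span else ("", "")
            fh.write(
                f"{p.source_id}\t{s}\t{e}\t{p.residues}\t"
                f"{int(p.pyroglutamate)}\t{int(p.amidated)}\t{p.notation()}\n"
            )


def write_peptides_fasta(peptides: Iterable[MaturePeptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peptides, 1):
            fh.write(f">{p.source_id or 'peptide'}|{i} {p.notation()}\n{p.residues}\n")
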