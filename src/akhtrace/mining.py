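"""Hallmark-based mining of protein and nucleotide databases.

A desk-scale replacement for TBLASTN screening of EST/genome databases:
instead of similarity search, every Q-anchored window of a protein (or
six-frame-translated nucleotide) sequence is evaluated against the AKH
hallmark rules, in precursor context — a window is a candidate mature
peptide when it ends at a glycine amidation signal (G plus up to two
basic residues, itself flanked by a convertase motif, a stop, or the
frame end) or directly at a convertase motif / frame end.  Exhaustive,
deterministic, and alignment-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq
from Bio import SeqIO

from .hallmarks import Classification, classify
from .peptides import MaturePeptide
from .processing import DIBASIC_MOTIFS

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class MinerConfig:
    min_len: int = 8
    max_len: int = 14
    include_proto: bool = False
    require_q_anchor: bool = True
    cleavage_motifs: tuple[str, ...] = DIBASIC_MOTIFS

    @property
    def accepted_labels(self) -> frozenset[str]:
        base = {"true_AKH", "AKH_like", "ACP"}
        if self.include_proto:
            base.add("proto_AKH")
        return frozenset(base)


@dataclass(frozen=True)
class MinerHit:
    """One candidate peptide found in a scanned residue frame.

    ``start``/``end`` are 1-based inclusive coordinates in the scanned
    frame's residue string (``frame='protein'`` for protein input).
    """

    record_id: str
    frame: str
    start: int
    end: int
    candidate: MaturePeptide
    classification: Classification


def six_frame_translate(nt_sequence: str) -> dict[str, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; stops rendered ``*``; ``N`` translates to
    ``X``.  Forward frame ``+i`` starts at offset ``i-1``; reverse
    frames are read from the reverse complement.
    """
    if not nt_sequence:
        raise ValueError("empty nucleotide sequence")
    nt = nt_sequence.upper()
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)!r}")
    fwd = Seq(nt)
    rev = fwd.reverse_complement()
    out: dict[str, str] = {}
    for i in range(3):
        for strand, seq in (("+", fwd), ("-", rev)):
            sub = seq[i:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[f"{strand}{i + 1}"] = str(sub.translate())
    return out


def _boundary(s: str, pos: int, motifs: tuple[str, ...]) -> bool:
    return pos >= len(s) or s[pos] == "*" or s[pos : pos + 2] in motifs


def _amide_signal(s: str, j: int, motifs: tuple[str, ...]) -> bool:
    """Is there a terminally anchored amidation signal G[KR]{0,2} at j?"""
    if j >= len(s) or s[j] != "G":
        return False
    for nb in range(3):
        tail = s[j + 1 : j + 1 + nb]
        if len(tail) == nb and all(c in "KR" for c in tail) and _boundary(
            s, j + 1 + nb, motifs
        ):
            return True
    return False


def scan_frame(
    record_id: str, frame: str, s: str, config: MinerConfig = MinerConfig()
) -> list[MinerHit]:
    """Evaluate all candidate windows of one residue string."""
    hits: list[MinerHit] = []
    anchors = (
        [i for i, c in enumerate(s) if c == "Q"]
        if config.require_q_anchor
        else range(len(s))
    )
    for i in anchors:
        for length in range(config.min_len, config.max_len + 1):
            j = i + length
            if j > len(s):
                break
            window = s[i:j]
            if "*" in window or "X" in window:
                continue
            if _amide_signal(s, j, config.cleavage_motifs):
                amidated = True
            elif _boundary(s, j, config.cleavage_motifs):
                amidated = False
            else:
                continue
            cand = MaturePeptide(
                residues=window,
                pyroglutamate=window[0] == "Q",
                amidated=amidated,
                source_id=record_id,
                source_span=(i + 1, j),
            )
            cls = classify(cand)
            if cls.label in config.accepted_labels:
                hits.append(MinerHit(record_id, frame, i + 1, j, cand, cls))
    return hits


def scan(
    fasta_path: str | Path,
    config: MinerConfig = MinerConfig(),
    nucleotide: bool = False,
) -> list[MinerHit]:
    """Scan a FASTA database for hallmark-matching candidate peptides.

    Protein databases are scanned directly (``frame='protein'``);
    nucleotide databases are scanned in all six translation frames.
    Hits are ordered by (record, frame, start) and independent of record
    order in the file.
    """
    hits: list[MinerHit] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if nucleotide:
            for frame, aa in six_frame_translate(seq).items():
                hits.extend(scan_frame(rec.id, frame, aa, config))
        else:
            hits.extend(scan_frame(rec.id, "protein", seq, config))
    hits.sort(key=lambda h: (h.record_id, FRAMES.index(h.frame) if h.frame in FRAMES else -1, h.start, h.end))
    return hits


def write_hits_tsv(hits: Iterable[MinerHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tframe\tstart\tend\tcandidate\tlabel\tn_hallmarks\n")
        for h in hits:
            fh.write(
                f"{h.record_id}\t{h.frame}\t{h.start}\t{h.end}\t"
                f"{h.candidate.notation()}\t{h.classification.label}\t"
                f"{h.classification.profile.n_hallmarks}\n"
            )
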