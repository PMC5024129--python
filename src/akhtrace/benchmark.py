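"""Ground-truth benchmarks over synthetic data.

Couples the generator's ground truth to the processing, classification
and mining stages and computes per-class precision/recall.  At
mutation_rate = 0 the synthetic design guarantees perfect separability;
at higher rates these functions quantify degradation (reported, not
asserted).
"""

from __future__ import annotations

from dataclasses import dataclass

from .hallmarks import LABELS, classify
from .mining import MinerConfig, scan_frame, six_frame_translate
from .processing import ProcessingParams, cleave
from .simulate import PrecursorSet, est_database


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0


def processing_benchmark(
    pset: PrecursorSet, params: ProcessingParams = ProcessingParams()
) -> dict[str, ClassMetrics]:
    """Run cleave + classify over a synthetic set and score per class.

    Each ground-truth peptide is matched by precursor span to a
    recovered peptide; a span match with the right label is a true
    positive for that label, a wrong or missing recovery a false
    negative, and every recovered-and-classified peptide that matches no
    ground truth a false positive for its predicted label.
    """
    truth_by_record = {t.record_id: t for t in pset.truth}
    tp = {l: 0 for l in LABELS}
    fp = {l: 0 for l in LABELS}
    fn = {l: 0 for l in LABELS}
    for prec in pset.precursors:
        t = truth_by_record[prec.id]
        want_span = t.mature.source_span
        matched = False
        for pep in cleave(prec, params):
            label = classify(pep).label
            if (
                pep.source_span == want_span
                and pep.residues == t.mature.residues
                and pep.pyroglutamate == t.mature.pyroglutamate
                and pep.amidated == t.mature.amidated
            ):
                matched = True
                if label == t.expected_label:
                    tp[label] += 1
                else:
                    fp[label] += 1
                    fn[t.expected_label] += 1
            else:
                fp[label] += 1
        if not matched:
            fn[t.expected_label] += 1
    return {l: ClassMetrics(tp[l], fp[l], fn[l]) for l in LABELS}


def miner_recall(
    pset: PrecursorSet, seed: int = 0, config: MinerConfig = MinerConfig()
) -> tuple[float, int, int]:
    """Recall of the six-frame miner on reverse-translated precursors.

    Counts a ground-truth peptide as found when some frame of its EST
    record yields a hit whose candidate has the same residues and
    modification flags.  Returns (recall, n_found, n_expected) over the
    ground-truth peptides whose class the miner is configured to report.
    """
    ests = dict(est_database(pset, seed=seed))
    found = expected = 0
    for t in pset.truth:
        if t.expected_label not in config.accepted_labels:
            continue
        expected += 1
        frames = six_frame_translate(ests[f"est_{t.record_id}"])
        for frame, aa in frames.items():
            hits = scan_frame(t.record_id, frame, aa, config)
            if any(
                h.candidate.residues == t.mature.residues
                and h.candidate.amidated == t.mature.amidated
                for h in hits
            ):
                found += 1
                break
    return (found / expected if expected else 1.0), found, expected
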