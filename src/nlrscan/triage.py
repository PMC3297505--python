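"""Candidate triage: acceptance thresholds, the rescue rule, gene collapsing.

A scanned protein is rejected outright when its combined E-value reaches the
initial cap (default 2).  Below the cap it is accepted when its E-value falls
under the training-set thresholds (strictly under the positive maximum ->
``accepted_strict``; under the negative minimum -> ``accepted``).  Sequences
between the negative minimum and the cap are kept only when their motif
content looks like a truncated/distorted NB-LRR: at least two distinct
TIR/CC-class motifs or three distinct NB-ARC-class motifs (``rescued``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .motifs import NB_ARC_MOTIFS, TIR_CC_MOTIFS
from .scan import DEFAULT_P_CUTOFF, Calibration, SequenceMotifProfile


@dataclass
class CandidateStatus:
    sequence_id: str
    status: str  # accepted_strict | accepted | rescued | rejected
    reason: str
    log10_e: float
    qualifying_motifs: frozenset[int] = field(default_factory=frozenset)


def rescue_check(
    profile: SequenceMotifProfile, p_cutoff: float = DEFAULT_P_CUTOFF
) -> tuple[bool, frozenset[int]]:
    """Distorted-NB-LRR rescue rule on best-hit motif content.

    True iff the profile carries >= 2 distinct TIR/CC-class motifs or
    >= 3 distinct NB-ARC-class motifs with best-window p <= p_cutoff.
    Distinct motifs are counted (not hits), so tandem repeats of one motif
    cannot trigger a rescue.
    """
    present = profile.motif_ids_at(p_cutoff)
    tir_cc = frozenset(present & TIR_CC_MOTIFS)
    nb_arc = frozenset(present & NB_ARC_MOTIFS)
    if len(tir_cc) >= 2:
        return True, tir_cc
    if len(nb_arc) >= 3:
        return True, nb_arc
    return False, frozenset()


def triage(
    profiles: list[SequenceMotifProfile],
    calibration: Calibration,
    initial_cap: float = 2.0,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[CandidateStatus]:
    """Assign exactly one status to every profile (total function)."""
    log_cap = math.log10(initial_cap)
    out = []
    for prof in profiles:
        e = prof.log10_e
        if e >= log_cap:
            st = CandidateStatus(prof.sequence_id, "rejected",
                                 f"E >= {initial_cap:g}", e)
        elif e < calibration.log10_t_strict:
            st = CandidateStatus(prof.sequence_id, "accepted_strict",
                                 "E below positive-set maximum", e)
        elif e < calibration.log10_t_main:
            st = CandidateStatus(prof.sequence_id, "accepted",
                                 "E below negative-set minimum", e)
        else:
            ok, quals = rescue_check(prof, p_cutoff)
            if ok:
                kind = "TIR/CC" if quals <= TIR_CC_MOTIFS else "NB-ARC"
                st = CandidateStatus(
                    prof.sequence_id, "rescued",
                    f"{len(quals)} distinct {kind} motifs: "
                    + ",".join(map(str, sorted(quals))),
                    e, quals,
                )
            else:
                st = CandidateStatus(prof.sequence_id, "rejected",
                                     "E above negative-set minimum, "
                                     "no qualifying motif pattern", e)
        out.append(st)
    return out


def collapse_to_genes(
    candidates: list[CandidateStatus],
    transcript_to_gene: dict[str, str],
) -> dict[str, list[str]]:
    """Collapse non-rejected candidate transcripts to distinct gene ids.

    Returns gene id -> supporting transcript ids.  Transcripts without a
    mapping entry raise; sequences that are their own gene should be mapped
    to themselves by the caller (single-transcript convention).
    """
    genes: dict[str, list[str]] = {}
    for cand in candidates:
        if cand.status == "rejected":
            continue
        if cand.sequence_id not in transcript_to_gene:
            raise KeyError(f"no gene mapping for transcript {cand.sequence_id!r}")
        genes.setdefault(transcript_to_gene[cand.sequence_id], []).append(
            cand.sequence_id
        )
    return genes
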