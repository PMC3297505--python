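"""TNL/CNL classification, coiled-coil prediction, subtypes, R-gene homology.

Class assignment is motif-driven: any TIR motif (13, 15, 18) makes a gene a
TNL, everything else is a CNL; the class-discriminating residue in the final
position of the Kin-2 motif (aspartate in TNLs, tryptophan in CNLs) is used
as a cross-check and conflicts are flagged, never silently resolved.

Coiled-coil presence is scored by a heptad-register propensity scanner: every
28-residue window is scored under all seven heptad registers (hydrophobics
rewarded at core positions a/d, charged residues at flanks e/g, proline
penalised throughout) and the best window score within the allowed start
range is mapped to a p-score through a packaged empirical null distribution
(best-window scores of simulated non-coiled proteins).  The acceptance
thresholds — p-score <= 0.047 for domains starting within the first 98
amino acids — are applied to that p-score; a table of externally computed
coiled-coil predictions can override the scanner verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align

from .genomeio import GeneModel
from .motifs import AMINO_ACIDS, LRR_MOTIFS, TIR_MOTIFS
from .reannotation import StructureCall
from .scan import BACKGROUND, DEFAULT_P_CUTOFF, MotifHit, load_substitution_matrix

CC_WINDOW = 28  # four heptads
CC_P_CUTOFF = 0.047
CC_MAX_START = 98  # 1-based latest allowed start position
CNL_EVIDENCE_MOTIFS = frozenset({2, 6, 16, 17})

_AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# heptad propensities per register position class:
#   core (a, d): aliphatic-hydrophobic favoured
#   flank (e, g): charged/polar favoured
#   surface (b, c, f): weakly polar
_CORE = {"L": 3.0, "I": 2.5, "V": 2.0, "M": 2.0, "F": 1.5, "A": 1.0,
         "Y": 0.5, "W": 0.5, "C": -0.5, "T": -0.5, "Q": -0.5, "H": -0.5,
         "S": -1.0, "E": -1.0, "K": -1.0, "R": -1.0, "N": -1.0, "D": -1.5,
         "G": -2.0, "P": -5.0}
_FLANK = {"E": 1.5, "K": 1.5, "R": 1.2, "Q": 1.0, "D": 0.5, "A": 0.5,
          "L": 0.3, "S": 0.0, "N": 0.0, "T": 0.0, "H": 0.0, "M": 0.0,
          "I": -0.2, "V": -0.2, "F": -0.5, "Y": -0.5, "W": -0.5, "C": -0.5,
          "G": -1.5, "P": -5.0}
_SURFACE = {"A": 0.5, "E": 0.5, "K": 0.5, "Q": 0.5, "R": 0.3, "L": 0.2,
            "S": 0.0, "N": 0.0, "D": 0.0, "T": 0.0, "H": 0.0, "M": 0.0,
            "I": 0.0, "V": 0.0, "F": -0.2, "Y": -0.2, "W": -0.2, "C": -0.2,
            "G": -1.0, "P": -5.0}

HEPTAD_TABLE = np.zeros((7, 20))
for _pos, _tab in enumerate([_CORE, _SURFACE, _SURFACE, _CORE, _FLANK,
                             _SURFACE, _FLANK]):  # a b c d e f g
    for _aa, _v in _tab.items():
        HEPTAD_TABLE[_pos, _AA_IDX[_aa]] = _v


@dataclass
class CcPrediction:
    p_score: float
    start_pos: int  # 1-based position of the best-scoring window
    present: bool
    score: float = float("nan")


def _encode20(protein: str) -> np.ndarray:
    return np.fromiter((_AA_IDX.get(c, -1) for c in protein.upper()),
                       dtype=np.int64, count=len(protein))


def cc_window_scores(protein: str) -> np.ndarray:
    """Best-register mean heptad propensity of every 28-residue window."""
    idx = _encode20(protein)
    n = len(idx) - CC_WINDOW + 1
    if n <= 0:
        return np.empty(0)
    # per-residue score for each of the 7 registers; unknown residues score -1
    per = np.full((7, len(idx)), -1.0)
    known = idx >= 0
    pos = np.arange(len(idx))
    for r in range(7):
        per[r, known] = HEPTAD_TABLE[(pos[known] + r) % 7, idx[known]]
    csum = np.cumsum(np.pad(per, ((0, 0), (1, 0))), axis=1)
    window = (csum[:, CC_WINDOW:] - csum[:, :-CC_WINDOW]) / CC_WINDOW
    return window.max(axis=0)


def best_cc_window(protein: str, max_start: int = CC_MAX_START
                   ) -> tuple[float, int]:
    """Best window score among windows starting within ``max_start`` (1-based)."""
    scores = cc_window_scores(protein)
    if len(scores) == 0:
        return float("-inf"), 0
    scores = scores[:max_start]
    best = int(np.argmax(scores))
    return float(scores[best]), best + 1


def simulate_cc_null(n: int, seed: int, length: int = 300,
                     max_start: int = CC_MAX_START) -> np.ndarray:
    """Best-window scores of ``n`` simulated background (non-coiled) proteins."""
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    out = np.empty(n)
    for i in range(n):
        protein = "".join(rng.choice(aas, size=length, p=BACKGROUND))
        out[i], _ = best_cc_window(protein, max_start)
    return np.sort(out)


def _load_cc_null() -> np.ndarray:
    src = resources.files("nlrscan.data").joinpath("cc_null.json")
    return np.asarray(json.loads(src.read_text())["scores"])


_CC_NULL: np.ndarray | None = None


def predict_cc(
    protein: str,
    cc_p_cutoff: float = CC_P_CUTOFF,
    cc_max_start: int = CC_MAX_START,
    null_scores: np.ndarray | None = None,
) -> CcPrediction:
    """Predict an N-terminal coiled-coil domain.

    The p-score is the fraction of null (simulated non-coiled) proteins whose
    best window scores at least as high as the query's best window within the
    allowed start range; present iff p <= cutoff and the window starts within
    ``cc_max_start`` residues.  Deterministic given the packaged null.
    """
    global _CC_NULL
    if null_scores is None:
        if _CC_NULL is None:
            _CC_NULL = _load_cc_null()
        null_scores = _CC_NULL
    if len(protein) < CC_WINDOW:
        return CcPrediction(p_score=1.0, start_pos=0, present=False)
    score, start = best_cc_window(protein, cc_max_start)
    n = len(null_scores)
    ge = n - int(np.searchsorted(null_scores, score, side="left"))
    p = (ge + 1) / (n + 1)
    return CcPrediction(
        p_score=p, start_pos=start,
        present=bool(p <= cc_p_cutoff and 1 <= start <= cc_max_start),
        score=score,
    )


def kin2_terminal_residue(protein: str, motif4_hit: MotifHit | None,
                          p_cutoff: float = DEFAULT_P_CUTOFF) -> str | None:
    """Residue aligned to the final Kin-2 consensus column, if Kin-2 hit."""
    if motif4_hit is None or motif4_hit.p_value > p_cutoff:
        return None
    if motif4_hit.end > len(protein):
        return None
    return protein[motif4_hit.end - 1]


def classify_family(
    motif_ids: set[int], kin2_terminal: str | None
) -> tuple[str, bool, str]:
    """Assign TNL/CNL/unresolved; returns (class, conflict_flag, evidence).

    TIR motif presence is the primary rule; the Kin-2 terminal residue
    (D = TNL, W = CNL) cross-checks it.  A gene with neither TIR motifs, nor
    a Kin-2 hit, nor any CNL-specific motif is unresolved.
    """
    tir = motif_ids & TIR_MOTIFS
    if tir:
        conflict = kin2_terminal == "W"
        ev = f"TIR motifs {sorted(tir)}"
        if kin2_terminal:
            ev += f"; Kin-2 terminal {kin2_terminal}"
        return "TNL", conflict, ev
    if kin2_terminal is None and not (motif_ids & CNL_EVIDENCE_MOTIFS):
        return "unresolved", False, "no TIR motifs, no Kin-2 hit, atypical profile"
    conflict = kin2_terminal == "D"
    ev = "no TIR motifs"
    if motif_ids & CNL_EVIDENCE_MOTIFS:
        ev += f"; CNL motifs {sorted(motif_ids & CNL_EVIDENCE_MOTIFS)}"
    if kin2_terminal:
        ev += f"; Kin-2 terminal {kin2_terminal}"
    return "CNL", conflict, ev


def assign_subtype(nlr_class: str, cc_present: bool, motif_ids: set[int]) -> str:
    """Structural subtype from class, coiled-coil call and LRR motif content."""
    has_lrr = bool(motif_ids & LRR_MOTIFS)
    if nlr_class == "TNL":
        return "TIR-NB-LRR" if has_lrr else "TIR-NB"
    if cc_present:
        return "CC-NB-LRR" if has_lrr else "CC-NB"
    return "NB-LRR" if has_lrr else "NB-ARC"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_substitution_matrix()
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def rgene_homology(
    protein: str,
    panel: dict[str, str],
    identity_cutoff: float = 80.0,
) -> dict | None:
    """Best local-alignment match against a reference R-gene panel.

    Identity is matches / aligned columns (gap columns excluded), in percent.
    Returns {"name", "identity", "coverage", "labelled"} for the best match,
    or None for an empty query.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    if not protein:
        return None
    aligner = _make_aligner()
    best = None
    for name in sorted(panel):
        target = panel[name]
        try:
            aln = aligner.align(protein, target)[0]
        except (ValueError, IndexError):
            continue
        matches = cols = 0
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            cols += qe - qs
            matches += sum(a == b for a, b in
                           zip(protein[qs:qe], target[ts:te]))
        if cols == 0:
            continue
        identity = 100.0 * matches / cols
        cand = {"name": name, "identity": identity,
                "coverage": cols / len(protein)}
        if best is None or identity > best["identity"]:
            best = cand
    if best is None:
        return None
    best["labelled"] = best["identity"] > identity_cutoff
    return best


@dataclass
class NlrAnnotation:
    """A fully re-annotated NB-LRR gene."""

    gene_id: str
    gene: GeneModel
    nlr_class: str  # TNL | CNL | unresolved
    subtype: str
    completeness: str
    kin2_terminal: str | None
    cc: CcPrediction
    motif_ids: set[int]
    structure: StructureCall
    protein: str
    log10_e: float
    class_conflict: bool = False
    homolog_label: str | None = None
    evidence: str = ""
    source_gene_ids: list[str] = field(default_factory=list)
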