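"""Motif scoring engine: position scores, exact window p-values, combined E-values.

Each motif consensus is turned into a position score matrix by taking the
BLOSUM62 substitution row of the consensus residue at every position (integer
log-odds against background residue frequencies).  A window's p-value is the
exact tail probability of its total score under i.i.d. background residues,
obtained by dynamic programming over the integer score support — no sampling,
no asymptotics.

Per-sequence motif evidence is combined Fisher-style over the best hit of
every non-monocot motif.  The best-window p-value is first corrected for the
number of windows scanned (p = min(1, p_window * n_windows)) so that an
unrelated sequence scores near-uniform per motif; the E-value is the combined
probability scaled by the database size.  Because genuine NB-LRR sequences
combine 10+ near-exact motifs, their combined probabilities underflow double
precision; all threshold logic therefore runs on log10(E), while the linear
``e_value`` (combined_p x database size, underflowing to 0) is kept for
reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import chi2

from .motifs import AMINO_ACIDS, SCORED_MOTIFS, MotifDefinition

#: scanning alphabet: 20 standard residues, X (unknown, scores background),
#: * (stop sentinel in six-frame translations, scores worst-case)
ALPHABET = AMINO_ACIDS + "X*"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_X_IDX = _INDEX["X"]

#: Robinson & Robinson background amino-acid frequencies
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: default p-value cutoff for reported (non-best) window hits
DEFAULT_P_CUTOFF = 1e-4


def load_substitution_matrix(name: str = "BLOSUM62"):
    """Load a named integer substitution matrix (Biopython collection)."""
    return substitution_matrices.load(name)


def encode(sequence: str) -> np.ndarray:
    """Encode a protein as indices into the scanning alphabet.

    Unknown characters (including B/Z/U) map to X; ``*`` is preserved.
    """
    return np.fromiter(
        (_INDEX.get(c, _X_IDX) for c in sequence.upper()), dtype=np.int64,
        count=len(sequence),
    )


@dataclass
class MotifScoringModel:
    """Position score matrix for one motif plus its exact null distribution."""

    motif_id: int
    consensus: str
    position_scores: np.ndarray  # (L, len(ALPHABET)) int
    background: np.ndarray  # (20,) strictly positive, sums to 1
    # exact null of the total window score under iid background:
    _null_offset: int = field(repr=False, default=0)
    _null_sf: np.ndarray = field(repr=False, default=None)  # survival function

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def max_score(self) -> int:
        return int(self.position_scores[:, :20].max(axis=1).sum())

    def pvalue(self, score: float) -> float:
        """P(window score >= score) under the background model (exact)."""
        s = math.ceil(score) - self._null_offset
        if s <= 0:
            return 1.0
        if s >= len(self._null_sf):
            return 0.0
        return float(self._null_sf[s])


def build_scoring_model(
    motif: MotifDefinition,
    substitution_matrix=None,
    background: np.ndarray = BACKGROUND,
) -> MotifScoringModel:
    """Build a scoring model from a consensus and a substitution matrix.

    Position ``i`` scores every residue by the substitution-matrix row of the
    consensus residue at ``i`` (integer log-odds against background).  The X
    column is forced to 0 (background-neutral) and the stop sentinel ``*`` to
    the row minimum (worst case), so six-frame translations can be scanned
    directly.
    """
    if substitution_matrix is None:
        substitution_matrix = load_substitution_matrix()
    if background.shape != (20,) or not np.all(background > 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    bad = [(i, c) for i, c in enumerate(motif.consensus) if c not in AMINO_ACIDS]
    if bad:
        pos, res = bad[0]
        raise ValueError(
            f"motif {motif.id}: non-standard residue {res!r} at position {pos}"
        )
    length = len(motif.consensus)
    scores = np.zeros((length, len(ALPHABET)), dtype=np.int64)
    for i, cons in enumerate(motif.consensus):
        row = np.array([substitution_matrix[cons, aa] for aa in AMINO_ACIDS],
                       dtype=np.int64)
        scores[i, :20] = row
        scores[i, _INDEX["X"]] = 0
        scores[i, _INDEX["*"]] = row.min()
    model = MotifScoringModel(
        motif_id=motif.id,
        consensus=motif.consensus,
        position_scores=scores,
        background=background,
    )
    model._null_offset, model._null_sf = _exact_null(scores[:, :20], background)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite position scores")
    return model


def _exact_null(scores: np.ndarray, background: np.ndarray):
    """Exact distribution of the window score sum by integer convolution.

    Returns (offset, sf) with sf[k] = P(S >= k + offset).
    """
    lo = int(scores.min(axis=1).sum())
    hi = int(scores.max(axis=1).sum())
    width = hi - lo + 1
    # start with a point mass at 0, tracked relative to the running minimum
    dist = np.array([1.0])
    run_lo = 0
    for row in scores:
        rlo, rhi = int(row.min()), int(row.max())
        step = np.zeros(rhi - rlo + 1)
        np.add.at(step, row - rlo, background)
        dist = np.convolve(dist, step)
        run_lo += rlo
    assert run_lo == lo and len(dist) == width
    sf = np.cumsum(dist[::-1])[::-1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return lo, sf


def window_scores(seq_idx: np.ndarray, model: MotifScoringModel) -> np.ndarray:
    """Total score of every window of the encoded sequence (vectorised)."""
    length = len(model)
    n = len(seq_idx) - length + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(length):
        out += model.position_scores[j, seq_idx[j:j + n]]
    return out


@dataclass
class MotifHit:
    """One scored window: protein-space coordinates plus optional frame/DNA info."""

    motif_id: int
    sequence_id: str
    start: int  # 0-based, protein space of the scanned frame
    end: int  # exclusive; end - start == motif length
    frame: str  # 'none' or one of +0,+1,+2,-0,-1,-2
    score: float
    p_value: float
    best: bool = False
    dna_start: int | None = None  # set by six-frame rescans
    dna_end: int | None = None


def scan(
    protein: str,
    model: MotifScoringModel,
    sequence_id: str = "",
    p_cutoff: float = DEFAULT_P_CUTOFF,
    frame: str = "none",
) -> list[MotifHit]:
    """Scan a protein with one motif model.

    Returns every window with p <= p_cutoff plus, always, the single
    best-scoring window flagged ``best`` (ties broken by smallest start).
    A protein shorter than the motif yields no hits.
    """
    if len(protein) == 0:
        raise ValueError("empty protein")
    idx = encode(protein)
    totals = window_scores(idx, model)
    if len(totals) == 0:
        return []
    best_i = int(np.argmax(totals))  # argmax takes the first (smallest start) tie
    hits: list[MotifHit] = []
    for i in np.nonzero(
        (totals >= _score_at_cutoff(model, p_cutoff)) | (np.arange(len(totals)) == best_i)
    )[0]:
        p = model.pvalue(totals[i])
        if p <= p_cutoff or i == best_i:
            hits.append(MotifHit(
                motif_id=model.motif_id, sequence_id=sequence_id,
                start=int(i), end=int(i) + len(model), frame=frame,
                score=float(totals[i]), p_value=p, best=(i == best_i),
            ))
    return hits


def _score_at_cutoff(model: MotifScoringModel, p_cutoff: float) -> int:
    """Smallest integer score with pvalue <= p_cutoff (fast pre-filter)."""
    sf = model._null_sf
    k = int(np.searchsorted(-sf, -p_cutoff))
    return k + model._null_offset


def corrected_pvalue(p_window: float, n_windows: int) -> float:
    """Best-window p-value corrected for the number of windows scanned."""
    if n_windows <= 0:
        return 1.0
    return min(1.0, p_window * n_windows)


def _chi2_logsf(x: float, k: int) -> float:
    """log of the chi-square upper tail, finite even deep in the tail.

    scipy's logsf underflows to -inf once sf < ~1e-308; beyond that point the
    standard asymptotic series sf ~ e^{-z} z^{a-1}/Gamma(a) * sum_j prod_{i<j}
    (a-1-i)/z (with a = k/2, z = x/2) is accurate to many digits.
    """
    val = float(chi2.logsf(x, df=k))
    if math.isfinite(val):
        return val
    a, z = k / 2.0, x / 2.0
    term, series = 1.0, 1.0
    for j in range(1, 40):
        term *= (a - j) / z
        series += term
        if abs(term) < 1e-17 * series:
            break
    return -z + (a - 1.0) * math.log(z) - math.lgamma(a) + math.log(max(series, 1e-300))


def combined_evalue(pvalues, database_size: int):
    """Fisher-combine best-hit p-values and scale to an E-value.

    Returns (combined_p, e_value, log10_e).  An empty p-value collection
    gives combined_p = 1 by convention.  e_value = combined_p * database_size
    exactly (so doubling the database doubles it), with log10_e computed in
    log space to survive underflow.
    """
    ps = [float(p) for p in pvalues]
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    if not ps:
        return 1.0, float(database_size), math.log10(database_size)
    stat = -2.0 * sum(math.log(p) for p in ps)
    log_p = _chi2_logsf(stat, 2 * len(ps))
    combined_p = math.exp(log_p)
    e_value = combined_p * database_size
    log10_e = (log_p + math.log(database_size)) / math.log(10)
    return combined_p, e_value, log10_e


@dataclass
class SequenceMotifProfile:
    """Per-sequence motif evidence: best hit per motif and combined E-value."""

    sequence_id: str
    best_hit_per_motif: dict[int, MotifHit]
    ordered_hits: list[MotifHit]
    combined_p: float
    e_value: float
    log10_e: float
    n_windows: dict[int, int] = field(default_factory=dict)
    corrected_p: dict[int, float] = field(default_factory=dict)

    def motif_ids_at(self, p_cutoff: float = DEFAULT_P_CUTOFF) -> set[int]:
        """Motifs present at the cutoff, on the window-count-corrected scale.

        The correction (p * number of windows scanned) makes the false-call
        rate per motif per sequence about ``p_cutoff`` regardless of sequence
        length, which is what a presence/absence call needs.
        """
        return {m for m, p in self.corrected_p.items() if p <= p_cutoff}


def build_profile(
    sequence_id: str,
    hits: list[MotifHit],
    n_windows: dict[int, int],
    database_size: int,
) -> SequenceMotifProfile:
    """Assemble a profile from scan hits of (possibly) several frames.

    The best hit per motif is the highest-scoring window over all supplied
    hits (ties by smallest start); its p-value is corrected by the total
    window count for that motif before entering the Fisher combination.
    Monocot motifs are reported but excluded from the combined statistic.
    """
    best: dict[int, MotifHit] = {}
    for h in hits:
        b = best.get(h.motif_id)
        if b is None or h.score > b.score or (h.score == b.score and h.start < b.start):
            best[h.motif_id] = h
    corrected = {m: corrected_pvalue(h.p_value, n_windows.get(m, 1))
                 for m, h in best.items()}
    ps = [corrected[m] for m in sorted(best) if m in SCORED_MOTIFS]
    combined_p, e_value, log10_e = combined_evalue(ps, database_size)
    return SequenceMotifProfile(
        sequence_id=sequence_id,
        best_hit_per_motif=best,
        ordered_hits=sorted(hits, key=lambda h: (h.start, h.motif_id)),
        combined_p=combined_p,
        e_value=e_value,
        log10_e=log10_e,
        n_windows=dict(n_windows),
        corrected_p=corrected,
    )


def profile_sequence(
    protein: str,
    models: dict[int, MotifScoringModel],
    sequence_id: str,
    database_size: int,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> SequenceMotifProfile:
    """Scan a protein with every model and build its motif profile."""
    hits: list[MotifHit] = []
    n_windows: dict[int, int] = {}
    for mid, model in sorted(models.items()):
        n_windows[mid] = max(0, len(protein) - len(model) + 1)
        hits.extend(scan(protein, model, sequence_id, p_cutoff))
    return build_profile(sequence_id, hits, n_windows, database_size)


@dataclass
class Calibration:
    """Training-set derived acceptance thresholds on the E-value scale."""

    t_strict: float  # maximum E over the positive training set
    t_main: float  # minimum E over the negative training set
    database_size: int
    specific: bool  # every positive E < every negative E
    log10_t_strict: float = -math.inf
    log10_t_main: float = -math.inf


def calibrate(positive_profiles, negative_profiles,
              database_size: int | None = None) -> Calibration:
    """Derive E-value thresholds from positive/negative training profiles.

    t_strict is the highest positive E, t_main the lowest negative E; the
    specificity flag records whether the sets separate completely.  Overlap
    is reported with a warning, never silently.
    """
    if not positive_profiles or not negative_profiles:
        raise ValueError("both training sets must be non-empty")
    lp = max(p.log10_e for p in positive_profiles)
    ln = min(p.log10_e for p in negative_profiles)
    specific = lp < ln
    if not specific:
        warnings.warn(
            "training sets do not separate: max positive E "
            f"(1e{lp:.1f}) >= min negative E (1e{ln:.1f})",
            stacklevel=2,
        )
    if database_size is None:
        database_size = len(positive_profiles) + len(negative_profiles)
    return Calibration(
        t_strict=max(10.0 ** lp, 5e-324),
        t_main=max(10.0 ** ln, 5e-324),
        database_size=max(1, int(database_size)),
        specific=specific,
        log10_t_strict=lp,
        log10_t_main=ln,
    )
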