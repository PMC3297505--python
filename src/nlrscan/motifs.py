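"""Definitions of the 20 NB-LRR diagnostic amino-acid motifs.

The motif set covers the conserved building blocks of plant NB-LRR immune
receptors: the NB-ARC nucleotide-binding module (P-loop, Kin-2, the RNBS
motifs, GLPL), the N-terminal TIR and pre-NB/CC-associated motifs that
discriminate the TNL and CNL superfamilies, the linker and LRR repeats, and
two monocot-specific motifs that are reported but excluded from statistics
and classification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: domain-class membership, fixed by the packaged motif table
NB_ARC_MOTIFS = frozenset({1, 2, 3, 4, 5, 6, 10, 12})
LINKER_MOTIFS = frozenset({7, 8})
LRR_MOTIFS = frozenset({9, 11, 19})
TIR_MOTIFS = frozenset({13, 15, 18})
PRE_NB_MOTIFS = frozenset({16, 17})
MONOCOT_MOTIFS = frozenset({14, 20})
#: "TIR/CC-specific" motifs used by the triage rescue rule
TIR_CC_MOTIFS = TIR_MOTIFS | PRE_NB_MOTIFS
#: motifs entering the combined E-value (monocot pair excluded)
SCORED_MOTIFS = frozenset(range(1, 21)) - MONOCOT_MOTIFS

_DOMAIN_OF = {
    **{m: "NB-ARC" for m in NB_ARC_MOTIFS},
    **{m: "linker" for m in LINKER_MOTIFS},
    **{m: "LRR" for m in LRR_MOTIFS},
    **{m: "TIR" for m in TIR_MOTIFS},
    **{m: "pre-NB" for m in PRE_NB_MOTIFS},
    **{m: "monocot" for m in MONOCOT_MOTIFS},
}

#: position of each motif along the canonical NB-LRR domain series
#: (N-terminal anchors -> NB-ARC series -> linker -> LRR repeats)
CANONICAL_STAGE = {
    16: 0, 17: 0, 13: 0, 15: 0, 18: 0,
    1: 1, 6: 2, 4: 3, 5: 4, 10: 5, 2: 6, 12: 7, 3: 8,
    7: 9, 8: 9,
    9: 10, 11: 10, 19: 10,
}


@dataclass(frozen=True)
class MotifDefinition:
    """One diagnostic motif: consensus sequence plus domain/group labels."""

    id: int
    name: str
    consensus: str
    domain_class: str  # NB-ARC | TIR | pre-NB | linker | LRR | monocot
    group: str  # CNL | TNL | both | none

    def __len__(self) -> int:
        return len(self.consensus)


def load_motifs(path=None) -> dict[int, MotifDefinition]:
    """Load the packaged motif table (or a user override) and validate it.

    The table is a TSV with columns id, name, consensus, domain_class, group.
    Ids must cover exactly 1..20 and domain/group labels must agree with the
    fixed domain partition above.
    """
    if path is None:
        src = resources.files("nlrscan.data").joinpath("motifs.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    motifs: dict[int, MotifDefinition] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        m = MotifDefinition(
            id=int(row["id"]),
            name=row["name"],
            consensus=row["consensus"],
            domain_class=row["domain_class"],
            group=row["group"],
        )
        if m.id in motifs:
            raise ValueError(f"duplicate motif id {m.id}")
        if not m.consensus:
            raise ValueError(f"motif {m.id}: empty consensus")
        bad = [c for c in m.consensus if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"motif {m.id}: non-standard residues {bad}")
        if _DOMAIN_OF[m.id] != m.domain_class:
            raise ValueError(
                f"motif {m.id}: domain_class {m.domain_class!r} does not match "
                f"the fixed partition ({_DOMAIN_OF[m.id]!r})"
            )
        expected_group = (
            "TNL" if m.id in TIR_MOTIFS
            else "CNL" if m.id in PRE_NB_MOTIFS | {2, 6}
            else "none" if m.id in MONOCOT_MOTIFS
            else "both"
        )
        if m.group != expected_group:
            raise ValueError(f"motif {m.id}: group {m.group!r} != {expected_group!r}")
        motifs[m.id] = m
    if set(motifs) != set(range(1, 21)):
        raise ValueError(f"motif ids must cover exactly 1..20, got {sorted(motifs)}")
    return motifs
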