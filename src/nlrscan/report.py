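"""Summary tables and the small ratio helpers used in reporting.

The ratio helpers reproduce the arithmetic used in the published style of
summary: a CNL:TNL ratio from class counts, the percentage of mapped genes
outside clusters, the percentage of homogeneous clusters, and the mapped
fraction of the identified set.
"""

from __future__ import annotations

import pandas as pd


def ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Plain rounded ratio, e.g. CNL:TNL gene counts."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    return round(numerator / denominator, ndigits)


def percent(part: float, whole: float, ndigits: int = 0) -> float:
    """Rounded percentage part/whole * 100."""
    if whole == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round(100.0 * part / whole, ndigits)


def cnl_tnl_ratio(n_cnl: int, n_tnl: int, ndigits: int = 1) -> float:
    return ratio(n_cnl, n_tnl, ndigits)


def percent_unclustered(n_mapped: int, n_clustered: int, ndigits: int = 0
                        ) -> float:
    return percent(n_mapped - n_clustered, n_mapped, ndigits)


def percent_homogeneous(n_homogeneous: int, n_clusters: int, ndigits: int = 0
                        ) -> float:
    return percent(n_homogeneous, n_clusters, ndigits)


def percent_mapped(n_mapped: int, n_identified: int, ndigits: int = 0
                   ) -> float:
    return percent(n_mapped, n_identified, ndigits)


SUBTYPES = ("TIR-NB", "TIR-NB-LRR", "CC-NB", "CC-NB-LRR", "NB-LRR", "NB-ARC")


def subtype_summary(annotations: dict) -> pd.DataFrame:
    """Class/subtype count table; subtype counts partition the gene set."""
    counts = dict.fromkeys(SUBTYPES, 0)
    classes = {"TNL": 0, "CNL": 0, "unresolved": 0}
    for ann in annotations.values():
        classes[ann.nlr_class] += 1
        counts[ann.subtype] += 1
    rows = [{"category": "TNL", "count": classes["TNL"]}]
    rows += [{"category": s, "count": counts[s]} for s in SUBTYPES[:2]]
    rows += [{"category": "CNL", "count": classes["CNL"]}]
    rows += [{"category": s, "count": counts[s]} for s in SUBTYPES[2:]]
    rows += [{"category": "unresolved", "count": classes["unresolved"]},
             {"category": "total", "count": len(annotations)}]
    return pd.DataFrame(rows)


def summary_counts(annotations: dict, placements, clusters) -> dict:
    """Headline counts plus the derived ratios."""
    mapped = [p for p in placements if p.is_nlr]
    clustered = {m for c in clusters for m in c.members}
    n_tnl = sum(a.nlr_class == "TNL" for a in annotations.values())
    n_cnl = sum(a.nlr_class == "CNL" for a in annotations.values())
    n_homog = sum(c.homogeneity == "homogeneous" for c in clusters)
    out = {
        "n_identified": len(annotations),
        "n_tnl": n_tnl,
        "n_cnl": n_cnl,
        "n_unresolved": len(annotations) - n_tnl - n_cnl,
        "n_mapped": len(mapped),
        "n_clusters": len(clusters),
        "n_clustered": len(clustered),
        "n_homogeneous": n_homog,
    }
    if n_tnl:
        out["cnl_tnl_ratio"] = cnl_tnl_ratio(n_cnl, n_tnl)
    if mapped:
        out["percent_unclustered"] = percent_unclustered(
            len(mapped), len(clustered))
        out["percent_mapped"] = percent_mapped(
            len(mapped), len(annotations))
    if clusters:
        out["percent_homogeneous"] = percent_homogeneous(
            n_homog, len(clusters))
    return out
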