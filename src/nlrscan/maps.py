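"""Deterministic SVG rendering of per-pseudomolecule NB-LRR maps.

One vertical bar per pseudomolecule; genes on the plus strand are labelled
on the left of the bar, minus-strand genes on the right; cluster spans are
marked beside the bar and labels are coloured by class.  The SVG is plain
templated text, so identical inputs give byte-identical files.
"""

from __future__ import annotations

from .clusters import Cluster, GenePlacement

CLASS_COLOUR = {"TNL": "#d4a017", "CNL": "#1f6fb2", "unresolved": "#888888"}


def render_chromosome_map(
    pseudomolecule_id: str,
    length: int,
    placements: list[GenePlacement],
    clusters: list[Cluster],
    classes: dict[str, str],
    height: int = 900,
    width: int = 460,
) -> str:
    """Render one pseudomolecule as an SVG string."""
    bar_x, bar_w = width // 2 - 10, 20
    top, bottom = 40, height - 40
    scale = (bottom - top) / max(length, 1)

    def y(pos: int) -> float:
        return top + pos * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="10">',
        f'<text x="{width // 2}" y="20" text-anchor="middle" '
        f'font-size="14">{pseudomolecule_id}</text>',
        f'<rect x="{bar_x}" y="{top}" width="{bar_w}" '
        f'height="{bottom - top:.1f}" fill="#dddddd" stroke="#555555"/>',
    ]
    genes = sorted((p for p in placements
                    if p.pseudomolecule_id == pseudomolecule_id and p.is_nlr),
                   key=lambda p: (p.start, p.gene_id))
    for g in genes:
        gy = y((g.start + g.end) // 2)
        colour = CLASS_COLOUR.get(classes.get(g.gene_id, "unresolved"),
                                  "#888888")
        if g.strand == "+":
            x0, x1, anchor, tx = bar_x, bar_x - 30, "end", bar_x - 34
        else:
            x0, x1 = bar_x + bar_w, bar_x + bar_w + 30
            anchor, tx = "start", bar_x + bar_w + 34
        parts.append(f'<line x1="{x0}" y1="{gy:.1f}" x2="{x1}" y2="{gy:.1f}" '
                     f'stroke="{colour}"/>')
        parts.append(f'<text x="{tx}" y="{gy + 3:.1f}" text-anchor="{anchor}" '
                     f'fill="{colour}">{g.gene_id}</text>')
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        if c.pseudomolecule_id != pseudomolecule_id:
            continue
        y0, y1 = y(c.span[0]), y(c.span[1])
        parts.append(f'<line x1="{bar_x + bar_w + 6}" y1="{y0:.1f}" '
                     f'x2="{bar_x + bar_w + 6}" y2="{y1:.1f}" '
                     f'stroke="#c0392b" stroke-width="3"/>')
        parts.append(f'<text x="{bar_x + bar_w + 10}" '
                     f'y="{(y0 + y1) / 2:.1f}" fill="#c0392b">'
                     f'{c.cluster_id}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_density_figure(points, model, outliers, width: int = 600,
                          height: int = 480) -> str:
    """Scatter of NB-LRR density points with GMM component ellipses (SVG)."""
    import numpy as np

    xs = points["gene_density"].to_numpy(float)
    ys = points["repeat_density"].to_numpy(float)
    x_max = max(1.0, float(np.nanmax(xs)) * 1.1) if len(xs) else 1.0
    pad = 50

    def sx(v):
        return pad + v / x_max * (width - 2 * pad)

    def sy(v):
        return height - pad - v * (height - 2 * pad)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="10">',
        f'<rect x="{pad}" y="{pad}" width="{width - 2 * pad}" '
        f'height="{height - 2 * pad}" fill="none" stroke="#333333"/>',
        f'<text x="{width // 2}" y="{height - 12}" text-anchor="middle">'
        f'gene density (per Mb)</text>',
        f'<text x="14" y="{height // 2}" transform="rotate(-90 14 '
        f'{height // 2})" text-anchor="middle">repeat density</text>',
    ]
    for k in range(len(model.weights)):
        mx, my = model.means[k]
        cov = model.covariances[k]
        for scale in (1.0, 2.0):
            rx = scale * float(np.sqrt(cov[0, 0]))
            ry = scale * float(np.sqrt(cov[1, 1]))
            parts.append(
                f'<ellipse cx="{sx(mx):.1f}" cy="{sy(my):.1f}" '
                f'rx="{rx / x_max * (width - 2 * pad):.1f}" '
                f'ry="{ry * (height - 2 * pad):.1f}" fill="none" '
                f'stroke="#666666" stroke-dasharray="4 3"/>')
    flagged = set(outliers)
    for gid, x, v in zip(points["gene_id"], xs, ys):
        colour = "#c0392b" if gid in flagged else "#1f6fb2"
        parts.append(f'<circle cx="{sx(x):.1f}" cy="{sy(v):.1f}" r="3" '
                     f'fill="{colour}"/>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
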