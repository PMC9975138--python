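"""Ideogram rendering for painted haplotypes.

Fixed colour semantics: the first three reference groups (sorted by
name) are blue, red and yellow; shared two-group labels blend to
purple (1+2), green (1+3) and orange (2+3); ``unspecific`` is grey and
``absent`` black.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .painting import ABSENT, UNSPECIFIC, PaintedTrack

__all__ = ["label_colors", "render_ideogram"]

_SINGLE = ("#1f77f0", "#d62728", "#ffdf00")  # blue, red, yellow
_PAIR = {(0, 1): "#7b2d8e", (0, 2): "#2ca02c", (1, 2): "#ff7f0e"}


def label_colors(group_names: list[str]) -> dict[str, str]:
    """Deterministic label -> colour map for up to three groups."""
    names = sorted(group_names)
    if len(names) > 3:
        raise ValueError("colour map defined for at most three reference groups")
    colors = {g: _SINGLE[i] for i, g in enumerate(names)}
    for (i, j), c in _PAIR.items():
        if i < len(names) and j < len(names):
            colors[f"{names[i]}+{names[j]}"] = c
    colors[UNSPECIFIC] = "#9b9b9b"
    colors[ABSENT] = "#000000"
    return colors


def render_ideogram(
    tracks: list[PaintedTrack],
    outfile: str | Path,
    group_names: list[str] | None = None,
) -> Path:
    """One horizontal bar per haplotype, coloured by tract label;
    deterministic row order (sample, haplotype)."""
    if not tracks:
        raise ValueError("no painted tracks to render")
    if group_names is None:
        singles = {lab for t in tracks for _, _, _, lab in t.tracts
                   if lab not in (UNSPECIFIC, ABSENT) and "+" not in lab}
        group_names = sorted(singles)
    colors = label_colors(group_names)
    ordered = sorted(tracks, key=lambda t: (t.sample, t.hap))
    fig, ax = plt.subplots(figsize=(10, 0.28 * len(ordered) + 1.2))
    for row, t in enumerate(ordered):
        for chrom, a, b, label in t.tracts:
            ax.add_patch(Rectangle((a, row), b - a, 0.8,
                                   facecolor=colors.get(label, "#cccccc"),
                                   edgecolor="none"))
    ax.set_ylim(-0.5, len(ordered) + 0.5)
    xmax = max(b for t in ordered for _, _, b, _ in t.tracts)
    xmin = min(a for t in ordered for _, a, _, _ in t.tracts)
    ax.set_xlim(xmin, xmax)
    ax.set_yticks([r + 0.4 for r in range(len(ordered))])
    ax.set_yticklabels([f"{t.sample}/{t.hap}" for t in ordered], fontsize=6)
    ax.set_xlabel("position (bp)")
    handles = [Rectangle((0, 0), 1, 1, facecolor=c) for c in colors.values()]
    ax.legend(handles, list(colors), loc="upper right", fontsize=6, ncol=2)
    fig.tight_layout()
    out = Path(outfile)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
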