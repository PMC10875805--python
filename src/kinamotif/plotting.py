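"""Stacked-letter rendering of logos and anti-logos with matplotlib.

Letters at each flank position are stacked by height (bits), tallest on
top, colored by side-chain class: basic blue, acidic red, hydrophobic
green, aromatic black, polar/uncharged magenta, no-side-chain orange.
Anti-logo letters are drawn below the axis.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from ._alphabet import HALF_WINDOW
from .motif import KinaseProfile, LogoModel

SIDE_CHAIN_COLORS = {
    **dict.fromkeys("RKH", "#1f4fd8"),   # basic
    **dict.fromkeys("DE", "#d62728"),    # acidic
    **dict.fromkeys("AVLIMCP", "#2ca02c"),  # hydrophobic
    **dict.fromkeys("FWY", "#000000"),   # aromatic
    **dict.fromkeys("STNQ", "#c427c4"),  # polar / uncharged
    "G": "#ff7f0e",                      # no side chain
}

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _draw_letter(ax, aa, x, y, height, width=0.8):
    """One glyph scaled to fill a width x height box with corner (x, y)."""
    tp = TextPath((0, 0), aa, size=1.0, prop=_FONT)
    bbox = tp.get_extents()
    if bbox.width == 0 or bbox.height == 0 or height <= 0:
        return
    trans = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(width / bbox.width, height / bbox.height)
        .translate(x, y)
    )
    ax.add_patch(
        PathPatch(trans.transform_path(tp),
                  facecolor=SIDE_CHAIN_COLORS.get(aa, "grey"), edgecolor="none")
    )


def _stack(ax, cells, sign):
    by_offset: dict[int, list] = {}
    for c in cells:
        by_offset.setdefault(c.offset, []).append(c)
    top = 0.0
    for offset, col in by_offset.items():
        col.sort(key=lambda c: c.height)  # tallest ends up outermost
        y = 0.0
        for c in col:
            if sign > 0:
                _draw_letter(ax, c.residue, offset - 0.4, y, c.height)
            else:
                _draw_letter(ax, c.residue, offset - 0.4, -(y + c.height), c.height)
            y += c.height
        top = max(top, y)
    return top


def plot_logo(
    profile_or_logo: KinaseProfile | LogoModel,
    ax=None,
    title: str | None = None,
    show_antilogo: bool = True,
):
    """Render a logo (and optionally its anti-logo, below zero) to an Axes."""
    if isinstance(profile_or_logo, KinaseProfile):
        logo = profile_or_logo.logo
        if title is None:
            title = f"{profile_or_logo.kinase} (n={profile_or_logo.n})"
    else:
        logo = profile_or_logo
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    top = _stack(ax, logo.logo, +1) or 1.0
    bottom = _stack(ax, logo.antilogo, -1) if show_antilogo else 0.0
    ax.axhline(0, color="0.3", lw=0.8)
    ax.set_xlim(-HALF_WINDOW - 0.6, HALF_WINDOW + 0.6)
    ax.set_ylim(-bottom * 1.1 - 0.05, top * 1.1 + 0.05)
    ax.set_xticks(range(-HALF_WINDOW, HALF_WINDOW + 1))
    ax.set_xlabel("position relative to phosphoacceptor")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    return ax


def save_logo_image(profile: KinaseProfile, path) -> None:
    ax = plot_logo(profile)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
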