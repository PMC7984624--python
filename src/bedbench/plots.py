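"""Diagram rendering: Barber-Johnson plane and the CMI/PI quadrant chart.

Both functions take the pipeline's region table (a DataFrame) and write an
SVG or PNG file; the format follows the output extension.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Polygon, Rectangle

from .barber_johnson import EfficiencyThresholds, bor_ray, bto_isoline

__all__ = ["plot_bj", "plot_quadrants"]

_ZONE_COLOURS = {"GREEN": "#b7e4b0", "YELLOW": "#f7e8a0", "RED": "#f2b8b0"}


def plot_bj(
    results,
    out,
    thresholds: EfficiencyThresholds = EfficiencyThresholds(),
    period_days: int = 365,
):
    """Barber-Johnson diagram: TOI (x) vs AvLOS (y) with the three shaded
    zones, the centroid, constant-BOR rays and constant-BTO isolines.

    Points are coloured by centroid distance (dark green = close, dark red
    = far), matching the conventional map colouring.
    """
    if results is None or len(results) == 0:
        warnings.warn("plot_bj: empty results, nothing drawn")
        return None
    t = thresholds
    s_lo, s_hi = bor_ray(t.bor_low), bor_ray(t.bor_high)
    xmax = max(4.0, 1.2 * float(results["toi"].max()))
    ymax = max(1.2 * s_hi * t.toi_high, 1.2 * float(results["avlos"].max()))

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.add_patch(Rectangle((0, 0), xmax, ymax, color=_ZONE_COLOURS["RED"], zorder=0))
    tl, th = t.toi_low, t.toi_high
    yellow = [
        [(tl, 0), (th, 0), (th, th * s_lo), (tl, tl * s_lo)],          # toi in, bor low
        [(tl, tl * s_hi), (th, th * s_hi), (th, ymax), (tl, ymax)],    # toi in, bor high
        [(0, 0), (tl, tl * s_lo), (tl, tl * s_hi)],                    # bor in, toi low... wedge
        [(th, th * s_lo), (xmax, xmax * s_lo), (xmax, min(xmax * s_hi, ymax)), (th, th * s_hi)],
    ]
    for verts in yellow:
        ax.add_patch(Polygon(verts, closed=True, color=_ZONE_COLOURS["YELLOW"], zorder=1))
    green = [(tl, tl * s_lo), (th, th * s_lo), (th, th * s_hi), (tl, tl * s_hi)]
    ax.add_patch(Polygon(green, closed=True, color=_ZONE_COLOURS["GREEN"], zorder=2))

    for bor in (t.bor_low, t.centroid_bor, t.bor_high):
        slope = bor_ray(bor)
        ax.plot([0, xmax], [0, slope * xmax], ls="--", lw=0.8, color="grey", zorder=3)
        ax.annotate(f"BOR {bor:.0%}", (0.82 * xmax, min(slope * 0.82 * xmax, 0.95 * ymax)), fontsize=7)
    for bto in (20, 30, 40, 60):
        c = bto_isoline(bto, period_days)
        if c < xmax + ymax:
            ax.plot([0, min(c, xmax)], [min(c, ymax), max(c - xmax, 0)], ls=":", lw=0.8, color="grey", zorder=3)
            ax.annotate(f"BTO {bto}", (min(c, xmax) * 0.45, max(c - min(c, xmax) * 0.45, 0)), fontsize=7)

    sc = ax.scatter(
        results["toi"],
        results["avlos"],
        c=results.get("centroid_distance"),
        cmap="RdYlGn_r",
        edgecolors="k",
        linewidths=0.4,
        s=28,
        zorder=4,
    )
    if "centroid_distance" in results:
        fig.colorbar(sc, ax=ax, label="distance from centroid")
    centroid_avlos = t.centroid_toi * bor_ray(t.centroid_bor)
    ax.plot(t.centroid_toi, centroid_avlos, marker="+", color="black", ms=12, mew=2, zorder=5)
    ax.set_xlim(0, xmax)
    ax.set_ylim(0, ymax)
    ax.set_xlabel("Turnover interval (days)")
    ax.set_ylabel("Average length of stay (days)")
    ax.set_title("Barber-Johnson diagram")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return Path(out)


def plot_quadrants(results, out):
    """Four-quadrant CMI (x) vs PI (y) chart with the (1, 1) crosshair.

    Quadrant shading follows the four-zone naming: green (CMI > 1, PI < 1),
    yellow (CMI <= 1, PI < 1), orange (CMI > 1, PI >= 1), red (both
    outside).  Points are coloured by the PI/CMI ratio (dark green = high).
    """
    if results is None or len(results) == 0:
        warnings.warn("plot_quadrants: empty results, nothing drawn")
        return None
    cmi, pi = results["cmi"], results["pi"]
    xmin, xmax = min(0.7, float(cmi.min()) * 0.95), max(1.3, float(cmi.max()) * 1.05)
    ymin, ymax = min(0.7, float(pi.min()) * 0.95), max(1.3, float(pi.max()) * 1.05)

    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.add_patch(Rectangle((1, ymin), xmax - 1, 1 - ymin, color=_ZONE_COLOURS["GREEN"], zorder=0))
    ax.add_patch(Rectangle((xmin, ymin), 1 - xmin, 1 - ymin, color=_ZONE_COLOURS["YELLOW"], zorder=0))
    ax.add_patch(Rectangle((1, 1), xmax - 1, ymax - 1, color="#f5cf9e", zorder=0))
    ax.add_patch(Rectangle((xmin, 1), 1 - xmin, ymax - 1, color=_ZONE_COLOURS["RED"], zorder=0))
    ax.axvline(1.0, color="black", lw=1.0, zorder=1)
    ax.axhline(1.0, color="black", lw=1.0, zorder=1)

    colour = pi / cmi
    sc = ax.scatter(cmi, pi, c=colour, cmap="RdYlGn_r", edgecolors="k", linewidths=0.4, s=30, zorder=2)
    fig.colorbar(sc, ax=ax, label="PI / CMI")
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymin, ymax)
    ax.set_xlabel("Case-Mix Index")
    ax.set_ylabel("Performance Index")
    ax.set_title("Complexity and performance quadrants")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return Path(out)
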