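"""Plots for flux distributions and knockout scans (matplotlib, Agg).

Figures are rendered to PNG bytes with timestamp metadata stripped, so the
same inputs always produce the same file — workflow reruns are
byte-reproducible.
"""

from __future__ import annotations

import io

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import FluxKitError
from .fba import FbaResult
from .perturbation import KnockoutRecord

__all__ = ["plot_flux_distribution", "plot_knockout_scan", "plot_essentiality"]


def _render(fig) -> bytes:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100, metadata={"Software": None})
    plt.close(fig)
    return buf.getvalue()


def plot_flux_distribution(result: FbaResult) -> bytes:
    """Bar chart of the optimal flux of every reaction (index order)."""
    if not result.fluxes:
        raise FluxKitError("cannot plot an empty flux distribution")
    fig, ax = plt.subplots(figsize=(8, 4))
    values = list(result.fluxes.values())
    ax.bar(range(len(values)), values, color="steelblue")
    ax.set_xlabel("reaction index")
    ax.set_ylabel("flux (mmol/gDW/hr)")
    title = ", ".join(result.objective_ids)
    ax.set_title(f"flux distribution ({result.sense} {title} = {result.objective_value:.6g})")
    fig.tight_layout()
    return _render(fig)


def plot_knockout_scan(records: list[KnockoutRecord]) -> bytes:
    """Mutant objective per deleted entity set (index order)."""
    if not records:
        raise FluxKitError("cannot plot an empty knockout scan")
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(
        range(len(records)),
        [r.mutant_objective for r in records],
        "o",
        markersize=3,
        color="firebrick",
    )
    ax.axhline(records[0].wild_type_objective, ls="--", lw=1, color="gray",
               label="wild type")
    ax.set_xlabel(f"{records[0].entity_kind} knockout index")
    ax.set_ylabel("mutant objective")
    ax.legend()
    fig.tight_layout()
    return _render(fig)


def plot_essentiality(records: list[KnockoutRecord], threshold_pct: float) -> bytes:
    """Knockout scan with the essentiality cutoff drawn as a horizontal line."""
    if not records:
        raise FluxKitError("cannot plot an empty knockout scan")
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(
        range(len(records)),
        [r.mutant_objective for r in records],
        "o",
        markersize=3,
        color="firebrick",
    )
    wt = records[0].wild_type_objective
    cutoff = wt * (1.0 - threshold_pct / 100.0)
    ax.axhline(cutoff, ls="-", lw=1.2, color="black",
               label=f"essentiality cutoff ({threshold_pct:g}% reduction)")
    ax.axhline(wt, ls="--", lw=1, color="gray", label="wild type")
    ax.set_xlabel(f"{records[0].entity_kind} knockout index")
    ax.set_ylabel("mutant objective")
    ax.legend()
    fig.tight_layout()
    return _render(fig)
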