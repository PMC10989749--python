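"""Static, dependency-free HTML result viewer.

Rebuilds ``index.html`` from whatever stage outputs exist in a pipeline
output directory: every table is linked, key results are rendered as
embedded (base64) PNG figures, and absent stages are shown as not run.
Regeneration from the same inputs is byte-identical.
"""

from __future__ import annotations

import base64
import html
import io
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

__all__ = ["generate_report"]


def _embed(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight",
                metadata={"Software": None})
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode()
    return f'<img src="data:image/png;base64,{data}"/>'


def _read(path: str) -> pd.DataFrame | None:
    if not os.path.exists(path):
        return None
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return df
    except Exception:
        return None


def _discrete_grouping(outdir: str) -> pd.Series | None:
    meta = _read(os.path.join(outdir, "meta.txt"))
    if meta is None:
        return None
    for col in meta.columns:
        vals = meta[col].dropna()
        if vals.dtype == object and 1 < vals.nunique() <= 12:
            return meta[col]
    return None


def _fig_taxonomy(outdir: str) -> str | None:
    for rank in ("genus", "phylum", "family", "species"):
        df = _read(os.path.join(outdir, "Abundance_Tables", f"taxa.{rank}.tsv"))
        if df is not None and df.shape[1]:
            break
    else:
        return None
    top = df.mean(axis=0).sort_values(ascending=False).head(10).index
    plot = df[top].copy()
    plot["other"] = 1.0 - plot.sum(axis=1)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    bottom = None
    for col in plot.columns:
        short = str(col).split(";")[-1]
        ax.bar(range(len(plot)), plot[col], bottom=bottom, label=short, width=0.9)
        bottom = plot[col] if bottom is None else bottom + plot[col]
    ax.set_xticks(range(len(plot)))
    ax.set_xticklabels(plot.index, rotation=90, fontsize=5)
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=5, ncol=2, loc="center left", bbox_to_anchor=(1, 0.5))
    return _embed(fig)


def _fig_alpha(outdir: str) -> str | None:
    alpha = _read(os.path.join(outdir, "Alpha_Diversity", "alpha.tsv"))
    if alpha is None:
        return None
    group = _discrete_grouping(outdir)
    fig, axes = plt.subplots(1, len(alpha.columns), figsize=(3 * len(alpha.columns), 2.8))
    if len(alpha.columns) == 1:
        axes = [axes]
    for ax, col in zip(axes, alpha.columns):
        vals = alpha[col].dropna()
        if group is not None:
            g = group.reindex(vals.index)
            levels = sorted(g.dropna().unique())
            ax.boxplot([vals[g == lev] for lev in levels], tick_labels=levels)
        else:
            ax.boxplot([vals], tick_labels=["all"])
        ax.set_title(col, fontsize=9)
    return _embed(fig)


def _fig_beta(outdir: str) -> str | None:
    dist = _read(os.path.join(outdir, "Distance_Matrix", "taxa.dist.tsv"))
    pcoa = _read(os.path.join(outdir, "Ordination", "pcoa.tsv"))
    if dist is None and pcoa is None:
        return None
    n_panels = (dist is not None) + (pcoa is not None)
    fig, axes = plt.subplots(1, n_panels, figsize=(4.2 * n_panels, 3.4))
    if n_panels == 1:
        axes = [axes]
    i = 0
    if dist is not None:
        im = axes[i].imshow(dist.to_numpy(), cmap="viridis")
        axes[i].set_title("pairwise distance", fontsize=9)
        axes[i].set_xticks([])
        axes[i].set_yticks([])
        fig.colorbar(im, ax=axes[i], shrink=0.8)
        i += 1
    if pcoa is not None:
        group = _discrete_grouping(outdir)
        ax = axes[i]
        if group is not None:
            g = group.reindex(pcoa.index)
            for lev in sorted(g.dropna().unique()):
                sel = (g == lev).to_numpy()
                ax.scatter(pcoa.iloc[sel, 0], pcoa.iloc[sel, 1], s=14, label=str(lev))
            ax.legend(fontsize=7)
        else:
            ax.scatter(pcoa.iloc[:, 0], pcoa.iloc[:, 1], s=14)
        ax.set_xlabel(pcoa.columns[0])
        ax.set_ylabel(pcoa.columns[1] if pcoa.shape[1] > 1 else "")
        ax.set_title("PCoA", fontsize=9)
    return _embed(fig)


def _fig_markers(outdir: str) -> str | None:
    markdir = os.path.join(outdir, "Markers")
    if not os.path.isdir(markdir):
        return None
    for name in sorted(os.listdir(markdir)):
        if not name.endswith(".tsv"):
            continue
        df = pd.read_csv(os.path.join(markdir, name), sep="\t")
        df = df.dropna(subset=["importance"])
        if df.empty:
            continue
        top = df.nlargest(10, "importance").iloc[::-1]
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1))
        labels = [str(f).split(";")[-1] for f in top["feature"]]
        ax.barh(range(len(top)), top["importance"])
        ax.set_yticks(range(len(top)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlabel("importance (mean decrease in accuracy)")
        return _embed(fig)
    return None


def _fig_network(outdir: str) -> str | None:
    path = os.path.join(outdir, "Network", "edges.tsv")
    if not os.path.exists(path):
        return None
    edges = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in edges.itertuples():
        g.add_edge(row.u, row.v, rho=row.rho)
    if g.number_of_nodes() == 0:
        return None
    pos = nx.spring_layout(g, seed=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = ["#c0392b" if g[u][v]["rho"] < 0 else "#27ae60" for u, v in g.edges]
    nx.draw_networkx(
        g, pos, ax=ax, node_size=80, font_size=5, edge_color=colors,
        labels={n: str(n).split(";")[-1] for n in g.nodes},
    )
    ax.axis("off")
    return _embed(fig)


_SECTIONS = (
    ("Taxonomy", "profiling", _fig_taxonomy),
    ("Alpha diversity", "alpha", _fig_alpha),
    ("Beta diversity", "beta", _fig_beta),
    ("Biomarkers", "markers", _fig_markers),
    ("Co-occurrence network", "network", _fig_network),
)


def generate_report(outdir: str | os.PathLike) -> str:
    """Write ``index.html`` summarising everything present under outdir."""
    outdir = str(outdir)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>markerflow results</title>",
        "<style>body{font-family:sans-serif;max-width:1000px;margin:2em auto}"
        "h2{border-bottom:1px solid #ccc} .notrun{color:#999}</style></head><body>",
        "<h1>markerflow result viewer</h1>",
    ]
    any_output = False
    for title, _stage, renderer in _SECTIONS:
        img = renderer(outdir)
        if img is None:
            parts.append(f"<h2 class='notrun'>{title}</h2><p class='notrun'>not run</p>")
        else:
            any_output = True
            parts.append(f"<h2>{title}</h2>{img}")
    if not any_output:
        parts.append("<p><b>Warning:</b> no stage outputs found in this directory.</p>")

    parts.append("<h2>Raw tables</h2><ul>")
    for root, dirs, files in sorted(os.walk(outdir)):
        dirs.sort()
        for name in sorted(files):
            if name.endswith((".tsv", ".txt", ".sh", ".log")):
                rel = os.path.relpath(os.path.join(root, name), outdir)
                parts.append(f"<li><a href='{html.escape(rel)}'>{html.escape(rel)}</a></li>")
    parts.append("</ul></body></html>")
    index = os.path.join(outdir, "index.html")
    with open(index, "w") as fh:
        fh.write("\n".join(parts))
    return index
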