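"""Human-readable summary of a screen analysis: markdown report + figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .infer import ConnectivityEdge, NullModel, build_network  # noqa: E402

__all__ = ["render_report", "feature_plane_figure", "network_figure"]


def feature_plane_figure(pair_df: pd.DataFrame, model: NullModel | None = None,
                         pulse_filter: int | None = 30) -> plt.Figure:
    """Scatter of pairs in the decision plane with the null ellipse and the
    significance contour.  Both axes span [−1, 1]."""
    df = pair_df
    if pulse_filter is not None and "n_pulses" in df.columns:
        df = df[df["n_pulses"] == pulse_filter]
    fig, ax = plt.subplots(figsize=(5, 5))
    null = df[~df["overlapping"]]
    cand = df[df["overlapping"]]
    ax.scatter(null["ItoPeak_norm_scaled"], null["Rbetween_flies"],
               s=18, c="0.6", label="non-overlapping (null)")
    ax.scatter(cand["ItoPeak_norm_scaled"], cand["Rbetween_flies"],
               s=24, c="tab:red", label="overlapping (candidate)")
    if model is not None:
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(model.covariance)
        for level, style in ((1.0, "--"), (model.threshold, "-")):
            if level is None:
                continue
            ell = model.location[:, None] + np.sqrt(level) * (L @ circle)
            ax.plot(ell[0], ell[1], style, color="k", lw=1)
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("scaled normalised response integral")
    ax.set_ylabel("between-fly reliability")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def network_figure(edges: list[ConnectivityEdge]) -> plt.Figure:
    """Signed, weighted network of significant connections."""
    g = build_network(edges, significant_only=True)
    fig, ax = plt.subplots(figsize=(6, 6))
    if g.number_of_edges():
        pos = nx.circular_layout(g)
        colors = ["tab:red" if g.edges[e]["sign"] >= 0 else "tab:blue"
                  for e in g.edges]
        widths = [0.5 + 0.3 * np.sqrt(g.edges[e]["strength"]) for e in g.edges]
        nx.draw_networkx(g, pos, ax=ax, edge_color=colors, width=widths,
                         node_color="0.85", node_size=900, font_size=7,
                         arrows=True)
    ax.set_axis_off()
    fig.tight_layout()
    return fig


def render_report(edges_df: pd.DataFrame, pair_df: pd.DataFrame,
                  outdir: str | Path, model: NullModel | None = None,
                  pulse_filter: int | None = 30) -> dict:
    """Write ``report.md`` plus the decision-plane and network figures.

    Lists every analysed pair exactly once with its strength, sign,
    reliability and significance call.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fig_plane = feature_plane_figure(pair_df, model, pulse_filter)
    fig_plane.savefig(outdir / "feature_plane.png", dpi=120)
    edges = [ConnectivityEdge(pre=r.pre, post=r.post, strength=r.strength,
                              sign=int(r.sign), reliability=r.reliability,
                              significant=bool(r.significant),
                              control=bool(r.control))
             for r in edges_df.itertuples()]
    fig_net = network_figure(edges)
    fig_net.savefig(outdir / "network.png", dpi=120)

    lines = ["# Functional-connectivity screen report", ""]
    if model is not None and model.threshold is not None:
        lines += [f"Significance: squared Mahalanobis distance > "
                  f"{model.threshold:.3f} (α = {model.alpha})", ""]
    n_sig = int(edges_df["significant"].sum())
    lines += [f"{len(edges_df)} pairs analysed, {n_sig} significant.", "",
              "| pre | post | strength | sign | reliability | significant | control |",
              "| --- | --- | --- | --- | --- | --- | --- |"]
    for r in edges_df.itertuples():
        lines.append(
            f"| {r.pre} | {r.post} | {r.strength:.3f} | {r.sign:+d} | "
            f"{r.reliability:.3f} | {'yes' if r.significant else 'no'} | "
            f"{'yes' if r.control else 'no'} |")
    lines += ["", "![feature plane](feature_plane.png)",
              "![network](network.png)", ""]
    (outdir / "report.md").write_text("\n".join(lines))
    out = {"figures": {"feature_plane": fig_plane, "network": fig_net},
           "n_pairs": len(edges_df), "n_significant": n_sig}
    plt.close(fig_plane)
    plt.close(fig_net)
    return out
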