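"""Heatmap and information-flow figures.

Renders a coupling geometry as the permuted coded matrix with block
boundaries from the two marginal trees' selected compositions, and an
information flow as the response heatmap on the left paired with the
serial covariate heatmaps on the right, joined by per-subject membership
ribbons (color stripes showing each subject's response cluster).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def _block_boundaries(labels: np.ndarray, order: np.ndarray) -> list[int]:
    ordered = labels[order]
    return [i for i in range(1, ordered.size) if ordered[i] != ordered[i - 1]]


def plot_coupling_geometry(geometry, path=None, ax=None, cmap="viridis",
                           title: str | None = None):
    """Permuted matrix heatmap with row/column block boundary lines."""
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 6))
    perm = geometry.permuted().to_numpy()
    ax.imshow(perm, aspect="auto", cmap=cmap, interpolation="nearest")
    for b in _block_boundaries(geometry.row_comp.labels, geometry.row_order):
        ax.axhline(b - 0.5, color="white", lw=1.0)
    for b in _block_boundaries(geometry.col_comp.labels, geometry.col_order):
        ax.axvline(b - 0.5, color="white", lw=1.0)
    ax.set_xlabel("features (tree order)")
    ax.set_ylabel("subjects (tree order)")
    if title:
        ax.set_title(title, fontsize=9)
    if own_fig:
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig
    return ax


def _membership_ribbon(ax, resp_labels: np.ndarray, order: np.ndarray):
    _, inv = np.unique(resp_labels, return_inverse=True)
    ax.imshow(inv[order][:, None], aspect="auto", cmap="tab10",
              interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])


def plot_information_flow(result, flow_index: int = 0, path=None):
    """Composite figure: response geometry left, serial covariate geometries right.

    Each covariate panel is preceded by a ribbon coloring subjects by their
    response cluster so exclusive linkages appear as uniformly colored
    blocks.
    """
    flow = result.flows[flow_index]
    resp_gi = flow_index
    resp_geom = result.response_geometries.get(resp_gi)
    n_links = len(flow.links)
    name_to_gi = {f"covariate_group_{gi}": gi
                  for gi in range(len(result.covariate_groups))}

    width_ratios = [4] + [0.4, 4] * n_links
    fig, axes = plt.subplots(
        1, 1 + 2 * n_links, figsize=(4 * (1 + n_links) + 1, 5),
        gridspec_kw={"width_ratios": width_ratios},
    )
    axes = np.atleast_1d(axes)

    resp_comp = flow.links[0].response_comp
    if resp_geom is not None:
        plot_coupling_geometry(resp_geom, ax=axes[0],
                               title="response coupling geometry")
    else:
        axes[0].axis("off")
        axes[0].set_title("response (single feature)", fontsize=9)

    for li, link in enumerate(flow.links):
        gi = name_to_gi.get(link.name)
        geom = result.covariate_geometries.get(gi) if gi is not None else None
        ribbon_ax = axes[1 + 2 * li]
        panel_ax = axes[2 + 2 * li]
        if geom is not None:
            order = geom.row_order
            plot_coupling_geometry(
                geom, ax=panel_ax,
                title=f"{link.name}  H(Y|X)={link.overall_entropy:.2f}",
            )
        else:
            order = np.arange(resp_comp.n)
            panel_ax.axis("off")
            panel_ax.set_title(link.name, fontsize=9)
        _membership_ribbon(ribbon_ax, resp_comp.labels, order)

    fig.suptitle(
        f"information flow: H(Y)={flow.links[0].response_entropy:.2f}, "
        f"serial error={flow.serial_error:.3f}" if flow.serial_error is not None
        else "information flow",
        fontsize=10,
    )
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
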