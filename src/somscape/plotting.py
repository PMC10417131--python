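"""Best-effort rendering of portraits, maps, curves and diagrams.

Rendering is presentation only: nothing downstream consumes these figures,
and they are excluded from the pipeline's bit-reproducibility guarantees.
Portraits use a diverging palette with symmetric limits at the largest
absolute metagene value of the image (blue = under-expression, dark red =
over-expression); HR maps use the same convention on log HR.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt

#: Diverging palette contract: low = dark blue, high = maroon.
PORTRAIT_CMAP = "RdBu_r"


def plot_portrait(image: np.ndarray, title: str | None = None, ax=None, cmap=PORTRAIT_CMAP):
    """Render one metagene image with symmetric color limits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    lim = float(np.nanmax(np.abs(image))) or 1.0
    im = ax.imshow(image, cmap=cmap, vmin=-lim, vmax=lim, origin="upper")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_portrait_gallery(model, samples, ncols: int = 6, path=None):
    """A grid of individual portraits; writes ``path`` if given."""
    samples = list(samples)
    nrows = int(np.ceil(len(samples) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.4 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, s in zip(axes.ravel(), samples):
        ax.axis("on")
        lim = float(np.max(np.abs(model.portrait(s)))) or 1.0
        ax.imshow(model.portrait(s), cmap=PORTRAIT_CMAP, vmin=-lim, vmax=lim)
        ax.set_title(s, fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_hr_map(hrmap, ax=None):
    """Log-scale HR image: red = inferior prognosis, blue = better."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3))
    log_hr = np.log(hrmap.hr)
    lim = float(np.nanmax(np.abs(log_hr))) or 1.0
    im = ax.imshow(log_hr, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"HR map ({hrmap.threshold_mode})", fontsize=9)
    plt.colorbar(im, ax=ax, fraction=0.046, label="log HR")
    return ax


def plot_km(split, ax=None):
    """Kaplan-Meier curves of a risk split with its log-rank p-value."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for group, curve in split.km_curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=f"{group} risk")
    ax.set_xlabel("time")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {split.p_value:.2g}", fontsize=8)
    return ax


def plot_ternary(coords: np.ndarray, labels=None, ax=None):
    """Scatter simplex coordinates (a, b, c), a+b+c=1, in a 2-D triangle."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    x = coords[:, 1] + coords[:, 2] / 2.0
    y = coords[:, 2] * np.sqrt(3) / 2.0
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.6))
    tri_x, tri_y = [0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0]
    ax.plot(tri_x, tri_y, color="black", lw=0.8)
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(x[sel], y[sel], s=12, label=str(lab))
        ax.legend(fontsize=7)
    else:
        ax.scatter(x, y, s=12)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_flows(flow_table, ax=None):
    """Stacked-bar rendering of a subtype x segment contingency table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    bottom = np.zeros(flow_table.shape[1])
    for subtype, row in flow_table.iterrows():
        ax.bar(flow_table.columns, row.to_numpy(), bottom=bottom, label=str(subtype))
        bottom += row.to_numpy()
    ax.set_ylabel("samples")
    ax.legend(fontsize=7)
    return ax
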