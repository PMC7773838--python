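"""Optional 3D scatter / ellipsoid rendering (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import GaussianModel, ellipsoid_axes


def scatter_with_ellipsoid(model: GaussianModel, table, out_path: str | Path) -> None:
    """Plot the angle-triplet cloud with the model's quantile ellipsoid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = table[["ce_deg", "sharp_deg", "tonnis_deg"]].to_numpy(dtype=float)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(x[:, 0], x[:, 1], x[:, 2], s=8, alpha=0.6, label="hips")

    axes = ellipsoid_axes(model)
    u = np.linspace(0, 2 * np.pi, 40)
    v = np.linspace(0, np.pi, 20)
    sphere = np.stack([np.outer(np.cos(u), np.sin(v)),
                       np.outer(np.sin(u), np.sin(v)),
                       np.outer(np.ones_like(u), np.cos(v))], axis=-1)
    basis = np.column_stack([d * h for d, h in axes])
    ell = sphere @ basis.T + model.mu
    ax.plot_wireframe(ell[..., 0], ell[..., 1], ell[..., 2],
                      color="tab:red", alpha=0.25, linewidth=0.5)
    ax.set_xlabel("CE angle (deg)")
    ax.set_ylabel("sharp angle (deg)")
    ax.set_zlabel("Tönnis angle (deg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
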