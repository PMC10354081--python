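"""Static plots of MDE curves and segmented fits (matplotlib, file output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .changepoint import SegmentedResults  # noqa: E402
from .mde import MDECurve  # noqa: E402


def plot_curves(curves: dict[str, MDECurve],
                fits: dict[str, SegmentedResults] | None = None,
                path: str = "mde_curves.pdf") -> str:
    """Overlay smoothed MDE curves (age axis reversed, old to young) and,
    when given, their segmented fits with breakpoint markers."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, curve in curves.items():
        x = curve.midpoints
        ax.plot(x, curve.smoothed, label=label, lw=1.5)
        if fits and label in fits:
            fit = fits[label]
            ax.plot(x, fit.predict(x), ls="--", lw=1, alpha=0.8)
            for psi, _ in fit.breakpoints_by_age():
                ax.axvline(psi, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("events per slice" if not any(c.per_ma for c in curves.values())
                  else "events per Ma")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
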