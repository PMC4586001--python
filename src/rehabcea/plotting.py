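"""Cost-effectiveness acceptability curve plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cea import CEACCurve

__all__ = ["plot_ceac"]


def plot_ceac(curves: Mapping[str, CEACCurve], path: str | Path | None = None,
              title: str = "Cost-effectiveness acceptability curve"):
    """Plot one or more CEACs against willingness to pay (DKK per QALY)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, curve in curves.items():
        ax.plot(curve.lambdas / 1000, curve.probabilities, label=name)
    ax.set_xlabel("Willingness to pay (DKK 1,000 per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    if len(curves) > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
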