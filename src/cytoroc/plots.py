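"""Optional ROC plotting (one panel per marker/score)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .roc import RocCurve


def plot_roc(curve: RocCurve, title: str, path) -> None:
    """Render one empirical ROC trace with its chance diagonal to a file."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post", color="C0")
    ax.plot([0, 1], [0, 1], ls="--", color="0.6", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
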