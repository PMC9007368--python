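"""Forest-style figures for the three per-sector effect families."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .etdrs import SECTORS  # noqa: E402

__all__ = ["forest_plot"]

_SECTOR_ORDER = list(SECTORS)


def forest_plot(df: pd.DataFrame, title: str, path: str | Path,
                alpha: float = 0.05) -> None:
    """One horizontal CI bar per sector (and per term, if several).

    Bonferroni-significant estimates are drawn filled, others open.
    """
    terms = list(df["term"].unique())
    fig, axes = plt.subplots(1, len(terms), figsize=(4.2 * len(terms), 4.0),
                             sharey=True, squeeze=False)
    for ax, term in zip(axes[0], terms):
        sub = df[df["term"] == term].set_index("sector") \
            .reindex(_SECTOR_ORDER).dropna(subset=["estimate_um"])
        y = range(len(sub))
        for yi, (_, row) in zip(y, sub.iterrows()):
            sig = (row["p_adjusted"] is not None
                   and row["p_adjusted"] < alpha)
            ax.plot([row["ci_low"], row["ci_high"]], [yi, yi],
                    color="0.3", lw=1.5)
            ax.plot(row["estimate_um"], yi, "o",
                    mfc=("C3" if sig else "white"), mec="C3", ms=6)
        ax.axvline(0.0, color="0.7", lw=1, zorder=0)
        ax.set_yticks(list(y), sub.index)
        ax.invert_yaxis()
        ax.set_xlabel("estimate (μm)")
        ax.set_title(term)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
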