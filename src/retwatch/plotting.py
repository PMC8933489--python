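"""Simple trajectory and subclone-envelope figures."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .dynamics import SubcloneAssignment


def plot_trajectories(
    traj: pd.DataFrame,
    subclones: Optional[Sequence[SubcloneAssignment]] = None,
    ax=None,
    logscale: bool = True,
):
    """Plot per-variant AF trajectories; shade each subclone's min/max envelope.

    Returns the matplotlib Axes.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(7, 4))
    for vid, sub in traj.groupby("variant_id"):
        sub = sub.sort_values("day")
        ax.plot(sub["day"], sub["af"], marker="o", lw=1, label=str(vid))
    if subclones:
        for sc in subclones:
            days = sorted(sc.envelope)
            lo = [sc.envelope[d][0] for d in days]
            hi = [sc.envelope[d][1] for d in days]
            ax.fill_between(days, lo, hi, alpha=0.2,
                            label=f"{sc.subclone_id} envelope")
    if logscale:
        ax.set_yscale("symlog", linthresh=1e-4)
    ax.set_xlabel("day")
    ax.set_ylabel("allele fraction")
    ax.legend(fontsize=7, ncol=2)
    return ax
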