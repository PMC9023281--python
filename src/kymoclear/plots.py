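"""Figure export: population box plots and intensity time courses."""

from __future__ import annotations

import numpy as np
import pandas as pd


def population_boxplot(events: pd.DataFrame, path=None):
    """Velocity and processivity box plots (median/IQR whiskers).

    ``events`` is the per-motor table from :func:`summarize_events`'
    sibling :func:`events_to_frame`.  Censored and boundary-limited
    events are excluded from the processivity panel, mirroring the
    population summaries.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(5, 3.2))
    vel = events.loc[
        (events.velocity_nt_s > 0)
        & ~events.boundary_limited
        & events.get("velocity_measurable", True),
        "velocity_nt_s",
    ]
    pro = events.loc[
        (events.processivity_knt > 0) & ~events.censored & ~events.boundary_limited,
        "processivity_knt",
    ]
    for ax, vals, label in ((axes[0], vel, "velocity (nt/s)"), (axes[1], pro, "processivity (knt)")):
        if len(vals):
            ax.boxplot([vals], whis=(5, 95), showfliers=True)
        ax.set_ylabel(label)
        ax.set_xticks([])
        ax.set_title(f"N = {len(vals)}", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def intensity_timecourse(aggregated: pd.DataFrame, frame_interval_s: float, path=None):
    """Mean +/- SEM normalized intensity versus time across molecules."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = aggregated["frame"].to_numpy() * frame_interval_s
    mean = aggregated["mean"].to_numpy()
    sem = aggregated["sem"].to_numpy()
    fig, ax = plt.subplots(figsize=(4.2, 3))
    ax.plot(t, mean, lw=1.5)
    ax.fill_between(t, mean - sem, mean + sem, alpha=0.3, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
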