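"""Four-row movement-feature plot (CoM speed, distance, hip velocity
with freeze markers, shank jerk with threshold crossings)."""

from __future__ import annotations

import numpy as np


def plot_features(features, hip_vel=None, freeze_cfg=None, jerk_cfg=None,
                  title=None, ax=None):
    """Plot the four feature rows; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(9, 8), sharex=True)
    t = features.t

    axes[0].plot(t, features.com_speed, lw=1)
    axes[0].set_ylabel("CoM speed\n[bodylengths/s]")

    axes[1].plot(t, features.d, lw=1)
    for k in range(9):
        axes[1].axhline(1 - k / 8, color="0.8", ls=":", lw=0.6)
    axes[1].set_ylabel("distance\nfrom stand")

    if hip_vel is not None:
        axes[2].plot(t, hip_vel, lw=1)
    if freeze_cfg is not None:
        axes[2].axhline(freeze_cfg.velocity_threshold, color="r", ls="--",
                        lw=0.8, label="threshold")
    for ft in np.atleast_1d(features.freeze_times):
        axes[2].axvline(ft, color="k", ls=":", lw=0.8)
    axes[2].set_ylabel("hip velocity\n[deg/s]")

    axes[3].plot(t, features.jerk, lw=1)
    if jerk_cfg is not None:
        axes[3].axhline(jerk_cfg.jerk_threshold, color="r", ls="--", lw=0.8)
    for ct in np.atleast_1d(features.jerk_crossings):
        axes[3].axvline(ct, color="k", ls="--", lw=0.8)
    axes[3].set_ylabel("shank jerk\n[deg/s$^3$]")
    axes[3].set_xlabel("time [s]")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
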