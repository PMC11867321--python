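"""Optional plots (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .stats import paired_comparison


def bland_altman_plot(estimated, measured, ax=None, label: str = "1RM (kg)"):
    """Bland–Altman scatter with bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    rep = paired_comparison(e, m)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((e + m) / 2.0, e - m, color="k", s=20)
    ax.axhline(rep.bias, color="b", label=f"bias {rep.bias:.2f}")
    for bound in (rep.loa_low, rep.loa_high):
        ax.axhline(bound, color="r", linestyle="--")
    ax.set_xlabel(f"mean of estimated and measured {label}")
    ax.set_ylabel(f"estimated - measured {label}")
    ax.legend(loc="best")
    return ax


def jump_trace_plot(analysis, ax=None):
    """Force, COM velocity and phase boundaries of one analyzed trial."""
    import matplotlib.pyplot as plt

    rec = analysis.recording
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(rec.time, rec.force, color="k", lw=0.8, label="vertical GRF (N)")
    ax.axhline(analysis.body_weight.weight, color="gray", lw=0.5)
    for name, (start, _) in analysis.segmentation.phases.items():
        ax.axvline(rec.time[min(start, rec.n_samples - 1)], color="b", lw=0.5, alpha=0.5)
        ax.text(rec.time[min(start, rec.n_samples - 1)], ax.get_ylim()[1], name,
                rotation=90, va="top", fontsize=7)
    ax2 = ax.twinx()
    kin = analysis.kinematics
    ax2.plot(kin.time, kin.velocity, color="r", lw=0.8, label="COM velocity (m/s)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("force (N)")
    ax2.set_ylabel("velocity (m/s)")
    return ax
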