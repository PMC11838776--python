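"""Optional matplotlib views of fit and comparison results."""

from __future__ import annotations

import numpy as np

from .evaluation import GroupComparison, RocCurve
from .io import RegionalTAC


def plot_tac(tac: RegionalTAC, ax=None, **kwargs):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    ax.plot(tac.schedule.mid_times, tac.activity, marker="o", ms=3,
            label=f"{tac.subject_id}/{tac.roi_id}", **kwargs)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"activity ({tac.units})")
    return ax


def plot_roc(roc: RocCurve, ax=None, label: str | None = None):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    ax.plot(1 - roc.specificity, roc.sensitivity,
            label=label or f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax


def plot_comparison(cmp: GroupComparison, ax=None,
                    case_label: str = "case", control_label: str = "control"):
    """Relative-probability histograms of the two cohorts and the bin-by-bin
    deviation (case minus control)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    centers = (cmp.bin_edges[:-1] + cmp.bin_edges[1:]) / 2
    width = np.diff(cmp.bin_edges).mean()
    ax.bar(centers - width / 5, cmp.hist_control, width=0.4 * width,
           label=control_label, alpha=0.7)
    ax.bar(centers + width / 5, cmp.hist_case, width=0.4 * width,
           label=case_label, alpha=0.7)
    ax.step(cmp.bin_edges[:-1], cmp.deviation, where="post", color="k",
            label=f"deviation (Delta_P = {cmp.delta_p:+.0f}%)")
    ax.set_xlabel("p_TSPO")
    ax.set_ylabel("relative probability")
    ax.legend()
    return ax
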