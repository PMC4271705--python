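"""Single-panel plots of precision sweeps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_AXIS_LABELS = {
    "a": "Encounter rate a (L g$^{-1}$ min$^{-1}$)",
    "h": "Handling time h (min g µmol$^{-1}$)",
    "v_max": "V$_{max}$ (µmol g$^{-1}$ min$^{-1}$)",
    "k_m": "K$_m$ (µmol L$^{-1}$)",
}


def plot_sweep(sweep: pd.DataFrame, path: str | Path, log_x: bool = True,
               markers: dict[str, float] | None = None) -> None:
    """Render one precision-sweep panel (one curve per patch level).

    ``markers`` optionally draws labelled dotted vertical lines, e.g. at
    the mean and median observed parameter values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    param = sweep["swept_param"].iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    for n_p, grp in sweep.groupby("patch_conc"):
        ax.plot(grp["value"], grp["p_star"], label=f"$N_p$ = {n_p:g}")
    if markers:
        for name, x in markers.items():
            ax.axvline(x, linestyle=":", color="grey")
            ax.annotate(name, (x, ax.get_ylim()[1]), fontsize=7,
                        ha="center", va="top")
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(_AXIS_LABELS.get(param, param))
    ax.set_ylabel("Root foraging precision $P^*$")
    ax.legend(frameon=False, fontsize=8,
              title=f"$N_b$ = {sweep['background_conc'].iloc[0]:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
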