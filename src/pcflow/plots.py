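"""Scatter and Bland-Altman figures for the method-comparison tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import PARAMETER_SPECS, bland_altman, pearson_ci

__all__ = ["scatter_plot", "bland_altman_plot", "cohort_plots"]


def scatter_plot(method, reference, *, ax=None, label_method="method",
                 label_reference="reference", units=""):
    """Scatter of method vs reference with the identity line and Pearson r."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    m = np.asarray(method, float)
    r = np.asarray(reference, float)
    ax.scatter(r, m, s=18, alpha=0.8)
    lo = min(r.min(), m.min())
    hi = max(r.max(), m.max())
    pad = 0.05 * (hi - lo or 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], "k--", lw=1,
            label="identity")
    try:
        pr = pearson_ci(m, r)
        ax.set_title(f"r = {pr.r:.2f} (p = {pr.p:.3g})", fontsize=10)
    except ValueError:
        pass
    ax.set_xlabel(f"{label_reference} {units}".strip())
    ax.set_ylabel(f"{label_method} {units}".strip())
    ax.legend(fontsize=8)
    return ax


def bland_altman_plot(method, reference, *, ax=None, units=""):
    """Differences vs means with bias and 95% limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    m = np.asarray(method, float)
    r = np.asarray(reference, float)
    ba = bland_altman(m, r)
    mean = (m + r) / 2.0
    ax.scatter(mean, m - r, s=18, alpha=0.8)
    for yv, style in ((ba.bias, "-"), (ba.loa_low, ":"), (ba.loa_high, ":")):
        ax.axhline(yv, color="k", ls=style, lw=1)
    ax.set_title(f"bias = {ba.bias:.2f} ± {ba.sd:.2f} {units}".strip(),
                 fontsize=10)
    ax.set_xlabel(f"mean of methods {units}".strip())
    ax.set_ylabel(f"difference {units}".strip())
    return ax


_UNITS = {"Vmean": "m/s", "Vpeak": "m/s", "MG": "mmHg", "PG": "mmHg",
          "VTI": "cm", "SV": "mL", "AVA_Cine": "cm$^2$", "AVA_Flow": "cm$^2$"}


def cohort_plots(wide: pd.DataFrame, outdir) -> list[Path]:
    """One scatter + Bland-Altman panel per parameter and CMR method."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for param, tmpl, ref_col in PARAMETER_SPECS:
        for tag, meth in (("1dir", "1Dir"), ("3dir", "3Dir")):
            cols = [tmpl.format(m=tag), ref_col]
            sub = wide[cols].dropna()
            if len(sub) < 3:
                continue
            fig, axes = plt.subplots(1, 2, figsize=(8, 4))
            u = _UNITS.get(param, "")
            scatter_plot(sub[cols[0]], sub[cols[1]], ax=axes[0],
                         label_method=meth, label_reference=ref_col, units=u)
            bland_altman_plot(sub[cols[0]], sub[cols[1]], ax=axes[1], units=u)
            fig.suptitle(f"{param}: {meth} vs reference")
            fig.tight_layout()
            p = outdir / f"{param.lower()}_{tag}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            paths.append(p)
    return paths
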