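"""Static exon-plot rendering (convenience output).

One panel per tumor with the tumor and matched-normal exon traces on the log2
scale and the called breakpoint marked. SVG output is made byte-deterministic
by fixing the hash salt and dropping the creation date.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .exon_break import FusionCall
from .types import ExonIntensityProfile


def render_exon_plot(profile: ExonIntensityProfile, calls: list[FusionCall],
                     path, pseudocount: float = 1.0) -> None:
    """Write a multi-panel tumor-vs-normal exon intensity figure."""
    sheet = profile.sheet
    pairs = sheet.pairs() if sheet is not None else None
    by_tumor = {c.sample_id: c for c in calls}
    tumors = [c.sample_id for c in calls]
    ncols = min(4, max(1, len(tumors)))
    nrows = math.ceil(len(tumors) / ncols)
    with plt.rc_context({"svg.hashsalt": "accsig"}):
        fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
                                 squeeze=False, sharex=True)
        x = np.arange(1, profile.n_exons + 1)
        for i, tumor in enumerate(tumors):
            ax = axes[i // ncols][i % ncols]
            normal = None
            if pairs is not None:
                match = pairs.loc[pairs["tumor"] == tumor, "normal"]
                normal = match.iloc[0] if len(match) else None
            t = np.log2(profile.data[tumor].to_numpy() + pseudocount)
            ax.plot(x, t, color="crimson", lw=1.2, label="tumor")
            if normal is not None and normal in profile.data.columns:
                n = np.log2(profile.data[normal].to_numpy() + pseudocount)
                ax.plot(x, n, color="steelblue", lw=1.2, label="normal")
            call = by_tumor[tumor]
            if call.status == "positive" and call.breakpoint is not None:
                ax.axvline(call.breakpoint + 0.5, color="black", ls="--", lw=0.8)
            ax.set_title(f"{tumor} [{call.status}]", fontsize=8)
            ax.tick_params(labelsize=7)
        for j in range(len(tumors), nrows * ncols):
            axes[j // ncols][j % ncols].axis("off")
        fig.suptitle(f"{profile.gene} exon intensities (log2)", fontsize=10)
        fig.supxlabel("exon (5' to 3')", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)
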