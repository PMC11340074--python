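"""Basic Manhattan and QQ plots for a GWAS result (optional layer).

Numerical outputs are the contract of this package; these helpers only
write quick-look image files.  matplotlib is imported lazily so the rest of
the package works without it.
"""

from __future__ import annotations

import numpy as np

from .gwas import GwasResult


def manhattan(result: GwasResult, path, highlight: set[str] | None = None) -> None:
    """Scatter of -log10 p by position, colored by chromosome, with the
    Bonferroni threshold drawn when diagnostics are attached."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(t.groupby("chromosome", sort=False)):
        x = grp["position"].to_numpy(dtype=float) + offset
        ax.scatter(x, grp["neglog10p"], s=6,
                   color="C0" if i % 2 == 0 else "C1", linewidths=0)
        if highlight:
            hits = grp["marker"].isin(highlight)
            ax.scatter(x[hits], grp.loc[hits, "neglog10p"], s=18, color="green")
        ticks.append(offset + grp["position"].median())
        labels.append(str(chrom))
        offset = x.max() + 1
    if result.diagnostics is not None:
        ax.axhline(result.diagnostics.threshold_neglog10, ls="--", color="red", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(result.method)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(result: GwasResult, path) -> None:
    """Observed vs expected -log10 p quantiles with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(result.pvalues)
    m = len(p)
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    obs = -np.log10(p)  # ascending p: both axes run from largest quantile down
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, obs, s=6, linewidths=0)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    title = result.method
    if result.diagnostics is not None:
        title += f" (slope {result.diagnostics.qq_slope:.2f})"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
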