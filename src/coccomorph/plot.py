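"""Basic ordination plot: CCA biplot of samples, taxa and gradients."""

from __future__ import annotations

from .stats import CCAResult


def cca_biplot(result: CCAResult, ax=None, arrow_scale: float = 1.0):
    """Draw a two-axis CCA biplot.

    Samples as points, taxa as labelled markers, environmental gradients
    as arrows from the origin (length proportional to the intraset
    correlation with each axis).  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if result.site_scores.shape[1] < 2:
        raise ValueError("need at least two canonical axes for a biplot")
    axes = result.site_scores.columns[:2]

    ax.scatter(result.site_scores[axes[0]], result.site_scores[axes[1]],
               marker="^", c="tab:gray", s=25, label="samples")
    for name, row in result.species_scores.iterrows():
        ax.plot(row[axes[0]], row[axes[1]], "o", color="tab:blue")
        ax.annotate(str(name), (row[axes[0]], row[axes[1]]),
                    textcoords="offset points", xytext=(4, 4), fontsize=9)
    for name, row in result.env_axis_scores.iterrows():
        ax.annotate(
            "", xy=(arrow_scale * row[axes[0]], arrow_scale * row[axes[1]]),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:red"))
        ax.annotate(str(name),
                    (arrow_scale * row[axes[0]], arrow_scale * row[axes[1]]),
                    color="tab:red", fontsize=8)
    pv = result.percent_variance
    ax.set_xlabel(f"{axes[0]} ({pv[0]:.1f}% of constrained inertia)")
    ax.set_ylabel(f"{axes[1]} ({pv[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    return ax
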