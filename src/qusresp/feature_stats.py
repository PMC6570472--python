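"""Univariate comparison and ranking of features between outcome groups.

Each feature is compared between the two classes with an unpaired
two-sample t-test when both class samples pass a Shapiro-Wilk normality
screen, otherwise with the two-sided Mann-Whitney rank-sum test (tie
corrected).  Features are ranked ascending by p-value; ties break by
absolute standardized mean difference (larger first), then by name.  The
resulting order initializes the sequential floating feature selection.

No multiple-testing correction enters the ranking; Bonferroni-adjusted
p-values are available as a reporting column only.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["univariate_rank", "plot_ranked_panel"]

SHAPIRO_ALPHA = 0.05


def _standardized_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _one_feature(a: np.ndarray, b: np.ndarray):
    """(p_value, test_used, smd) for one feature, two class samples."""
    const_a = np.ptp(a) == 0
    const_b = np.ptp(b) == 0
    if const_a and const_b and a[0] == b[0]:
        # constant in both classes: carries no information, ranked last
        return 1.0, "none", 0.0
    smd = _standardized_mean_diff(a, b)
    normal = False
    if len(a) >= 3 and len(b) >= 3 and not const_a and not const_b:
        normal = (stats.shapiro(a).pvalue > SHAPIRO_ALPHA
                  and stats.shapiro(b).pvalue > SHAPIRO_ALPHA)
    if normal:
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
        return float(p), "t", smd
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), "mann_whitney", smd


def univariate_rank(table: pd.DataFrame, labels: Sequence[int],
                    features: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Rank features by two-group p-value (smallest first).

    Returns a DataFrame indexed by feature with columns ``p_value``,
    ``test_used``, ``smd``, ``rank`` (1-based permutation) and
    ``p_bonferroni``.  Rows with missing values are dropped per feature;
    each class must retain at least 2 samples.
    """
    y = np.asarray(labels)
    if features is None:
        features = [c for c in table.columns if c != "label"]
    rows = {}
    for feat in features:
        v = table[feat].to_numpy(dtype=float)
        ok = np.isfinite(v)
        a = v[ok & (y == 1)]
        b = v[ok & (y == 0)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"feature {feat!r}: need >=2 samples per class")
        p, test, smd = _one_feature(a, b)
        rows[feat] = {"p_value": p, "test_used": test, "smd": smd}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    order = sorted(out.index,
                   key=lambda f: (out.at[f, "p_value"],
                                  -abs(out.at[f, "smd"]), f))
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out


def plot_ranked_panel(table: pd.DataFrame, labels: Sequence[int],
                      ranked: pd.DataFrame, path=None, top: int = 15,
                      title: str = "top features by significance"):
    """Scatter/box panel of the top-ranked features by group.

    One panel per feature, features in rank order (raster layout); returns
    the matplotlib figure, optionally saved to ``path``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    y = np.asarray(labels)
    feats = list(ranked.index[:top])
    ncol = 5
    nrow = int(np.ceil(len(feats) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             squeeze=False)
    for ax in axes.ravel()[len(feats):]:
        ax.set_visible(False)
    for ax, feat in zip(axes.ravel(), feats):
        v = table[feat].to_numpy(dtype=float)
        groups = [v[(y == 1) & np.isfinite(v)], v[(y == 0) & np.isfinite(v)]]
        ax.boxplot(groups, positions=[1, 2], widths=0.5, showfliers=False)
        for pos, g in zip((1, 2), groups):
            jitter = (np.random.default_rng(0).uniform(-0.12, 0.12, len(g)))
            ax.plot(pos + jitter, g, ".", ms=3, alpha=0.6)
        ax.set_xticks([1, 2], ["R", "NR"])
        ax.set_title(f"{feat}\np={ranked.at[feat, 'p_value']:.3g}",
                     fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
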