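"""TRE summary statistics, spatial error maps and the ANOVA/Tukey-Kramer test.

Conventions: standard deviations use the n−1 denominator; quartiles use
linear interpolation between order statistics; the 8x8 spatial heat map
reports the mean TRE per image bin, with empty bins carried as NaN and
bins whose centre lies outside the circular endoscopic field flagged
invalid.  The one-way fixed-effects ANOVA reports F and p from the F
distribution; Tukey-Kramer pairwise intervals honour unequal group
sizes through the studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import config


class StatsError(ValueError):
    pass


def anova_oneway(groups: dict[str, np.ndarray] | list[np.ndarray]) -> tuple[float, float, int, int]:
    """One-way fixed-effects ANOVA; returns (F, p, df_between, df_within)."""
    arrays = list(groups.values()) if isinstance(groups, dict) else [np.asarray(g) for g in groups]
    arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise StatsError("ANOVA needs >= 2 groups with >= 2 values each")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = int(ns.sum()) - len(arrays)
    if ss_within == 0.0:
        # all groups internally constant: F is 0 when the means agree too
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return float(F), p, df_b, df_w


def tukey_kramer(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons for (possibly) unequal group sizes.

    For each pair the standard error is sqrt(MSE/2·(1/n_i + 1/n_j)) and
    the interval half-width q_{1−α;k,ν}·SE, with q from the
    studentized-range distribution.
    """
    names = sorted(groups)
    arrays = {k: np.asarray(groups[k], dtype=float).ravel() for k in names}
    if len(names) < 2 or any(len(a) < 2 for a in arrays.values()):
        raise StatsError("Tukey-Kramer needs >= 2 groups with >= 2 values each")
    k = len(names)
    ns = {k_: len(a) for k_, a in arrays.items()}
    means = {k_: a.mean() for k_, a in arrays.items()}
    df_w = sum(ns.values()) - k
    mse = sum(((a - means[k_]) ** 2).sum() for k_, a in arrays.items()) / df_w
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = means[a] - means[b]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q_stat, p_adj = (np.inf if diff != 0 else 0.0), (0.0 if diff != 0 else 1.0)
            else:
                q_stat = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q_stat, k, df_w))
            half = q_crit * se
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": diff,
                    "lower": diff - half,
                    "upper": diff + half,
                    "q": q_stat,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """The protocol's statistical test: one-way ANOVA + Tukey-Kramer post-hoc."""
    F, p, df_b, df_w = anova_oneway(groups)
    return {
        "F": F,
        "p": p,
        "df_between": df_b,
        "df_within": df_w,
        "pairwise": tukey_kramer(groups, alpha),
    }


def _distribution_stats(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    return {
        "n": int(len(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "q1": float(np.quantile(x, 0.25)),  # linear interpolation
        "q3": float(np.quantile(x, 0.75)),
        "min": float(x.min()),
        "max": float(x.max()),
    }


@dataclass
class TRESummary:
    overall: dict[str, float]
    per_distance: pd.DataFrame
    heatmap: np.ndarray          # (bins, bins) mean TRE; NaN where empty
    heatmap_counts: np.ndarray
    heatmap_valid: np.ndarray    # False where the bin centre is outside the FOV
    heatmap_edges: tuple[np.ndarray, np.ndarray]
    anova: dict | None

    def summary(self) -> str:
        o = self.overall
        lines = [
            "TRE summary",
            f"  records : {o['n']}",
            f"  mean±sd : {o['mean']:.3f} ± {o['sd']:.3f} mm",
            f"  median  : {o['median']:.3f} mm (IQR {o['q1']:.3f}–{o['q3']:.3f})",
            f"  range   : {o['min']:.3f} – {o['max']:.3f} mm",
        ]
        if self.anova is not None:
            lines.append(
                f"  ANOVA across distances: F = {self.anova['F']:.3f}, p = {self.anova['p']:.3f}"
            )
        return "\n".join(lines)


def tre_heatmap(
    records: pd.DataFrame,
    image_size: tuple[int, int],
    bins: int = config.HEATMAP_BINS,
    fov_center: tuple[float, float] | None = None,
    fov_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Mean TRE binned over real-sphere image coordinates.

    Returns (mean map, count map, validity mask, (x_edges, y_edges));
    the map is indexed [iy, ix] like an image.
    """
    w, h = image_size
    x_edges = np.linspace(0, w, bins + 1)
    y_edges = np.linspace(0, h, bins + 1)
    stat, _, _, _ = sps.binned_statistic_2d(
        records["u_real"], records["v_real"], records["tre_mm"],
        statistic="mean", bins=[x_edges, y_edges],
    )
    count, _, _, _ = sps.binned_statistic_2d(
        records["u_real"], records["v_real"], records["tre_mm"],
        statistic="count", bins=[x_edges, y_edges],
    )
    mean_map = stat.T      # [iy, ix]
    count_map = count.T
    cx, cy = fov_center if fov_center is not None else (w / 2.0, h / 2.0)
    radius = fov_radius if fov_radius is not None else min(cx, cy)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    XX, YY = np.meshgrid(xc, yc)
    valid = (XX - cx) ** 2 + (YY - cy) ** 2 <= radius * radius
    return mean_map, count_map, valid, (x_edges, y_edges)


def summarize(
    records: pd.DataFrame,
    image_size: tuple[int, int],
    heatmap_bins: int = config.HEATMAP_BINS,
    fov_radius: float | None = None,
    run_anova: bool = True,
) -> TRESummary:
    """Overall and per-distance TRE statistics, heat map and ANOVA."""
    if len(records) == 0:
        raise StatsError("no TRE records to summarize")
    overall = _distribution_stats(records["tre_mm"].to_numpy())
    per_rows = []
    groups: dict[str, np.ndarray] = {}
    for d, sub in records.groupby("distance_mm"):
        st = _distribution_stats(sub["tre_mm"].to_numpy())
        st["distance_mm"] = float(d)
        per_rows.append(st)
        groups[f"{float(d):g}mm"] = sub["tre_mm"].to_numpy()
    per_distance = pd.DataFrame(per_rows).set_index("distance_mm")
    mean_map, count_map, valid, edges = tre_heatmap(
        records, image_size, heatmap_bins, fov_radius=fov_radius
    )
    anova = None
    if run_anova and len(groups) >= 2 and all(len(g) >= 2 for g in groups.values()):
        anova = anova_tukey(groups)
    return TRESummary(overall, per_distance, mean_map, count_map, valid, edges, anova)


# ---------------------------------------------------------------------------
# figures


def plot_boxplots(records: pd.DataFrame, path: str) -> None:
    """Per-distance TRE boxplots, mirroring the accuracy-protocol report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    distances = sorted(records["distance_mm"].unique())
    data = [records.loc[records["distance_mm"] == d, "tre_mm"] for d in distances]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.boxplot(data, labels=[f"{d:g}" for d in distances])
    ax.set_xlabel("working distance (mm)")
    ax.set_ylabel("TRE (mm)")
    ax.set_title("Overlay error vs working distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(summary: TRESummary, path: str) -> None:
    """Spatial mean-TRE map; invalid (out-of-FOV) bins are blanked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(summary.heatmap_valid, summary.heatmap, np.nan)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(shown, origin="upper", cmap="coolwarm")
    fig.colorbar(im, ax=ax, label="mean TRE (mm)")
    ax.set_title("Spatial TRE distribution")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
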