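"""Compare risk levels statistically and re-stratify them by clustering.

From the per-trial peak summaries: Shapiro-Wilk normality per metric and
level, Wilcoxon signed-rank tests between risk levels (Bonferroni
corrected, trials paired by subject and repetition), then the centroid
(k-means, k = 6) clustering of peak compressive loads grouped by peak
moments, with pairwise Welch t-tests between clusters and the
cluster-vs-LI cross-tabulation.  Writes results/stats.json and
results/clusters.json plus violin/scatter figures.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from liftrisk.risk_analysis import cluster_loads, normality_test, wilcoxon_pairwise

RESULTS = Path("results")
FIGURES = RESULTS / "figures"
SEED = 0
METRICS = ["rom_deg", "peak_moment_norm", "peak_compression_bw", "peak_shear_bw",
           "peak_emg_longissimus", "peak_emg_iliocostalis",
           "peak_emg_rectus_abdominis"]


def main() -> None:
    frame = pd.read_csv(RESULTS / "summaries.csv")
    stats_report = {"normality": {}, "wilcoxon": {}}
    for metric in METRICS:
        stats_report["normality"][metric] = {
            str(level): dict(zip(("W", "p"), normality_test(sub[metric])))
            for level, sub in frame.groupby("risk_level")
        }
        table = wilcoxon_pairwise(frame, metric)
        stats_report["wilcoxon"][metric] = table.to_dict(orient="records")
        sig = table[table.p_adjusted < 0.05]
        print(f"{metric}: {len(sig)}/3 level pairs significant after Bonferroni")
    (RESULTS / "stats.json").write_text(json.dumps(stats_report, indent=1))

    report = cluster_loads(frame, k=6, seed=SEED)
    print("\ncluster centroids (peak moment N m/kg, peak compression xBW, n):")
    print(report.centroids.round(2).to_string(index=False))
    print("\ncluster vs designed risk level:")
    print(report.crosstab.to_string())
    spread = (report.crosstab > 0).sum(axis=1)
    print(f"\neach risk level spreads across {spread.min()}-{spread.max()} clusters: "
          "compressive load carries finer risk structure than the three levels")
    (RESULTS / "clusters.json").write_text(json.dumps(
        {"k": report.k,
         "centroids": report.centroids.to_dict(orient="records"),
         "ttests": report.ttests.to_dict(orient="records"),
         "crosstab": {str(i): r.to_dict() for i, r in report.crosstab.iterrows()},
         "silhouette": report.silhouette}, indent=1))

    FIGURES.mkdir(parents=True, exist_ok=True)
    for metric in ("peak_moment_norm", "peak_compression_bw", "peak_shear_bw"):
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = [frame.loc[frame.risk_level == lvl, metric] for lvl in (1, 2, 3)]
        ax.violinplot(groups, positions=[1, 2, 3], showmedians=True)
        ax.set_ylabel(metric)
        ax.set_xticks([1, 2, 3])
        ax.set_xlabel("designed risk level (LI)")
        fig.tight_layout()
        fig.savefig(FIGURES / f"violin_{metric}.png", dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(5, 4))
    scatter = ax.scatter(frame.peak_moment_norm, frame.peak_compression_bw,
                         c=report.assignments, cmap="viridis")
    ax.set_xlabel("peak moment (N m/kg)")
    ax.set_ylabel("peak compression (xBW)")
    fig.colorbar(scatter, label="cluster")
    fig.tight_layout()
    fig.savefig(FIGURES / "clusters_scatter.png", dpi=120)
    plt.close(fig)
    print(f"\nwrote stats.json, clusters.json and figures under {FIGURES}")


if __name__ == "__main__":
    main()
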