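"""Statistical comparison and re-stratification of lifting risk.

From per-trial peak summaries (normalized EMG, lumbosacral range of
motion, body-normalized peak moment, compression and shear), this module

* tests distributions for normality (Shapiro-Wilk),
* compares risk levels pairwise with the Wilcoxon signed-rank test and
  Bonferroni correction (trials paired by subject and repetition),
* re-stratifies risk with a centroid (k-means) cluster analysis of peak
  compressive loads grouped by peak moments, reporting pairwise Welch
  t-tests between clusters and a cluster-vs-LI-level cross-tabulation.

The clustering asks whether compressive load supports a finer risk
resolution than the three equation-based levels: if the NIOSH levels
spread across many clusters, compression carries independent information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .io import Trial
from .signals import LiftCycle, TimeSeries
from .trunk_model import JointLoadSeries

__all__ = [
    "MUSCLE_PAIRS",
    "TrialSummary",
    "ClusterReport",
    "summarize_trial",
    "summaries_to_frame",
    "normality_test",
    "wilcoxon_pairwise",
    "cluster_loads",
    "cluster_separation_tests",
]

MUSCLE_PAIRS = {
    "longissimus": (
        "erector_spinae_longissimus_left",
        "erector_spinae_longissimus_right",
    ),
    "iliocostalis": (
        "erector_spinae_iliocostalis_left",
        "erector_spinae_iliocostalis_right",
    ),
    "rectus_abdominis": (
        "rectus_abdominis_middle_left",
        "rectus_abdominis_middle_right",
    ),
}


@dataclass(frozen=True)
class TrialSummary:
    """Peak metrics of one trial, evaluated within the detected lift cycle."""

    subject_id: str
    risk_level: int
    repetition: int
    peak_emg: dict[str, float]     # per muscle, left/right peaks averaged
    rom_deg: float                 # lumbosacral flexion-extension range
    peak_moment_norm: float        # N m / kg
    peak_compression_bw: float     # multiples of body weight
    peak_shear_bw: float


@dataclass
class ClusterReport:
    """Centroid clustering of (peak moment, peak compression)."""

    k: int
    assignments: np.ndarray              # cluster label (1..k) per trial
    centroids: pd.DataFrame              # original units, ascending compression
    ttests: pd.DataFrame                 # pairwise Welch t between clusters
    crosstab: pd.DataFrame               # LI level x cluster counts
    silhouette: dict[int, float] = field(default_factory=dict)


def _window_peak(values: np.ndarray, fs: float, cycle: LiftCycle) -> float:
    """Max of a series inside the cycle, index-mapped through time for
    streams sampled at a different rate than the segmentation stream."""
    i0 = int(np.floor((cycle.start_time) * fs))
    i1 = int(np.ceil((cycle.end_time) * fs))
    i0 = max(i0, 0)
    i1 = min(i1, values.size - 1)
    return float(np.max(values[i0 : i1 + 1]))


def summarize_trial(
    trial: Trial,
    loads: JointLoadSeries,
    envelopes: dict[str, TimeSeries],
    cycle: LiftCycle,
) -> TrialSummary:
    """Peaks and range of motion within the lift cycle.

    ``loads`` must carry the body-normalized fields; ``envelopes`` are the
    iMVC-normalized per-channel envelopes.  Left/right homologous channels
    are peak-extracted first, then averaged.
    """
    if loads.moment_norm is None:
        raise ValueError("loads must be body-normalized first")
    peak_emg = {}
    for muscle, (left, right) in MUSCLE_PAIRS.items():
        peaks = [
            _window_peak(np.squeeze(envelopes[ch].values), envelopes[ch].fs, cycle)
            for ch in (left, right)
            if ch in envelopes
        ]
        if peaks:
            peak_emg[muscle] = float(np.mean(peaks))
    sl = slice(cycle.start_index, cycle.end_index + 1)
    angle_cycle = trial.angle[sl]
    return TrialSummary(
        subject_id=trial.subject_id,
        risk_level=trial.risk_level,
        repetition=trial.repetition,
        peak_emg=peak_emg,
        rom_deg=float(np.rad2deg(angle_cycle.max() - angle_cycle.min())),
        peak_moment_norm=float(np.max(loads.moment_norm[sl])),
        peak_compression_bw=float(np.max(loads.compression_bw[sl])),
        peak_shear_bw=float(np.max(loads.shear_bw[sl])),
    )


def summaries_to_frame(summaries: list[TrialSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "risk_level": s.risk_level,
            "repetition": s.repetition,
            "rom_deg": s.rom_deg,
            "peak_moment_norm": s.peak_moment_norm,
            "peak_compression_bw": s.peak_compression_bw,
            "peak_shear_bw": s.peak_shear_bw,
        }
        row.update({f"peak_emg_{m}": v for m, v in s.peak_emg.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 5000 samples."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test is degenerate")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_pairwise(
    frame: pd.DataFrame,
    metric: str,
    pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (1, 3)),
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Wilcoxon signed-rank tests between risk levels with Bonferroni
    correction; samples paired by (subject, repetition)."""
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    wide = frame.pivot_table(
        index=["subject_id", "repetition"], columns="risk_level", values=metric
    )
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            raise ValueError(f"risk level {a} or {b} missing from the summaries")
        paired = wide[[a, b]].dropna()
        if len(paired) != len(wide):
            raise ValueError(
                f"unmatched pairing between levels {a} and {b}: "
                f"{len(paired)} of {len(wide)} (subject, repetition) pairs complete"
            )
        x, y = paired[a].to_numpy(), paired[b].to_numpy()
        d = x - y
        n_nz = int(np.count_nonzero(d))
        if n_nz == 0:
            z, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(x, y)
            # signed z from the normal approximation of the W statistic
            w = float(res.statistic)
            mu = n_nz * (n_nz + 1) / 4.0
            sd = np.sqrt(n_nz * (n_nz + 1) * (2 * n_nz + 1) / 24.0)
            z = (w - mu) / sd if sd > 0 else 0.0
            p = float(res.pvalue)
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        rows.append(
            {"level_a": a, "level_b": b, "n": len(paired), "z": z,
             "p_raw": p, "p_adjusted": p_adj}
        )
    return pd.DataFrame(rows)


def cluster_loads(
    frame: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    scan_k: tuple[int, int] | None = (2, 8),
) -> ClusterReport:
    """Centroid (k-means) clustering of peak compressive loads grouped by
    peak moments.

    Features (peak_moment_norm, peak_compression_bw) are standardized;
    clusters are relabelled 1..k by ascending compression centroid.  The
    report includes pairwise Welch t statistics between the clusters'
    compression values and the LI-level cross-tabulation.  A silhouette
    scan over ``scan_k`` documents the choice of k.
    """
    features = frame[["peak_moment_norm", "peak_compression_bw"]].to_numpy()
    n = features.shape[0]
    if k > n:
        raise ValueError(f"cannot form k={k} clusters from {n} trials")
    X = StandardScaler().fit_transform(features)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(X)
    # relabel so centroid compression increases with cluster index
    comp_by_label = {
        lab: features[raw_labels == lab, 1].mean() for lab in np.unique(raw_labels)
    }
    order = sorted(comp_by_label, key=comp_by_label.get)
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[lab] for lab in raw_labels])
    centroids = pd.DataFrame(
        [
            {
                "cluster": c,
                "peak_moment_norm": features[labels == c, 0].mean(),
                "peak_compression_bw": features[labels == c, 1].mean(),
                "n": int((labels == c).sum()),
            }
            for c in range(1, k + 1)
        ]
    )
    ttests = cluster_separation_tests(labels, features[:, 1])
    crosstab = pd.crosstab(frame["risk_level"], pd.Series(labels, name="cluster"))
    crosstab = crosstab.reindex(columns=range(1, k + 1), fill_value=0)
    silhouette = {}
    if scan_k is not None:
        for kk in range(scan_k[0], scan_k[1] + 1):
            if kk >= n:
                break
            lab = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(X)
            silhouette[kk] = float(silhouette_score(X, lab))
    return ClusterReport(
        k=k,
        assignments=labels,
        centroids=centroids,
        ttests=ttests,
        crosstab=crosstab,
        silhouette=silhouette,
    )


def cluster_separation_tests(labels: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """Welch two-sample t-test between every pair of clusters' values.

    With clusters labelled by ascending mean, t is negative whenever the
    lower-labelled cluster has the lower mean.  Singleton clusters are
    excluded with a warning.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    uniq = np.unique(labels)
    usable = []
    for c in uniq:
        if (labels == c).sum() < 2:
            warnings.warn(f"cluster {c} is a singleton; excluded from t-tests")
        else:
            usable.append(c)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            res = stats.ttest_ind(values[labels == a], values[labels == b], equal_var=False)
            rows.append(
                {"cluster_a": int(a), "cluster_b": int(b),
                 "t": float(res.statistic), "p": float(res.pvalue)}
            )
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "t", "p"])
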