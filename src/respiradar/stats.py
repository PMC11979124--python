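"""Agreement and group-comparison statistics for paired rate series.

Radar-vs-reference agreement follows the standard method-comparison suite:
Bland-Altman mean difference with 95% limits of agreement
(mean +/- 1.96 sd, sample sd), Pearson correlation, RMSE, and MAPE.
Differences are taken as reference - radar by default (positive mean
difference = laser reads above radar); the convention is recorded in the
report.  Rate differences across anesthesia levels use the Kruskal-Wallis
test followed by Dunn's pairwise post-hoc z-tests with Holm (default) or
Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .pipeline import InstantRateSeries

__all__ = [
    "PairedRates",
    "AgreementReport",
    "GroupComparison",
    "pair_series",
    "bland_altman",
    "error_metrics",
    "agreement_report",
    "kruskal_posthoc",
    "dunn_posthoc",
    "split_by_schedule",
    "significance_stars",
    "bland_altman_plot",
    "correlation_plot",
]


@dataclass(frozen=True)
class PairedRates:
    """Radar and reference bpm sampled on one common uniform grid."""

    grid_times: np.ndarray
    radar_bpm: np.ndarray
    reference_bpm: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.grid_times) == len(self.radar_bpm) == len(self.reference_bpm)):
            raise ValueError("grid_times, radar_bpm, reference_bpm must have equal length")
        if len(self.grid_times) < 2:
            raise ValueError("need at least 2 pairs")

    def __len__(self) -> int:
        return len(self.grid_times)


@dataclass(frozen=True)
class AgreementReport:
    """Method-comparison summary (all rate quantities in bpm, MAPE in %)."""

    n_pairs: int
    mean_difference: float
    loa_low: float
    loa_high: float
    pearson_r: float
    rmse: float
    mape: float
    difference_sign: str = "reference_minus_radar"
    mape_denominator: str = "radar"

    def to_frame(self) -> pd.DataFrame:
        """One-column table mirroring the usual per-subject report layout."""
        rows = {
            "Root mean square error (RMSE) [bpm]": self.rmse,
            "Mean absolute percentage error (MAPE) [%]": self.mape,
            "Correlation coefficient": self.pearson_r,
            "95% limit of agreement low [bpm]": self.loa_low,
            "95% limit of agreement high [bpm]": self.loa_high,
            "Mean difference [bpm]": self.mean_difference,
            "Number of pairs": self.n_pairs,
        }
        return pd.DataFrame({"value": rows})


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis result plus the Dunn post-hoc adjusted p-value matrix."""

    group_labels: tuple[str, ...]
    kw_statistic: float
    kw_p: float
    posthoc: pd.DataFrame  # symmetric, unit diagonal
    alpha: float = 0.05

    def stars(self) -> pd.DataFrame:
        return self.posthoc.map(significance_stars)


def pair_series(
    radar: InstantRateSeries, reference: InstantRateSeries, grid_rate: float = 1.0
) -> PairedRates:
    """Resample two rate series onto their common time overlap.

    Both series are linearly interpolated onto a uniform grid at
    ``grid_rate`` spanning the overlap; 1 Hz is the default so each breath
    contributes roughly one pair at anesthetized-rat rates, avoiding
    pseudo-replication of the 10 Hz pipeline grid.
    """
    if grid_rate <= 0:
        raise ValueError("grid_rate must be positive")
    t0 = max(radar.grid_times[0], reference.grid_times[0])
    t1 = min(radar.grid_times[-1], reference.grid_times[-1])
    if t1 <= t0:
        raise ValueError("no overlap between radar and reference series")
    n = int(np.floor((t1 - t0) * grid_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / grid_rate
    return PairedRates(
        grid_times=grid,
        radar_bpm=np.interp(grid, radar.grid_times, radar.bpm),
        reference_bpm=np.interp(grid, reference.grid_times, reference.bpm),
    )


def _differences(pairs: PairedRates, sign: str) -> np.ndarray:
    if sign == "reference_minus_radar":
        return pairs.reference_bpm - pairs.radar_bpm
    if sign == "radar_minus_reference":
        return pairs.radar_bpm - pairs.reference_bpm
    raise ValueError("sign must be 'reference_minus_radar' or 'radar_minus_reference'")


def bland_altman(
    pairs: PairedRates, sign: str = "reference_minus_radar"
) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sd, n-1 sd)."""
    d = _differences(pairs, sign)
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean_d, mean_d - 1.96 * sd, mean_d + 1.96 * sd


def error_metrics(
    pairs: PairedRates, mape_denominator: str = "radar", sign: str = "reference_minus_radar"
) -> tuple[float, float, float]:
    """RMSE (bpm), MAPE (%), and Pearson r for a paired series.

    MAPE divides by the radar series by default; a zero anywhere in the
    chosen denominator is an error naming the offending timestamps.
    Pearson r of a constant series is undefined and reported as NaN with a
    warning (identical non-constant series give r = 1).
    """
    d = _differences(pairs, sign)
    rmse = float(np.sqrt(np.mean(d**2)))
    if mape_denominator == "radar":
        denom = pairs.radar_bpm
    elif mape_denominator == "reference":
        denom = pairs.reference_bpm
    else:
        raise ValueError("mape_denominator must be 'radar' or 'reference'")
    zero = denom == 0
    if np.any(zero):
        ts = ", ".join(f"{t:.3f}" for t in pairs.grid_times[zero][:10])
        raise ValueError(f"zero in MAPE denominator series at t = {ts} s")
    mape = float(100.0 * np.mean(np.abs(d) / np.abs(denom)))
    if np.std(pairs.radar_bpm) == 0 or np.std(pairs.reference_bpm) == 0:
        warnings.warn("Pearson r undefined for a constant series; reporting NaN", stacklevel=2)
        r = float("nan")
    else:
        r = float(sstats.pearsonr(pairs.radar_bpm, pairs.reference_bpm).statistic)
    return rmse, mape, r


def agreement_report(
    pairs: PairedRates, mape_denominator: str = "radar", sign: str = "reference_minus_radar"
) -> AgreementReport:
    """Full Bland-Altman + error-metric report for one paired series."""
    mean_d, lo, hi = bland_altman(pairs, sign=sign)
    rmse, mape, r = error_metrics(pairs, mape_denominator=mape_denominator, sign=sign)
    return AgreementReport(
        n_pairs=len(pairs),
        mean_difference=mean_d,
        loa_low=lo,
        loa_high=hi,
        pearson_r=r,
        rmse=rmse,
        mape=mape,
        difference_sign=sign,
        mape_denominator=mape_denominator,
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after Kruskal-Wallis, with tie correction.

    z_ij = |Rbar_i - Rbar_j| / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tied groups; two-sided normal p-values are
    adjusted jointly ('holm' default, or 'bonferroni') and returned as a
    symmetric matrix with unit diagonal.
    """
    labels = list(groups)
    sizes = {lab: len(groups[lab]) for lab in labels}
    pooled = np.concatenate([np.asarray(groups[lab], dtype=float) for lab in labels])
    n_total = len(pooled)
    ranks = sstats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for lab in labels:
        mean_ranks[lab] = float(np.mean(ranks[start : start + sizes[lab]]))
        start += sizes[lab]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pair_list = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raw = []
    for i, j in pair_list:
        li, lj = labels[i], labels[j]
        se = np.sqrt(var_base * (1.0 / sizes[li] + 1.0 / sizes[lj]))
        if se == 0:
            raw.append(1.0)
            continue
        z = abs(mean_ranks[li] - mean_ranks[lj]) / se
        raw.append(float(2.0 * sstats.norm.sf(z)))
    adjusted = multipletests(raw, method=adjust)[1] if raw else raw
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (i, j), p in zip(pair_list, adjusted):
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return mat


def kruskal_posthoc(
    rates_by_level: dict[str, np.ndarray], alpha: float = 0.05, adjust: str = "holm"
) -> GroupComparison:
    """Kruskal-Wallis across protocol levels plus Dunn post-hoc comparisons."""
    if len(rates_by_level) < 2:
        raise ValueError("need at least 2 levels")
    for lab, vals in rates_by_level.items():
        if len(vals) < 2:
            raise ValueError(f"level {lab!r} has fewer than 2 samples")
    samples = [np.asarray(v, dtype=float) for v in rates_by_level.values()]
    if all(np.array_equal(samples[0], s) for s in samples[1:]) and np.ptp(samples[0]) == 0:
        # degenerate all-identical input: no evidence of any group effect
        h, p = 0.0, 1.0
    else:
        h, p = sstats.kruskal(*samples)
    posthoc = dunn_posthoc(rates_by_level, adjust=adjust)
    return GroupComparison(
        group_labels=tuple(rates_by_level),
        kw_statistic=float(h),
        kw_p=float(p),
        posthoc=posthoc,
        alpha=alpha,
    )


def split_by_schedule(
    series: InstantRateSeries,
    schedule: list[tuple[float, str]] | tuple[tuple[float, str], ...],
    sample_rate: float = 1.0,
    margin: float = 0.0,
) -> dict[str, np.ndarray]:
    """Collect bpm samples per protocol level, decimated to ``sample_rate``.

    ``schedule`` lists consecutive ``(duration_s, label)`` windows from
    t = 0.  Samples are drawn from the interpolated bpm series at
    ``sample_rate`` (1 Hz default; the 10 Hz pipeline grid is strongly
    autocorrelated and would overstate the effective sample size).
    ``margin`` trims that many seconds off both ends of each window.
    Repeated labels are pooled.
    """
    out: dict[str, list[np.ndarray]] = {}
    edge = 0.0
    for dur, label in schedule:
        lo, hi = edge + margin, edge + dur - margin
        edge += dur
        n = max(int(np.floor((hi - lo) * sample_rate)) + 1, 0)
        t = lo + np.arange(n) / sample_rate
        t = t[(t >= series.grid_times[0]) & (t <= series.grid_times[-1])]
        if len(t):
            out.setdefault(label, []).append(np.interp(t, series.grid_times, series.bpm))
    return {lab: np.concatenate(chunks) for lab, chunks in out.items()}


def significance_stars(
    p: float, thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)
) -> str:
    """Map a p-value to ns / * / ** / *** at the given thresholds."""
    if p < thresholds[2]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[0]:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def _savefig(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def bland_altman_plot(pairs: PairedRates, path, sign: str = "reference_minus_radar"):
    """Difference-vs-mean scatter with mean difference and 95% LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    d = _differences(pairs, sign)
    mean_pair = 0.5 * (pairs.radar_bpm + pairs.reference_bpm)
    mean_d, lo, hi = bland_altman(pairs, sign=sign)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_pair, d, s=6, alpha=0.4)
    for y, style in ((mean_d, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of radar and reference [bpm]")
    ax.set_ylabel(f"Difference ({sign.replace('_', ' ')}) [bpm]")
    _savefig(fig, path)


def correlation_plot(pairs: PairedRates, path):
    """Radar-vs-reference scatter with the identity line and Pearson r."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, _, r = error_metrics(pairs)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pairs.radar_bpm, pairs.reference_bpm, s=6, alpha=0.4)
    lims = [
        min(pairs.radar_bpm.min(), pairs.reference_bpm.min()),
        max(pairs.radar_bpm.max(), pairs.reference_bpm.max()),
    ]
    ax.plot(lims, lims, "k--", linewidth=1)
    ax.set_xlabel("Radar [bpm]")
    ax.set_ylabel("Reference [bpm]")
    ax.set_title(f"r = {r:.2f}")
    _savefig(fig, path)
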