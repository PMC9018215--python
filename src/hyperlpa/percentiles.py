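"""Empirical percentile placement of scores against a reference cohort.

Percentiles use the mid-rank convention,
``100 * (#{ref < s} + 0.5 * #{ref == s}) / N``, which handles the ties that
integer dosages produce.  Reports flag scores above the 95th and 97.5th
reference percentiles — the bands used to judge whether a family member's
polygenic score is extreme — and the paired full/ablated report recomputes
the reference distribution itself under the same ablation, so a sample
score is never compared against a reference scored with different rows.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    GenomicInterval,
    GrsResult,
    PercentileReport,
    ScoreWeight,
    VariantRecord,
)
from .scoring import compute_grs

__all__ = [
    "percentile_rank",
    "build_reports",
    "ablation_percentile_report",
    "reports_table",
    "plot_score_distribution",
]


def percentile_rank(score, reference_scores) -> float:
    """Mid-rank empirical percentile of ``score`` within the reference.

    Accepts a scalar or an array of scores; monotone non-decreasing in the
    score.  An empty reference is an error.
    """
    ref = np.sort(np.asarray(reference_scores, dtype=float))
    if ref.size == 0:
        raise ConfigurationError("reference score set is empty")
    s = np.asarray(score, dtype=float)
    below = np.searchsorted(ref, s, side="left")
    at_or_below = np.searchsorted(ref, s, side="right")
    pct = 100.0 * (below + 0.5 * (at_or_below - below)) / ref.size
    return float(pct) if np.isscalar(score) or s.ndim == 0 else pct


def build_reports(results: Sequence[GrsResult],
                  reference_scores) -> List[PercentileReport]:
    """Percentile reports for scored samples against a reference distribution."""
    ref = np.asarray(reference_scores, dtype=float)
    p95 = float(np.percentile(ref, 95))
    p975 = float(np.percentile(ref, 97.5))
    reports = []
    for r in results:
        pct = percentile_rank(r.score, ref)
        reports.append(PercentileReport(
            sample_id=r.sample_id, score=r.score, percentile=pct,
            flag_95=r.score > p95, flag_975=r.score > p975,
        ))
    return reports


def ablation_percentile_report(sample_variants: Sequence[VariantRecord],
                               weights: Sequence[ScoreWeight],
                               reference_variants: Sequence[VariantRecord],
                               interval: GenomicInterval,
                               missing_policy: str = "skip",
                               samples: Optional[Sequence[str]] = None,
                               reference_samples: Optional[Sequence[str]] = None,
                               ) -> Dict[str, List[PercentileReport]]:
    """Paired percentile reports under the full and locus-ablated score.

    Both cohorts are scored with the identical weight table, and the ablated
    report's reference distribution is recomputed under the same exclusion
    interval.  Returns ``{"full": [...], "ablated": [...]}``.
    """
    out: Dict[str, List[PercentileReport]] = {}
    for label, exclude in (("full", ()), ("ablated", [interval])):
        ref = compute_grs(reference_variants, weights, exclude=exclude,
                          missing_policy=missing_policy,
                          samples=reference_samples)
        res = compute_grs(sample_variants, weights, exclude=exclude,
                          missing_policy=missing_policy, samples=samples)
        out[label] = build_reports(res, [r.score for r in ref])
    return out


def reports_table(reports: Sequence[PercentileReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.score, r.percentile, r.flag_95, r.flag_975)
         for r in reports],
        columns=["sample_id", "score", "percentile", "flag_95", "flag_975"],
    ).set_index("sample_id")


def plot_score_distribution(reference_scores, sample_groups: Dict[str, Sequence[float]],
                            path, title: str = "") -> None:
    """Density-with-dots layout: reference distribution with shaded top/bottom
    5th and 2.5th percentile bands and per-group sample dots below (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref = np.asarray(reference_scores, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(ref, bins=60, density=True, color="0.8", edgecolor="none")
    for lo, hi, alpha in ((5, 95, 0.15), (2.5, 97.5, 0.25)):
        ax.axvspan(ref.min(), np.percentile(ref, lo), color="tab:blue", alpha=alpha)
        ax.axvspan(np.percentile(ref, hi), ref.max(), color="tab:blue", alpha=alpha)
    colors = ["tab:orange", "black", "tab:green", "tab:red"]
    y0 = -0.05 * ax.get_ylim()[1]
    for i, (label, vals) in enumerate(sample_groups.items()):
        vals = np.asarray(list(vals), dtype=float)
        ax.plot(vals, np.full(vals.shape, y0 * (i + 1)), "o",
                color=colors[i % len(colors)], label=label, clip_on=False)
    ax.set_xlabel("score")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
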