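"""Eye-level aggregation and AMD-vs-control group comparison.

The sampling unit is the donor eye: per-image metrics are averaged (unweighted)
within each eye and region (macula, periphery, and "combined" pooling both),
and groups are compared on the per-eye values with a two-tailed pooled-variance
(equal-variance) two-sample t-test.  Group spread is reported as the SEM of
the per-eye means, sd / sqrt(n_eyes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

REGIONS = ("macula", "periphery")
GROUPS = ("AMD", "control")


def summarize_eyes(image_records: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-eye, per-region unweighted means over images.

    ``image_records`` needs columns ``specimen_id``, ``group``, ``region``
    plus one column per metric.  Returns one row per (eye, region) including
    a pooled ``combined`` region; regions with zero images are simply absent.
    """
    required = {"specimen_id", "group", "region"}
    missing = required - set(image_records.columns)
    if missing:
        raise ValueError(f"image records missing columns: {sorted(missing)}")
    if metrics is None:
        metrics = [c for c in image_records.columns if c not in required]
    frames = []
    for region in REGIONS:
        sub = image_records[image_records["region"] == region]
        if len(sub):
            agg = sub.groupby(["specimen_id", "group"], as_index=False)[metrics].mean()
            agg["n_images"] = sub.groupby(["specimen_id", "group"]).size().to_numpy()
            agg["region"] = region
            frames.append(agg)
    # combined pools every image with equal weight regardless of region
    agg = image_records.groupby(["specimen_id", "group"], as_index=False)[metrics].mean()
    agg["n_images"] = image_records.groupby(["specimen_id", "group"]).size().to_numpy()
    agg["region"] = "combined"
    frames.append(agg)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary for one metric in one region."""

    metric: str
    region: str
    mean_1: float
    mean_2: float
    sem_1: float
    sem_2: float
    n_1: int
    n_2: int
    t_statistic: float
    p_value: float
    group_1: str = "AMD"
    group_2: str = "control"


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def compare_groups(
    eye_summaries: pd.DataFrame,
    metric: str,
    region: str = "combined",
    group_1: str = "AMD",
    group_2: str = "control",
) -> GroupComparison:
    """Pooled-variance two-tailed t-test on per-eye values.

    t is signed as group_1 minus group_2 with n1 + n2 - 2 degrees of freedom;
    fewer than two eyes in either group raises
    :class:`~afspectra.errors.InsufficientDataError`.
    """
    sub = eye_summaries[eye_summaries["region"] == region]
    v1 = sub.loc[sub["group"] == group_1, metric].dropna().to_numpy()
    v2 = sub.loc[sub["group"] == group_2, metric].dropna().to_numpy()
    if len(v1) < 2 or len(v2) < 2:
        raise InsufficientDataError(
            f"need >= 2 eyes per group for {metric}/{region}: "
            f"{group_1} has {len(v1)}, {group_2} has {len(v2)}"
        )
    t, p = stats.ttest_ind(v1, v2, equal_var=True)
    return GroupComparison(
        metric=metric,
        region=region,
        mean_1=float(v1.mean()),
        mean_2=float(v2.mean()),
        sem_1=_sem(v1),
        sem_2=_sem(v2),
        n_1=len(v1),
        n_2=len(v2),
        t_statistic=float(t),
        p_value=float(p),
        group_1=group_1,
        group_2=group_2,
    )


def results_table(
    eye_summaries: pd.DataFrame,
    metrics: list[str],
    regions: tuple = ("macula", "periphery", "combined"),
) -> pd.DataFrame:
    """Results-summary table: group mean +/- SEM and p per metric and region."""
    rows = []
    for metric in metrics:
        for region in regions:
            try:
                c = compare_groups(eye_summaries, metric, region)
            except InsufficientDataError:
                continue
            rows.append(
                {
                    "metric": metric,
                    "region": region,
                    f"{c.group_1}_mean": c.mean_1,
                    f"{c.group_1}_sem": c.sem_1,
                    f"{c.group_2}_mean": c.mean_2,
                    f"{c.group_2}_sem": c.sem_2,
                    "t": c.t_statistic,
                    "p": c.p_value,
                }
            )
    return pd.DataFrame(rows)
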