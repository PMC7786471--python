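"""Paired baseline/follow-up comparison and the descriptive report.

Network-level metrics (average degree, density, reciprocity, E-I per ring)
are compared as T0/T1 values with absolute change — and percentage-point
change for the proportion-scaled metrics.  Actor-level metrics (diversity of
contacts, value of contacts) are compared with a classical paired t test
over actors with a defined value at both timepoints; incomplete pairs are
dropped and their count logged.

Differences are taken as post − pre, so an increase yields a positive t
statistic.  (Reports that feed pairs the other way round print the same
magnitudes with flipped signs.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import network_metrics as nm
from .core_model import (
    CollaborationNetwork,
    MetricsReport,
    PrePostStudy,
    Timepoint,
)
from .network_metrics import RINGS_12, RINGS_123, NodeSubsetSpec

logger = logging.getLogger(__name__)


class ZeroVarianceWarning(UserWarning):
    """All paired differences are identical; the t statistic is degenerate."""


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t test on post − pre differences."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ci_low: float
    ci_high: float
    n_pairs: int
    mean_difference: float


@dataclass(frozen=True)
class MetricChange:
    """One network metric at both timepoints with its change."""

    t0: Optional[float]
    t1: Optional[float]
    change: Optional[float]
    change_pp: Optional[float] = None  # percentage points, proportion metrics only


def paired_t_test(
    pre: Sequence[Optional[float]],
    post: Sequence[Optional[float]],
    alpha: float = 0.05,
) -> PairedTestResult:
    """Paired t test of post − pre with a two-sided p and 95% CI.

    Pairs with a missing value (None/NaN) at either timepoint are dropped
    first.  Zero-variance differences yield t = 0 with a
    :class:`ZeroVarianceWarning` instead of an error.
    """
    if len(pre) != len(post):
        raise ValueError(f"mismatched lengths: {len(pre)} vs {len(post)}")
    pairs = [
        (float(a), float(b))
        for a, b in zip(pre, post)
        if a is not None and b is not None and not (np.isnan(a) or np.isnan(b))
    ]
    dropped = len(pre) - len(pairs)
    if dropped:
        logger.info("paired t test: dropped %d incomplete pair(s)", dropped)
    n = len(pairs)
    if n < 2:
        raise ValueError(f"insufficient pairs: need at least 2, have {n}")
    diffs = np.array([b - a for a, b in pairs])
    mean_d = float(diffs.mean())
    sd_d = float(diffs.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        warnings.warn(
            "paired differences have zero variance; t statistic degenerate",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        return PairedTestResult(0.0, df, 1.0, mean_d, mean_d, n, mean_d)
    se = sd_d / np.sqrt(n)
    t_stat = mean_d / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return PairedTestResult(
        t_statistic=float(t_stat),
        degrees_of_freedom=df,
        p_value=p,
        ci_low=mean_d - t_crit * se,
        ci_high=mean_d + t_crit * se,
        n_pairs=n,
        mean_difference=mean_d,
    )


# ---------------------------------------------------------------------------
# network comparison
# ---------------------------------------------------------------------------

def _safe(func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except (ValueError, KeyError):
        return None


def _actor_metric_pairs(
    study: PrePostStudy, metric
) -> tuple[list[Optional[float]], list[Optional[float]], list[str]]:
    """Per-actor (T0, T1) values over rings 1+2, aligned by actor."""
    actor_ids = sorted(
        a.actor_id for a in study.t0.actors.values() if a.ring in (1, 2)
    )
    pre = [_safe(metric, study.t0, i) for i in actor_ids]
    post = [_safe(metric, study.t1, i) for i in actor_ids]
    return pre, post, actor_ids


def _diversity_h(network: CollaborationNetwork, actor_id: str) -> Optional[float]:
    comp = nm.diversity(network, actor_id)
    return None if comp is None else comp.h_i


def compare_networks(study: PrePostStudy, subset: NodeSubsetSpec = RINGS_12) -> dict:
    """Per-metric T0/T1 change summary for one district and ring subset.

    Reciprocity, diversity and value are only computed when the subset
    excludes ring 3 (their out-ties are structurally missing); otherwise the
    corresponding entries are ``None``, mirroring the report's
    not-applicable cells.
    """
    includes_ring3 = 3 in subset.rings_included
    out: dict[str, object] = {"district": study.district, "subset": subset.label}

    def change(metric) -> MetricChange:
        v0 = _safe(metric, study.t0, subset)
        v1 = _safe(metric, study.t1, subset)
        delta = None if v0 is None or v1 is None else v1 - v0
        return MetricChange(v0, v1, delta)

    out["avg_degree"] = change(nm.average_degree)
    d = change(nm.density)
    out["density"] = MetricChange(
        d.t0, d.t1, d.change, None if d.change is None else 100.0 * d.change
    )

    for ring in (1, 2):
        e0 = _safe(nm.ei_decomposition, study.t0, ring, subset)
        e1 = _safe(nm.ei_decomposition, study.t1, ring, subset)
        i0 = None if e0 is None else e0.ei_index
        i1 = None if e1 is None else e1.ei_index
        out[f"ei_ring{ring}"] = MetricChange(
            i0, i1, None if i0 is None or i1 is None else i1 - i0
        )
        out[f"ei_ring{ring}_decomposition"] = (e0, e1)

    if includes_ring3:
        out["reciprocity"] = None
        out["diversity"] = None
        out["value"] = None
        out["diversity_test"] = None
        out["value_test"] = None
        return out

    r = change(nm.reciprocity)
    out["reciprocity"] = MetricChange(
        r.t0, r.t1, r.change, None if r.change is None else 100.0 * r.change
    )

    for name, actor_metric, summary in (
        ("diversity", _diversity_h, nm.mean_diversity),
        ("value", nm.mean_tie_value, nm.value_summary),
    ):
        s0 = _safe(summary, study.t0, subset)
        s1 = _safe(summary, study.t1, subset)
        out[name] = {
            "t0_mean": None if s0 is None else s0[0],
            "t0_sd": None if s0 is None else s0[1],
            "t1_mean": None if s1 is None else s1[0],
            "t1_sd": None if s1 is None else s1[1],
        }
        pre, post, _ = _actor_metric_pairs(study, actor_metric)
        try:
            out[f"{name}_test"] = paired_t_test(pre, post)
        except ValueError:
            out[f"{name}_test"] = None
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_NA_COLUMNS = (
    "reciprocity_pct",
    "diversity_mean",
    "diversity_sd",
    "value_mean",
    "value_sd",
)


def build_report(studies: Sequence[PrePostStudy]) -> MetricsReport:
    """Descriptive-statistics report over districts: one row per (district,
    ring subset, timepoint), plus a paired-tests table per (district,
    subset).  Densities and reciprocities are reported in percent."""
    if not studies:
        raise ValueError("need at least one district study")
    rows: list[dict] = []
    test_rows: list[dict] = []
    not_applicable: set[tuple[str, str, str]] = set()

    for study in studies:
        for subset in (RINGS_12, RINGS_123):
            summary = compare_networks(study, subset)
            for tp, network in ((Timepoint.T0, study.t0), (Timepoint.T1, study.t1)):
                key = 0 if tp is Timepoint.T0 else 1
                row: dict[str, object] = {
                    "district": study.district,
                    "subset": subset.label,
                    "timepoint": tp.value,
                    "n": len(network.ids_in_rings(subset.rings_included)),
                }

                def pick(metric_change, attr=("t0", "t1")):
                    if metric_change is None:
                        return None
                    return getattr(metric_change, attr[key])

                row["avg_degree"] = pick(summary["avg_degree"])
                dens = pick(summary["density"])
                row["density_pct"] = None if dens is None else 100.0 * dens
                for ring in (1, 2):
                    row[f"ei_ring{ring}"] = pick(summary[f"ei_ring{ring}"])
                    deco = summary[f"ei_ring{ring}_decomposition"][key]
                    row[f"ring{ring}_internal_contacts"] = (
                        None if deco is None else deco.internal_contacts
                    )
                    row[f"ring{ring}_external_contacts"] = (
                        None if deco is None else deco.external_contacts
                    )
                    row[f"ring{ring}_internal_avg_degree"] = (
                        None if deco is None else deco.internal_avg_degree
                    )
                    row[f"ring{ring}_external_avg_degree"] = (
                        None if deco is None else deco.external_avg_degree
                    )
                if summary["reciprocity"] is None:
                    row["reciprocity_pct"] = None
                else:
                    rec = pick(summary["reciprocity"])
                    row["reciprocity_pct"] = None if rec is None else 100.0 * rec
                for name in ("diversity", "value"):
                    agg = summary[name]
                    row[f"{name}_mean"] = (
                        None if agg is None else agg[f"t{key}_mean"]
                    )
                    row[f"{name}_sd"] = None if agg is None else agg[f"t{key}_sd"]
                rows.append(row)

            if 3 in subset.rings_included:
                for column in _NA_COLUMNS:
                    not_applicable.add((study.district, subset.label, column))
            for name in ("diversity", "value"):
                result = summary[f"{name}_test"]
                test_rows.append(
                    {
                        "district": study.district,
                        "subset": subset.label,
                        "metric": name,
                        "t": None if result is None else result.t_statistic,
                        "df": None if result is None else result.degrees_of_freedom,
                        "p_value": None if result is None else result.p_value,
                        "ci_low": None if result is None else result.ci_low,
                        "ci_high": None if result is None else result.ci_high,
                        "n_pairs": None if result is None else result.n_pairs,
                    }
                )

    return MetricsReport(
        table=pd.DataFrame(rows),
        tests=pd.DataFrame(test_rows),
        not_applicable=not_applicable,
    )
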