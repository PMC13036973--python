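"""Detection metrics, statistical comparisons, and the trade-off sweep.

Metric definitions:

* IDA — injury detection accuracy: percentage of injury events matched by
  at least one alert episode inside the match window (default
  [event - 1000 ms, event + 100 ms]).
* FAR — false alarm rate: percentage of alert episodes matched to no
  event (alarm-precision complement; a per-window denominator is available
  via ``denominator="window"``).
* APA — advance prediction accuracy at a lead threshold (default 150 ms):
  percentage of events alerted at least that far in advance (inclusive).
  ``rule="within"`` switches to the |lead| <= threshold variant.
* Adaptation overhead — share of proxy MACs spent on the GP forecaster,
  the agent, and re-pruning rather than on inference.

Consecutive alerts closer than 200 ms are merged into one alert episode
before matching, so a sustained alarm does not inflate either numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MATCH_BEFORE_S = 1.0
MATCH_AFTER_S = 0.1
MERGE_GAP_S = 0.2
LEAD_THRESHOLD_MS = 150.0


@dataclass
class DetectionRecord:
    event_time_s: float
    alert_time_s: float | None
    detected: bool
    lead_ms: float | None = None
    event_type: str | None = None


def merge_alerts(alert_times, gap_s: float = MERGE_GAP_S) -> list[float]:
    """Collapse alerts closer than ``gap_s`` into one episode (first time)."""
    times = sorted(float(t) for t in alert_times)
    episodes: list[float] = []
    last = None
    for t in times:
        if last is None or t - last > gap_s:
            episodes.append(t)
        last = t
    return episodes


def match_events(event_times, alert_times, event_types=None,
                 before_s: float = MATCH_BEFORE_S,
                 after_s: float = MATCH_AFTER_S,
                 merge_gap_s: float = MERGE_GAP_S):
    """Pair alert episodes with events; returns (records, n_unmatched, n_episodes)."""
    episodes = merge_alerts(alert_times, merge_gap_s)
    matched = np.zeros(len(episodes), dtype=bool)
    records = []
    for i, et in enumerate(event_times):
        best = None
        for j, at in enumerate(episodes):
            if et - before_s <= at <= et + after_s:
                matched[j] = True
                if best is None or at < best:
                    best = at
        etype = event_types[i] if event_types is not None else None
        if best is None:
            records.append(DetectionRecord(et, None, False, None, etype))
        else:
            records.append(DetectionRecord(et, best, True,
                                           (et - best) * 1000.0, etype))
    return records, int((~matched).sum()), len(episodes)


def compute_ida(records: list[DetectionRecord]) -> float:
    if not records:
        raise ValueError("IDA undefined with zero events")
    return 100.0 * sum(r.detected for r in records) / len(records)


def compute_far(records, alert_times, merge_gap_s: float = MERGE_GAP_S,
                denominator: str = "alert", n_windows: int | None = None) -> float:
    """Percentage of unmatched alert episodes (or per-window variant)."""
    episodes = merge_alerts(alert_times, merge_gap_s)
    if not episodes:
        warnings.warn("FAR computed with zero alerts; reporting 0 %")
        return 0.0
    matched_times = {r.alert_time_s for r in records if r.detected}
    unmatched = [t for t in episodes if t not in matched_times]
    if denominator == "alert":
        return 100.0 * len(unmatched) / len(episodes)
    if denominator == "window":
        if not n_windows:
            raise ValueError("per-window FAR needs n_windows")
        return 100.0 * len(unmatched) / n_windows
    raise ValueError("denominator must be 'alert' or 'window'")


def compute_apa(records: list[DetectionRecord],
                lead_threshold_ms: float = LEAD_THRESHOLD_MS,
                rule: str = "at_least") -> float:
    """Advance prediction accuracy (inclusive threshold)."""
    if not records:
        raise ValueError("APA undefined with zero events")
    tol = 1e-6  # inclusive threshold robust to float lead arithmetic
    if rule == "at_least":
        hits = sum(1 for r in records
                   if r.detected and r.lead_ms >= lead_threshold_ms - tol)
    elif rule == "within":
        hits = sum(1 for r in records
                   if r.detected and abs(r.lead_ms) <= lead_threshold_ms + tol)
    else:
        raise ValueError("rule must be 'at_least' or 'within'")
    return 100.0 * hits / len(records)


def compute_adaptation_overhead(logs: pd.DataFrame) -> float:
    """100 x adaptation MACs / total MACs over a session log."""
    total = float(logs["macs"].sum())
    if total == 0:
        return 0.0
    return 100.0 * float(logs["adapt_macs"].sum()) / total


def session_metrics(result, lead_threshold_ms: float = LEAD_THRESHOLD_MS) -> dict:
    """IDA/FAR/APA/overhead bundle for one streamed session result."""
    records, _, _ = match_events(result.event_times, result.alert_times)
    out = {"n_events": len(result.event_times),
           "n_alert_episodes": len(merge_alerts(result.alert_times))}
    out["ida_pct"] = compute_ida(records) if records else np.nan
    out["far_pct"] = compute_far(records, result.alert_times) \
        if result.alert_times else 0.0
    out["apa150_pct"] = compute_apa(records, lead_threshold_ms) \
        if records else np.nan
    out["adaptation_overhead_pct"] = compute_adaptation_overhead(result.logs)
    out["latency_proxy_mean"] = float(result.logs["latency_proxy"].mean())
    out["energy_proxy_mean"] = float(result.logs["energy_proxy"].mean())
    return out


def pooled_metrics(results) -> dict:
    """Metrics over a collection of sessions, events and alerts pooled
    with per-session time offsets to keep sessions disjoint."""
    records_all, alerts_all, n_unmatched, n_episodes = [], [], 0, 0
    overhead_num = overhead_den = 0.0
    offset = 0.0
    for res in results:
        ev = [t + offset for t in res.event_times]
        al = [t + offset for t in res.alert_times]
        recs, unm, eps = match_events(ev, al)
        records_all += recs
        alerts_all += al
        n_unmatched += unm
        n_episodes += eps
        overhead_num += float(res.logs["adapt_macs"].sum())
        overhead_den += float(res.logs["macs"].sum())
        offset += float(res.logs["t"].max() or 0.0) + 10.0
    out = {
        "n_events": len(records_all),
        "n_alert_episodes": n_episodes,
        "ida_pct": compute_ida(records_all) if records_all else np.nan,
        "far_pct": (100.0 * n_unmatched / n_episodes) if n_episodes else 0.0,
        "apa150_pct": compute_apa(records_all) if records_all else np.nan,
        "adaptation_overhead_pct":
            100.0 * overhead_num / overhead_den if overhead_den else 0.0,
    }
    return out


def paired_comparison(metric_a, metric_b, alpha: float = 0.01,
                      corrections: int = 1) -> dict:
    """Paired t-test with Bonferroni adjustment of the significance level."""
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 matched pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return {"t": None, "p": None, "mean_diff": float(diff.mean()),
                "significant": False, "exact_tie": bool(np.allclose(diff, 0)),
                "alpha_adjusted": alpha / corrections}
    t, p = stats.ttest_rel(a, b)
    adj = alpha / corrections
    return {"t": float(t), "p": float(p), "mean_diff": float(diff.mean()),
            "significant": bool(p < adj), "exact_tie": False,
            "alpha_adjusted": adj}


def correlation_risk_vs_outcome(risk_scores, outcomes) -> tuple[float, float]:
    """Pearson r (with two-sided p) between risk scores and outcomes."""
    x = np.asarray(risk_scores, float)
    y = np.asarray(outcomes, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tradeoff_sweep(eval_fn, eps_values, hidden_widths) -> pd.DataFrame:
    """Accuracy / latency-proxy grid over exploration rates and Q-network
    widths.  ``eval_fn(eps, width) -> (accuracy, latency_proxy)``."""
    rows = []
    for eps in eps_values:
        for width in hidden_widths:
            acc, lat = eval_fn(eps, width)
            rows.append({"eps": eps, "hidden": width,
                         "accuracy": acc, "latency_proxy": lat})
    return pd.DataFrame(rows)


def pareto_front(df: pd.DataFrame, maximize: str = "accuracy",
                 minimize: str = "latency_proxy") -> np.ndarray:
    """Boolean mask of non-dominated sweep configurations."""
    acc = df[maximize].to_numpy()
    lat = df[minimize].to_numpy()
    n = len(df)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if j != i and acc[j] >= acc[i] and lat[j] <= lat[i] and \
                    (acc[j] > acc[i] or lat[j] < lat[i]):
                dominated[i] = True
                break
    return ~dominated
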