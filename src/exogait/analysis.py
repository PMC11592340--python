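"""sEMG comparison pipeline: step segmentation, gait-cycle
normalization, subject/group averaging with outlier removal, MAV and
peak extraction, percent change against the no-exosuit baseline, and
one-way ANOVA with post hoc pairwise testing.

All statistics run on relative (percent) changes or raw per-subject
metrics; envelopes are treated as unitless, so the pipeline is invariant
to the (unstated) sEMG normalization convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .synthetic import CONDITIONS, MUSCLES, EMGDataset, ProtocolSubject


class AnalysisError(ValueError):
    pass


@dataclass
class CycleMatrix:
    """Steps x normalized-phase matrix for one channel of one recording."""

    data: np.ndarray  # (n_steps, n_points)
    subject_id: int = -1
    condition: str = ""
    muscle: str = ""

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0)


def detect_touchdowns(grf: np.ndarray, rate: float, threshold: float = 30.0,
                      low: float = 5.0) -> np.ndarray:
    """Sample indices of touchdown events (upward GRF threshold crossings
    after a swing interval)."""
    grf = np.asarray(grf, dtype=float)
    above = grf >= threshold
    idx = []
    armed = True
    for i in range(len(grf)):
        if grf[i] < low:
            armed = True
        if above[i] and armed:
            idx.append(i)
            armed = False
    return np.asarray(idx, dtype=int)


def segment_and_normalize(
    envelope: np.ndarray, grf: np.ndarray, rate: float,
    n_points: int = 101, threshold: float = 30.0,
) -> CycleMatrix:
    """Cut an envelope into touchdown-to-touchdown cycles and resample
    each to ``n_points`` by linear interpolation.

    Incomplete first/last fragments are dropped: k touchdowns yield
    k - 1 complete cycles.
    """
    envelope = np.asarray(envelope, dtype=float)
    grf = np.asarray(grf, dtype=float)
    if envelope.shape != grf.shape:
        raise AnalysisError("envelope and GRF must be sampled together")
    td = detect_touchdowns(grf, rate, threshold)
    if len(td) < 2:
        raise AnalysisError("need at least 2 touchdowns to segment steps")
    rows = []
    for a, b in zip(td[:-1], td[1:]):
        seg = envelope[a:b]
        rows.append(np.interp(np.linspace(0.0, len(seg) - 1.0, n_points),
                              np.arange(len(seg)), seg))
    return CycleMatrix(np.vstack(rows))


def average_subject_then_group(
    matrices: list[CycleMatrix],
    outlier_mads: float | None = 3.0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Group-average trace with subject-level outlier elimination.

    Per-subject mean traces are computed first; subjects whose MAV
    deviates from the group median by more than ``outlier_mads`` median
    absolute deviations are excluded (pass ``None`` to disable).  Returns
    ``(group_mean, group_sd, kept_indices)``.
    """
    if len(matrices) < 2:
        raise AnalysisError("need >= 2 subjects for a group average")
    subject_means = np.vstack([m.mean_trace() for m in matrices])
    mavs = np.abs(subject_means).mean(axis=1)
    keep = np.ones(len(matrices), dtype=bool)
    if outlier_mads is not None:
        med = np.median(mavs)
        mad = np.median(np.abs(mavs - med))
        if mad > 0:
            keep = np.abs(mavs - med) <= outlier_mads * mad * 1.4826
    if not keep.any():
        raise AnalysisError("outlier rule excluded every subject")
    kept = subject_means[keep]
    return kept.mean(axis=0), kept.std(axis=0, ddof=0), list(np.where(keep)[0])


def mav(trace: np.ndarray) -> float:
    """Mean absolute value over the cycle."""
    return float(np.mean(np.abs(trace)))


def peak(trace: np.ndarray) -> float:
    return float(np.max(trace))


@dataclass
class SummaryStats:
    """Per muscle x condition MAV/peak metrics and percent changes vs NE."""

    table: pd.DataFrame  # columns: muscle, condition, mav, peak,
    #                                pct_change_mav, pct_change_peak
    n_subjects: int = 0


def summarize(
    traces: dict[str, dict[str, np.ndarray]], baseline: str = "NE",
    n_subjects: int = 0,
) -> SummaryStats:
    """Summary metrics from group-average traces.

    ``traces[muscle][condition]`` is a cycle-normalized group mean trace;
    percent change is ``100 (metric_cond - metric_NE) / metric_NE``.
    """
    rows = []
    for muscle, conds in traces.items():
        if baseline not in conds:
            raise AnalysisError(f"baseline {baseline!r} missing for {muscle}")
        base_mav, base_peak = mav(conds[baseline]), peak(conds[baseline])
        if base_mav == 0 or base_peak == 0:
            raise AnalysisError(f"zero baseline metric for {muscle}")
        for cond, tr in conds.items():
            m, p = mav(tr), peak(tr)
            rows.append({
                "muscle": muscle, "condition": cond, "mav": m, "peak": p,
                "pct_change_mav": 100.0 * (m - base_mav) / base_mav,
                "pct_change_peak": 100.0 * (p - base_peak) / base_peak,
            })
    return SummaryStats(table=pd.DataFrame(rows), n_subjects=n_subjects)


@dataclass
class StatsResult:
    """ANOVA + post hoc results per muscle x metric."""

    table: pd.DataFrame  # muscle, metric, F, p, significant
    pairwise: pd.DataFrame  # muscle, metric, cond_a, cond_b, p, significant
    alpha: float = 0.05


def compare_conditions(
    metrics: pd.DataFrame, alpha: float = 0.05, posthoc: str = "tukey",
) -> StatsResult:
    """One-way ANOVA across conditions per muscle x metric, with post hoc
    pairwise tests.

    ``metrics`` is long format with columns subject_id, condition, muscle,
    metric, value.  Degenerate groups (zero within-group variance
    everywhere) are flagged with NaN statistics rather than raised.
    Post hoc: Tukey HSD (default) or Bonferroni-corrected t-tests.
    """
    if posthoc not in ("tukey", "bonferroni"):
        raise AnalysisError(f"unknown post hoc {posthoc!r}")
    rows, pair_rows = [], []
    for (muscle, metric), g in metrics.groupby(["muscle", "metric"]):
        groups = [g.loc[g.condition == c, "value"].to_numpy()
                  for c in CONDITIONS if (g.condition == c).any()]
        labels = [c for c in CONDITIONS if (g.condition == c).any()]
        if len(groups) < 2 or min(len(x) for x in groups) < 2:
            raise AnalysisError("need >= 2 conditions with >= 2 subjects")
        if all(np.var(x) == 0 for x in groups):
            rows.append({"muscle": muscle, "metric": metric,
                         "F": np.nan, "p": np.nan, "significant": False,
                         "degenerate": True})
            continue
        F, p = sstats.f_oneway(*groups)
        rows.append({"muscle": muscle, "metric": metric, "F": float(F),
                     "p": float(p), "significant": bool(p < alpha),
                     "degenerate": False})
        if posthoc == "tukey":
            res = sstats.tukey_hsd(*groups)
            for i, j in combinations(range(len(groups)), 2):
                pp = float(res.pvalue[i, j])
                pair_rows.append({
                    "muscle": muscle, "metric": metric,
                    "cond_a": labels[i], "cond_b": labels[j],
                    "p": pp, "significant": bool(pp < alpha)})
        else:
            pairs = list(combinations(range(len(groups)), 2))
            for i, j in pairs:
                _, pp = sstats.ttest_ind(groups[i], groups[j])
                pp = min(1.0, float(pp) * len(pairs))
                pair_rows.append({
                    "muscle": muscle, "metric": metric,
                    "cond_a": labels[i], "cond_b": labels[j],
                    "p": pp, "significant": bool(pp < alpha)})
    return StatsResult(table=pd.DataFrame(rows),
                       pairwise=pd.DataFrame(pair_rows), alpha=alpha)


def subject_metrics(dataset: EMGDataset, n_points: int = 101,
                    threshold: float = 30.0) -> pd.DataFrame:
    """Per-subject MAV/peak metrics for every muscle x condition.

    The returned long-format frame feeds :func:`compare_conditions`;
    ``pct_change_*`` columns additionally express each metric relative to
    the same subject's NE baseline.
    """
    rows = []
    for rec in dataset.records:
        for muscle, env in rec.envelopes.items():
            cm = segment_and_normalize(env.values, rec.grf.values, rec.rate,
                                       n_points=n_points, threshold=threshold)
            tr = cm.mean_trace()
            rows.append({"subject_id": rec.subject_id,
                         "condition": rec.condition, "muscle": muscle,
                         "mav": mav(tr), "peak": peak(tr)})
    df = pd.DataFrame(rows)
    base = df[df.condition == "NE"].set_index(["subject_id", "muscle"])
    for col in ("mav", "peak"):
        ref = df.set_index(["subject_id", "muscle"]).index.map(base[col])
        df[f"pct_change_{col}"] = 100.0 * (df[col].to_numpy()
                                           - ref.to_numpy()) / ref.to_numpy()
    return df


def analyze_dataset(dataset: EMGDataset, n_points: int = 101,
                    outlier_mads: float | None = 3.0,
                    alpha: float = 0.05, posthoc: str = "tukey",
                    ) -> tuple[SummaryStats, StatsResult]:
    """Full comparison pipeline on a generated or loaded dataset.

    Group traces per muscle x condition are subject-averaged with the
    outlier rule, summarized as MAV/peak percent changes against NE, and
    the per-subject metrics are compared across conditions with ANOVA +
    post hoc tests.
    """
    traces: dict[str, dict[str, np.ndarray]] = {m: {} for m in MUSCLES}
    for cond in CONDITIONS:
        for muscle in MUSCLES:
            mats = []
            for sid in sorted({r.subject_id for r in dataset.records}):
                rec = dataset.get(sid, cond)
                cm = segment_and_normalize(
                    rec.envelopes[muscle].values, rec.grf.values, rec.rate,
                    n_points=n_points)
                cm.subject_id, cm.condition, cm.muscle = sid, cond, muscle
                mats.append(cm)
            if len(mats) >= 2:
                mean, _sd, _kept = average_subject_then_group(
                    mats, outlier_mads=outlier_mads)
            else:
                mean = mats[0].mean_trace()
            traces[muscle][cond] = mean
    summary = summarize(traces, n_subjects=dataset.n_subjects)

    df = subject_metrics(dataset, n_points=n_points)
    long = df.melt(id_vars=["subject_id", "condition", "muscle"],
                   value_vars=["mav", "peak"], var_name="metric",
                   value_name="value")
    stats = compare_conditions(long, alpha=alpha, posthoc=posthoc)
    return summary, stats


def estimate_pws(
    subject: ProtocolSubject,
    ramp_start: float = 0.8,
    ramp_step: float = 0.05,
    titration_step: float = 0.05,
    max_speed: float = 4.0,
    max_iters: int = 200,
) -> tuple[float, float, float]:
    """Treadmill protocol: find PTS by ramping, then titrate the PWS.

    The treadmill speed is increased from ``ramp_start`` until the
    subject transitions to running (the preferred transition speed, PTS).
    The initial preferred-walking-speed estimate is 0.75 x PTS; from
    there the speed moves up or down by ``titration_step`` following the
    subject's comfort feedback until the feedback direction alternates,
    and the final PWS is the midpoint of the last two visited speeds.
    Returns ``(pts, initial_pws, final_pws)``.
    """
    speed = ramp_start
    while not subject.is_running(speed):
        speed += ramp_step
        if speed > max_speed:
            raise AnalysisError("no walk-to-run transition within range")
    pts = speed
    initial = 0.75 * pts
    speed = initial
    prev_dir = 0
    prev_speed = speed
    for _ in range(max_iters):
        direction = subject.comfort_feedback(speed)
        if prev_dir != 0 and direction != prev_dir:
            return pts, initial, (speed + prev_speed) / 2.0
        prev_dir = direction
        prev_speed = speed
        speed = max(0.1, speed + direction * titration_step)
    return pts, initial, (speed + prev_speed) / 2.0
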