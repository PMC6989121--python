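"""Optogenetic stimulus-response analysis.

Three analyses around stimulation trials:

* responder detection — a cell is a responder if its trial-averaged
  post-stimulus signal exceeds the pre-stimulus baseline mean+2*sigma;
* onset latency — a 4-parameter logistic is fitted to the responder's
  trial-averaged transient, and the onset is where the fitted curve rises
  above baseline mean+1*sigma;
* three-way modulation — per cell, trial means of activity pre-stimulus
  vs during stimulation are compared with a paired t-test; p < alpha
  splits cells into decreased / increased by sign, otherwise unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit

from .events import EventTrain
from .io import StimLog, TraceMatrix

__all__ = [
    "TrialTensor",
    "ResponderCall",
    "ModulationCall",
    "build_trials",
    "classify_responders",
    "sigmoid_onset",
    "classify_modulation",
    "action_window_means",
]


@dataclass
class TrialTensor:
    """Cells x trials x time snippets aligned to stimulus onset or offset.

    ``lags`` is the common time axis relative to the alignment reference
    (onset by default). Trials overlapping a recording edge are dropped
    and counted in ``n_dropped``.
    """

    cell_ids: list[str]
    region: list[str]
    lags: np.ndarray
    data: np.ndarray  # (n_cells, n_trials, n_lags)
    pre_s: float
    post_s: float
    stim_duration_s: float
    align: str
    n_dropped: int
    trial_onsets: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


def build_trials(
    tm: TraceMatrix,
    stim: StimLog,
    pre_s: float = 2.0,
    post_s: float = 4.0,
    align: str = "onset",
) -> TrialTensor:
    """Cut per-stimulus snippets out of the trace matrix.

    ``align="offset"`` shifts the time axis by the stimulus duration so
    lag 0 is the stimulus offset.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    stim_dur = float(np.median(stim.duration_s))
    dt = 1.0 / tm.frame_rate_hz
    lags = np.arange(-pre_s, post_s + dt / 2, dt)
    refs = stim.onsets + (stim_dur if align == "offset" else 0.0)
    keep = (refs - pre_s >= tm.t[0]) & (refs + post_s <= tm.t[-1])
    refs_kept = refs[keep]
    if refs_kept.size == 0:
        raise ValueError("no stimulus fully inside the recording")
    data = np.empty((tm.n_cells, refs_kept.size, lags.size))
    for i in range(tm.n_cells):
        for k, r in enumerate(refs_kept):
            data[i, k] = np.interp(r + lags, tm.t, tm.values[i])
    return TrialTensor(
        cell_ids=list(tm.cell_ids),
        region=list(tm.region),
        lags=lags,
        data=data,
        pre_s=pre_s,
        post_s=post_s,
        stim_duration_s=stim_dur,
        align=align,
        n_dropped=int((~keep).sum()),
        trial_onsets=stim.onsets[keep],
    )


@dataclass
class ResponderCall:
    cell_id: str
    is_responder: bool
    onset_s: float | None  # from the sigmoid fit; present only for responders
    peak_latency_s: float | None
    fit_fallback: bool = False


def _logistic(t, b, A, t0, s):
    z = np.clip(-(t - t0) / s, -500.0, 500.0)
    return b + A / (1.0 + np.exp(z))


def sigmoid_onset(
    lags: np.ndarray,
    y: np.ndarray,
    baseline_mean: float,
    baseline_sd: float,
) -> tuple[float | None, bool]:
    """Onset latency from a 4-parameter logistic fit.

    Fits f(t) = b + A/(1 + exp(-(t - t0)/s)) to the post-reference rise by
    least squares (initialized at b = baseline mean, A = peak - b,
    t0 = half-rise time, s = 0.1 s). The onset is the smallest lag with
    f(lag) > baseline_mean + baseline_sd. Returns (onset, used_fallback);
    on fit failure falls back to the first raw-sample crossing.
    """
    thr = baseline_mean + baseline_sd
    post = lags >= 0
    t_fit, y_fit = lags[post], y[post]
    peak = float(y_fit.max())
    if peak <= thr:
        return None, False
    half = baseline_mean + (peak - baseline_mean) / 2.0
    above = np.nonzero(y_fit >= half)[0]
    t0_init = float(t_fit[above[0]]) if above.size else float(t_fit[len(t_fit) // 2])
    try:
        with warnings.catch_warnings():
            # near-step responses make the covariance singular; only the
            # point estimate is used here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _logistic,
                t_fit,
                y_fit,
                p0=[baseline_mean, peak - baseline_mean, t0_init, 0.1],
                maxfev=5000,
            )
        f = _logistic(t_fit, *popt)
        hit = np.nonzero(f > thr)[0]
        if hit.size and popt[1] > 0:
            return float(t_fit[hit[0]]), False
    except RuntimeError:
        pass
    raw_hit = np.nonzero(y_fit > thr)[0]
    if raw_hit.size:
        return float(t_fit[raw_hit[0]]), True
    return None, True


def classify_responders(
    tt: TrialTensor,
    post_window_s: tuple[float, float] | None = None,
    fit_onsets: bool = True,
    baseline_stats: str = "pooled",
) -> tuple[list[ResponderCall], float]:
    """Mean+2*sigma responder detection on trial-averaged traces.

    A cell is a responder if the maximum of its trial-averaged signal in
    the post-stimulus window exceeds the pre-stimulus baseline
    mean + 2*SD. ``baseline_stats`` picks where the baseline statistics
    come from: "pooled" (default) uses all per-trial pre-stimulus samples,
    so trial-to-trial variability from spontaneous transients widens the
    threshold; "averaged" computes them on the trial-averaged trace, which
    is markedly more liberal for spontaneously active cells. With baseline
    SD zero the threshold degenerates to the baseline mean. Default post
    window: stimulus offset to offset+1.5 s.
    Returns (per-cell calls, responder fraction).
    """
    if baseline_stats not in ("pooled", "averaged"):
        raise ValueError("baseline_stats must be 'pooled' or 'averaged'")
    offset_lag = 0.0 if tt.align == "offset" else tt.stim_duration_s
    if post_window_s is None:
        post_window_s = (offset_lag, offset_lag + 1.5)
    pre_mask = tt.lags < (0.0 if tt.align == "onset" else -tt.stim_duration_s)
    if pre_mask.sum() < 10:
        raise ValueError("pre-stimulus window must contain >= 10 samples")
    post_mask = (tt.lags >= post_window_s[0]) & (tt.lags <= post_window_s[1])
    calls: list[ResponderCall] = []
    avg = tt.data.mean(axis=1)  # (n_cells, n_lags)
    for i, (cid, y) in enumerate(zip(tt.cell_ids, avg)):
        if baseline_stats == "pooled":
            base = tt.data[i][:, pre_mask].ravel()
        else:
            base = y[pre_mask]
        mu, sd = float(base.mean()), float(base.std())
        is_resp = bool(np.max(y[post_mask]) > mu + 2.0 * sd)
        onset = None
        peak_lat = None
        fallback = False
        if is_resp:
            post_idx = np.nonzero(post_mask)[0]
            peak_lat = float(tt.lags[post_idx[np.argmax(y[post_idx])]] - offset_lag)
            rel_lags = tt.lags - offset_lag
            onset, fallback = sigmoid_onset(rel_lags, y, mu, sd) if fit_onsets else (None, False)
        calls.append(
            ResponderCall(
                cell_id=cid,
                is_responder=is_resp,
                onset_s=onset,
                peak_latency_s=peak_lat,
                fit_fallback=fallback,
            )
        )
    frac = sum(c.is_responder for c in calls) / len(calls) if calls else 0.0
    return calls, frac


@dataclass
class ModulationCall:
    cell_id: str
    cls: str  # decreased | unchanged | increased
    p_value: float
    mean_pre: float
    mean_stim: float
    event_rate_stim_hz: float | None = None


def classify_modulation(
    tt: TrialTensor,
    alpha: float = 0.05,
    trains: list[EventTrain] | None = None,
    stim: StimLog | None = None,
) -> tuple[list[ModulationCall], dict[str, float], dict[str, float]]:
    """Paired-t three-way modulation classification.

    Per cell, the trial means of activity pre-stimulus and during
    stimulation are compared with a paired t-test; p < alpha assigns
    decreased/increased by the sign of (stim - pre), otherwise unchanged.
    Identical paired samples give p = 1 (zero-variance convention).

    If event trains and the stimulation log are supplied, each cell's
    event rate during the stimulation windows is attached and per-cluster
    mean rates are returned.
    """
    if tt.n_trials < 2:
        raise ValueError("need >= 2 trials for a paired test")
    pre_mask = tt.lags < (0.0 if tt.align == "onset" else -tt.stim_duration_s)
    on_lag = 0.0 if tt.align == "onset" else -tt.stim_duration_s
    stim_mask = (tt.lags >= on_lag) & (tt.lags < on_lag + tt.stim_duration_s)
    rate_by_cell: dict[str, float] = {}
    if trains is not None and stim is not None:
        total = float(np.sum(stim.duration_s))
        for tr in trains:
            n_in = sum(
                int(np.sum((tr.onsets >= o) & (tr.onsets < o + d)))
                for o, d in zip(stim.onsets, stim.duration_s)
            )
            rate_by_cell[tr.cell_id] = n_in / total if total > 0 else 0.0
    calls: list[ModulationCall] = []
    for i, cid in enumerate(tt.cell_ids):
        pre = tt.data[i][:, pre_mask].mean(axis=1)
        dur = tt.data[i][:, stim_mask].mean(axis=1)
        diff = dur - pre
        if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(dur, pre).pvalue)
        if p < alpha:
            cls = "increased" if dur.mean() > pre.mean() else "decreased"
        else:
            cls = "unchanged"
        calls.append(
            ModulationCall(
                cell_id=cid,
                cls=cls,
                p_value=p,
                mean_pre=float(pre.mean()),
                mean_stim=float(dur.mean()),
                event_rate_stim_hz=rate_by_cell.get(cid),
            )
        )
    n = len(calls)
    fractions = {
        c: sum(call.cls == c for call in calls) / n
        for c in ("decreased", "unchanged", "increased")
    }
    cluster_rates = {}
    if rate_by_cell:
        for c in ("decreased", "unchanged", "increased"):
            rs = [
                call.event_rate_stim_hz
                for call in calls
                if call.cls == c and call.event_rate_stim_hz is not None
            ]
            cluster_rates[c] = float(np.mean(rs)) if rs else np.nan
    return calls, fractions, cluster_rates


@dataclass
class ActionWindowResult:
    cell_ids: list[str]
    mean_pre: np.ndarray
    mean_post: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    frac_significant: float
    n_triggers: int


def action_window_means(
    tm: TraceMatrix,
    trigger_times,
    win_s: float = 1.0,
    alpha: float = 0.05,
) -> ActionWindowResult:
    """Per-cell activity one second before vs after movement onset.

    For each cell, means over [-win, 0) and [0, win) around every trigger
    are compared across triggers with a paired t-test. Returns per-cell
    means, p-values and the fraction of significant cells. Zero triggers
    yield an empty result with count 0.
    """
    trig = np.asarray(trigger_times, dtype=float)
    trig = trig[(trig - win_s >= tm.t[0]) & (trig + win_s <= tm.t[-1])]
    if trig.size == 0:
        return ActionWindowResult(
            cell_ids=list(tm.cell_ids),
            mean_pre=np.empty((tm.n_cells, 0)),
            mean_post=np.empty((tm.n_cells, 0)),
            p_values=np.full(tm.n_cells, np.nan),
            significant=np.zeros(tm.n_cells, dtype=bool),
            frac_significant=0.0,
            n_triggers=0,
        )
    pre = np.empty((tm.n_cells, trig.size))
    post = np.empty((tm.n_cells, trig.size))
    for k, tt in enumerate(trig):
        pre_mask = (tm.t >= tt - win_s) & (tm.t < tt)
        post_mask = (tm.t >= tt) & (tm.t < tt + win_s)
        pre[:, k] = tm.values[:, pre_mask].mean(axis=1)
        post[:, k] = tm.values[:, post_mask].mean(axis=1)
    pvals = np.empty(tm.n_cells)
    for i in range(tm.n_cells):
        diff = post[i] - pre[i]
        if trig.size < 2 or np.isclose(diff.std(), 0.0):
            pvals[i] = 1.0
        else:
            pvals[i] = stats.ttest_rel(post[i], pre[i]).pvalue
    sig = pvals < alpha
    return ActionWindowResult(
        cell_ids=list(tm.cell_ids),
        mean_pre=pre,
        mean_post=post,
        p_values=pvals,
        significant=sig,
        frac_significant=float(sig.mean()),
        n_triggers=int(trig.size),
    )
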