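"""Detection and classification of stimulus-locked Ca2+ responses.

Each ROI's dF/F trace is scanned for transients locked to the protocol's
stimulus events.  A response is accepted when the signal exceeds the mean
pre-stimulation baseline plus ``sd_multiplier`` baseline standard deviations
for a sustained period (>= 3 s by default).  All response amplitudes are
normalized to the same ROI's terminal K+ (depolarization) response, and
neurons are classified as nonresponsive, K_only, specialist (selective for
one of the two urine stimuli) or generalist (responsive to both).

Index conventions (all dimensionless, in [-1, 1]):

* response index   RI  = (m_A - m_B) / (m_A + m_B), where m_X is the mean
  K+-normalized peak amplitude over the repeated presentations of stimulus X;
* reliability index ReI = (r1 - r2) / (r1 + r2) over the two consecutive
  responses to the same stimulus, computed from peak amplitudes (rei_amp)
  and from response integrals (rei_auc).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import K_LABEL, StimulusProtocol

logger = logging.getLogger(__name__)

CLASS_NONRESPONSIVE = "nonresponsive"
CLASS_K_ONLY = "K_only"
CLASS_GENERALIST = "generalist"
NEURON_CLASSES = (
    CLASS_NONRESPONSIVE,
    CLASS_K_ONLY,
    "specialist_A",
    "specialist_B",
    CLASS_GENERALIST,
)


@dataclass
class TraceSet:
    """ROI x time dF/F matrix with a common time axis."""

    time_s: np.ndarray
    dff: np.ndarray
    roi_ids: Sequence[str]
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.roi_ids = list(self.roi_ids)
        if self.dff.shape != (len(self.roi_ids), self.time_s.size):
            raise ValueError(
                f"dff shape {self.dff.shape} does not match "
                f"{len(self.roi_ids)} ROIs x {self.time_s.size} timepoints"
            )
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise ValueError(f"time axis not strictly increasing at row {bad + 1}")
            if np.any(np.abs(dt - np.median(dt)) > 0.01 * np.median(dt)):
                raise ValueError("time axis not uniform within 1% tolerance")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def sampling_rate_hz(self) -> float:
        if self.time_s.size < 2:
            return 1.0
        return 1.0 / float(np.median(np.diff(self.time_s)))


def dff_from_raw(
    raw_f: np.ndarray, time_s: np.ndarray, f0_window_s: float = 20.0
) -> np.ndarray:
    """Convert raw fluorescence to dF/F with F0 = mean over the first window."""
    raw_f = np.atleast_2d(np.asarray(raw_f, dtype=float))
    time_s = np.asarray(time_s, dtype=float)
    mask = time_s < time_s[0] + f0_window_s
    f0 = raw_f[:, mask].mean(axis=1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline fluorescence F0")
    return (raw_f - f0) / f0


@dataclass(frozen=True)
class DetectionCriteria:
    """Parameters of the sustained supra-threshold detection rule."""

    baseline_window_s: float = 20.0
    response_window_s: float = 15.0
    sd_multiplier: float = 2.0
    sustain_s: float = 3.0
    k_required: bool = True
    require_both_presentations: bool = False

    def __post_init__(self) -> None:
        if self.baseline_window_s <= 0 or self.response_window_s <= 0:
            raise ValueError("window lengths must be > 0")
        if self.sustain_s <= 0:
            raise ValueError("sustain_s must be > 0")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


def _sustained_run(above: np.ndarray, min_run: int) -> bool:
    """True iff `above` contains >= min_run consecutive True values."""
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def detect_responses(
    traces: TraceSet,
    protocol: StimulusProtocol,
    criteria: DetectionCriteria | None = None,
) -> pd.DataFrame:
    """Score every (ROI, event) pair against the detection rule.

    Returns one row per ROI x event with columns: roi_id, stimulus,
    presentation (1-based per label), detected, peak_raw, peak_norm, auc,
    baseline_mean, baseline_sd.  peak_norm is peak_raw divided by the same
    ROI's K+ peak and is NaN when that peak is not positive.
    """
    criteria = criteria or DetectionCriteria()
    time = traces.time_s
    fs = traces.sampling_rate_hz
    min_run = math.ceil(criteria.sustain_s * fs)

    rows: list[dict] = []
    presentation_counter: dict[str, int] = {}
    windows: list[tuple] = []
    for i, ev in enumerate(protocol.events):
        presentation_counter[ev.label] = presentation_counter.get(ev.label, 0) + 1
        resp_lo = ev.onset_s
        resp_hi = ev.onset_s + criteria.response_window_s
        if resp_lo < time[0] - 1e-9 or resp_hi > time[-1] + 1e-9:
            raise ValueError(
                f"event {ev.label!r} (onset {ev.onset_s} s) response window "
                f"extends outside the trace extent [{time[0]}, {time[-1]}] s"
            )
        base_lo = ev.onset_s - criteria.baseline_window_s
        if i > 0:
            prev_hi = protocol.events[i - 1].onset_s + criteria.response_window_s
            if base_lo < prev_hi:
                logger.warning(
                    "baseline window of %r truncated to avoid the preceding "
                    "event's response window",
                    ev.label,
                )
                base_lo = prev_hi
        base_lo = max(base_lo, time[0])
        windows.append(
            (ev, presentation_counter[ev.label], base_lo, resp_lo, resp_hi)
        )

    for roi_idx, roi_id in enumerate(traces.roi_ids):
        trace = traces.dff[roi_idx]
        for ev, presentation, base_lo, resp_lo, resp_hi in windows:
            base_mask = (time >= base_lo) & (time < resp_lo)
            resp_mask = (time >= resp_lo) & (time < resp_hi)
            baseline = trace[base_mask]
            if baseline.size == 0:
                raise ValueError(
                    f"event {ev.label!r}: empty baseline window before onset"
                )
            b_mean = float(baseline.mean())
            b_sd = float(baseline.std(ddof=0))
            if b_sd == 0.0:
                logger.warning(
                    "zero-variance baseline for ROI %s event %s; "
                    "threshold reduces to the baseline mean",
                    roi_id,
                    ev.label,
                )
            threshold = b_mean + criteria.sd_multiplier * b_sd
            window = trace[resp_mask]
            above = window > threshold
            detected = _sustained_run(above, min_run)
            peak_raw = float(window.max() - b_mean)
            resid = np.clip(window - b_mean, 0.0, None)
            auc = float(np.trapezoid(resid, time[resp_mask]))
            rows.append(
                {
                    "roi_id": roi_id,
                    "stimulus": ev.label,
                    "presentation": presentation,
                    "detected": detected,
                    "peak_raw": peak_raw,
                    "auc": auc,
                    "baseline_mean": b_mean,
                    "baseline_sd": b_sd,
                }
            )

    events = pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "stimulus",
            "presentation",
            "detected",
            "peak_raw",
            "auc",
            "baseline_mean",
            "baseline_sd",
        ],
    )
    # K+-normalize peaks per ROI
    k_peak = (
        events.loc[events["stimulus"] == K_LABEL]
        .set_index("roi_id")["peak_raw"]
        .rename("k_peak")
    )
    events = events.join(k_peak, on="roi_id")
    with np.errstate(divide="ignore", invalid="ignore"):
        events["peak_norm"] = np.where(
            events["k_peak"] > 0, events["peak_raw"] / events["k_peak"], np.nan
        )
    return events.drop(columns="k_peak")


def _ratio_index(a: float, b: float) -> float:
    """(a - b) / (a + b) with NaN when the denominator vanishes."""
    denom = a + b
    if denom <= 0:
        return float("nan")
    return (a - b) / denom


def classify_neurons(
    events: pd.DataFrame,
    criteria: DetectionCriteria | None = None,
    stim_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each ROI a response class and compute RI / ReI indices.

    A neuron "responds to" a stimulus when it is detected in at least one of
    the stimulus's presentations (both, with ``require_both_presentations``).
    When ``k_required`` (the default) a missing or non-positive K+ response
    makes the neuron nonresponsive regardless of urine events.  RI averages
    the measured K+-normalized peaks of *all* presentations per stimulus,
    with negative measured peaks clipped to zero.
    """
    criteria = criteria or DetectionCriteria()
    if stim_labels is None:
        stim_labels = [s for s in events["stimulus"].unique() if s != K_LABEL]
    if len(stim_labels) != 2:
        raise ValueError(f"expected exactly 2 urine stimuli, got {list(stim_labels)}")
    stim_a, stim_b = stim_labels

    rows = []
    for roi_id, grp in events.groupby("roi_id", sort=False):
        k_rows = grp[grp["stimulus"] == K_LABEL]
        k_detected = bool(k_rows["detected"].any()) if len(k_rows) else False
        k_peak = float(k_rows["peak_raw"].max()) if len(k_rows) else float("nan")
        k_sensitive = k_detected and k_peak > 0

        rec: dict = {"roi_id": roi_id, "k_sensitive": k_sensitive}
        responds: dict[str, bool] = {}
        mean_norm: dict[str, float] = {}
        for stim in (stim_a, stim_b):
            pres = grp[grp["stimulus"] == stim].sort_values("presentation")
            det = pres["detected"].to_numpy(dtype=bool)
            responds[stim] = (
                bool(det.all()) and det.size > 0
                if criteria.require_both_presentations
                else bool(det.any())
            )
            peaks = np.clip(pres["peak_norm"].to_numpy(dtype=float), 0.0, None)
            mean_norm[stim] = float(np.mean(peaks)) if peaks.size else float("nan")
            if len(pres) == 2:
                p1, p2 = np.clip(pres["peak_norm"].to_numpy(dtype=float), 0, None)
                a1, a2 = np.clip(pres["auc"].to_numpy(dtype=float), 0, None)
                rec[f"rei_amp_{stim}"] = _ratio_index(p1, p2)
                rec[f"rei_auc_{stim}"] = _ratio_index(a1, a2)
            else:
                rec[f"rei_amp_{stim}"] = float("nan")
                rec[f"rei_auc_{stim}"] = float("nan")

        if criteria.k_required and not k_sensitive:
            cls = CLASS_NONRESPONSIVE
        elif responds[stim_a] and responds[stim_b]:
            cls = CLASS_GENERALIST
        elif responds[stim_a]:
            cls = f"specialist_{_suffix(stim_a)}"
        elif responds[stim_b]:
            cls = f"specialist_{_suffix(stim_b)}"
        else:
            cls = CLASS_K_ONLY
        rec["neuron_class"] = cls

        urine_responsive = cls == CLASS_GENERALIST or cls.startswith("specialist")
        if urine_responsive:
            ri = _ratio_index(mean_norm[stim_a], mean_norm[stim_b])
            if math.isnan(ri):
                logger.warning(
                    "ROI %s: zero summed amplitude; RI undefined and excluded",
                    roi_id,
                )
            rec["ri"] = ri
        else:
            rec["ri"] = float("nan")
        rows.append(rec)

    cols = ["roi_id", "k_sensitive", "neuron_class", "ri"]
    cols += [f"rei_amp_{s}" for s in (stim_a, stim_b)]
    cols += [f"rei_auc_{s}" for s in (stim_a, stim_b)]
    return pd.DataFrame(rows, columns=cols)


def _suffix(stim_label: str) -> str:
    """specialist class suffix: trailing token of the stimulus label."""
    return stim_label.rsplit("_", 1)[-1] if "_" in stim_label else stim_label


def _round_half_up(x: float, decimals: int = 1) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_population(
    classifications: pd.DataFrame,
    experiment_ids: Sequence | None = None,
) -> dict:
    """Population bookkeeping: class counts and shares.

    Percentages are reported to one decimal (round half up) among (a) all
    K+-sensitive ROIs and (b) urine-sensitive ROIs.  When ``experiment_ids``
    is given (one id per ROI, aligned with the classification rows),
    per-experiment generalist:specialist ratios are included.
    """
    if classifications.empty:
        raise ValueError("empty classification table")
    cls = classifications["neuron_class"]
    counts = {c: int((cls == c).sum()) for c in cls.unique()}
    n_total = int(len(cls))
    n_k = int(classifications["k_sensitive"].sum())
    urine_mask = cls.str.startswith("specialist") | (cls == CLASS_GENERALIST)
    n_urine = int(urine_mask.sum())

    def shares(denom: int) -> dict:
        if denom == 0:
            return {c: None for c in counts}
        return {c: _round_half_up(100.0 * n / denom) for c, n in counts.items()}

    summary = {
        "n_rois": n_total,
        "n_k_sensitive": n_k,
        "n_urine_sensitive": n_urine,
        "counts": counts,
        "pct_of_k_sensitive": {
            c: (_round_half_up(100.0 * n / n_k) if n_k else None)
            for c, n in counts.items()
            if c != CLASS_NONRESPONSIVE
        },
        "pct_of_urine_sensitive": {
            c: (_round_half_up(100.0 * n / n_urine) if n_urine else None)
            for c, n in counts.items()
            if c == CLASS_GENERALIST or c.startswith("specialist")
        },
    }
    if experiment_ids is not None:
        ratios = {}
        df = classifications.assign(_exp=list(experiment_ids))
        for exp, grp in df.groupby("_exp"):
            g = int((grp["neuron_class"] == CLASS_GENERALIST).sum())
            s = int(grp["neuron_class"].str.startswith("specialist").sum())
            ratios[exp] = (g / s) if s else None
        summary["generalist_specialist_ratio_by_experiment"] = ratios
    return summary
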