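"""Gaze-validation pipeline: log fusion, calibration, RMSE, peeks, dispersion.

The two log streams of a session -- the 60 Hz frame log (crosshair,
cursor, target screen positions) and the 100 Hz gaze log -- share a
POSIX clock.  :func:`merge_logs` fuses them into a per-sample timeline,
labelling each gaze sample with its trial and epoch:

* ``pre``       -- the 750 ms of tracking just before stimulus onset
  (75 gaze samples per trial at 10 ms sampling),
* ``stimulus``  -- the 150 ms presentation,
* ``post``      -- a window (default 550 ms) after stimulus offset.

Gaze is expressed in visual degrees relative to the crosshair: the
interpolated moving crosshair during ``pre``, and the *last crosshair
center* (its position on the final frame before onset -- the crosshair
is hidden from onset on) during ``stimulus`` and ``post``.

Downstream statistics mirror the validation analyses of the paradigm:
a single per-session calibration offset (mean gaze-minus-crosshair over
all pre-stimulus samples) subtracted from every sample, radial RMS
tracking and pursuit errors, detection of "peeks" (any stimulus-epoch
gaze sample more than 1.5 deg from the last crosshair center), and
per-epoch dispersion of gaze.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry, screen_to_visual

__all__ = [
    "MergedTimeline",
    "CalibrationOffset",
    "PeekReport",
    "merge_logs",
    "estimate_calibration_offset",
    "apply_offset_correction",
    "radial_rmse",
    "detect_peeks",
    "epoch_dispersion",
]

_EPS = 1e-6  # guard for samples landing exactly on an epoch boundary


@dataclass
class MergedTimeline:
    """Fused per-sample view of one session's frame and gaze logs.

    ``samples`` has one row per retained gaze sample with its trial,
    epoch, crosshair reference (px) and gaze in visual degrees relative
    to that reference.  ``frames`` is the frame log with the same
    trial/window labels plus cursor-minus-crosshair in degrees.
    ``trials`` has one row per trial (onset, offset, last crosshair
    center).
    """

    samples: pd.DataFrame
    frames: pd.DataFrame
    trials: pd.DataFrame
    geometry: DisplayGeometry
    n_dropped_gaze: int
    pre_window_s: float
    post_window_s: float


@dataclass(frozen=True)
class CalibrationOffset:
    """Constant per-session gaze reporting bias in visual degrees."""

    dx_deg: float
    dy_deg: float
    n_samples: int

    @property
    def radial_deg(self) -> float:
        return math.hypot(self.dx_deg, self.dy_deg)


@dataclass(frozen=True)
class PeekReport:
    """Per-trial peek flags and the session-level peek percentage."""

    flags: pd.DataFrame
    percentage: float
    criterion_deg: float
    n_trials: int


def _extract_trials(frames: pd.DataFrame) -> pd.DataFrame:
    """Trial boundaries from runs of stimulus-epoch frames."""
    t = frames["t_posix"].to_numpy(dtype=float)
    is_stim = (frames["epoch"].to_numpy() == "stimulus").astype(int)
    frame_period = float(np.median(np.diff(t))) if len(t) > 1 else 1.0 / 60.0
    edges = np.diff(np.concatenate([[0], is_stim, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    if len(starts) == 0:
        raise ValueError("frame log contains no stimulus epochs; cannot segment trials")
    chx = frames["crosshairX_px"].to_numpy(dtype=float)
    chy = frames["crosshairY_px"].to_numpy(dtype=float)
    rows = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        has_ch = np.flatnonzero(~np.isnan(chx[:s]))
        if len(has_ch) == 0:
            raise ValueError(f"no crosshair frames precede stimulus run {k}")
        last = has_ch[-1]
        rows.append(
            {
                "trial": k,
                "onset_posix": t[s],
                "offset_posix": t[e] + frame_period,
                "last_crosshair_t_posix": t[last],
                "last_crosshairX_px": chx[last],
                "last_crosshairY_px": chy[last],
            }
        )
    return pd.DataFrame(rows)


def merge_logs(
    frames: pd.DataFrame,
    gaze: pd.DataFrame,
    geometry: DisplayGeometry | None = None,
    tolerance_s: float = 0.010,
    pre_window_s: float = 0.75,
    post_window_s: float = 0.55,
) -> MergedTimeline:
    """Fuse a frame log and a gaze log into a labelled per-sample timeline.

    Gaze samples are joined to the nearest frame timestamp; samples
    farther than ``tolerance_s`` from every frame are dropped (and
    counted).  The crosshair position at each pre-stimulus gaze time is
    interpolated linearly between frames.  Raises if either log is
    unsorted or if no gaze sample overlaps the frame log.
    """
    if geometry is None:
        geometry = DisplayGeometry()
    ft = frames["t_posix"].to_numpy(dtype=float)
    gt = gaze["t_posix"].to_numpy(dtype=float)
    if np.any(np.diff(ft) < 0):
        raise ValueError("frame log timestamps are not sorted")
    if np.any(np.diff(gt) < 0):
        raise ValueError("gaze log timestamps are not sorted")

    trials = _extract_trials(frames)
    onsets = trials["onset_posix"].to_numpy()
    offsets = trials["offset_posix"].to_numpy()

    # nearest-frame join
    idx = np.clip(np.searchsorted(ft, gt), 1, len(ft) - 1)
    nearest = np.where(np.abs(gt - ft[idx - 1]) <= np.abs(ft[idx] - gt), idx - 1, idx)
    matched = np.abs(gt - ft[nearest]) <= tolerance_s + 1e-12
    n_dropped = int((~matched).sum())
    if matched.sum() == 0:
        raise ValueError("no gaze sample within tolerance of any frame; clocks disjoint?")
    gt_m = gt[matched]
    gx = gaze["gazeX_px"].to_numpy(dtype=float)[matched]
    gy = gaze["gazeY_px"].to_numpy(dtype=float)[matched]

    # per-sample trial and epoch labels
    window_start = onsets - pre_window_s
    trial_of = np.searchsorted(window_start - _EPS, gt_m, side="right") - 1
    trial_ids = np.full(len(gt_m), -1, dtype=int)
    epoch = np.full(len(gt_m), "none", dtype=object)
    valid = trial_of >= 0
    tv = trial_of[valid]
    t_in = gt_m[valid]
    on, off = onsets[tv], offsets[tv]
    in_pre = (t_in < on - _EPS) & (t_in >= on - pre_window_s - _EPS)
    in_stim = (t_in >= on - _EPS) & (t_in < off - _EPS)
    in_post = (t_in >= off - _EPS) & (t_in <= off + post_window_s + _EPS)
    lab = np.full(len(t_in), "none", dtype=object)
    lab[in_pre] = "pre"
    lab[in_stim] = "stimulus"
    lab[in_post] = "post"
    epoch[valid] = lab
    trial_ids[valid] = np.where(lab == "none", -1, tv)

    # crosshair reference per sample
    chx = frames["crosshairX_px"].to_numpy(dtype=float)
    chy = frames["crosshairY_px"].to_numpy(dtype=float)
    has_ch = ~np.isnan(chx)
    ref_x = np.full(len(gt_m), np.nan)
    ref_y = np.full(len(gt_m), np.nan)
    pre_mask = epoch == "pre"
    if pre_mask.any():
        # interpolate within the trial's own tracking stretch; samples after
        # the trial's last crosshair frame clamp to it rather than bridging
        # the hidden gap into the next trial's trajectory
        last_ch_t = trials["last_crosshair_t_posix"].to_numpy()
        t_interp = np.minimum(gt_m[pre_mask], last_ch_t[trial_ids[pre_mask]])
        ref_x[pre_mask] = np.interp(t_interp, ft[has_ch], chx[has_ch])
        ref_y[pre_mask] = np.interp(t_interp, ft[has_ch], chy[has_ch])
    frozen = (epoch == "stimulus") | (epoch == "post")
    if frozen.any():
        last_x = trials["last_crosshairX_px"].to_numpy()
        last_y = trials["last_crosshairY_px"].to_numpy()
        ref_x[frozen] = last_x[trial_ids[frozen]]
        ref_y[frozen] = last_y[trial_ids[frozen]]

    have_ref = ~np.isnan(ref_x)
    vis = np.full((len(gt_m), 2), np.nan)
    if have_ref.any():
        vis[have_ref] = screen_to_visual(
            np.stack([gx[have_ref], gy[have_ref]], axis=-1),
            geometry,
            np.stack([ref_x[have_ref], ref_y[have_ref]], axis=-1),
        )

    samples = pd.DataFrame(
        {
            "t_posix": gt_m,
            "gazeX_px": gx,
            "gazeY_px": gy,
            "trial": trial_ids,
            "epoch": epoch,
            "refX_px": ref_x,
            "refY_px": ref_y,
            "gaze_x_deg": vis[:, 0],
            "gaze_y_deg": vis[:, 1],
        }
    )

    # frame labels + cursor deviation for tracking RMSE
    f_trial = np.searchsorted(window_start - _EPS, ft, side="right") - 1
    f_window = np.full(len(ft), "none", dtype=object)
    fv = f_trial >= 0
    on_f, off_f = onsets[np.clip(f_trial, 0, None)], offsets[np.clip(f_trial, 0, None)]
    f_pre = fv & (ft < on_f - _EPS) & (ft >= on_f - pre_window_s - _EPS)
    f_stim = fv & (ft >= on_f - _EPS) & (ft < off_f - _EPS)
    f_post = fv & (ft >= off_f - _EPS) & (ft <= off_f + post_window_s + _EPS)
    f_window[f_pre] = "pre"
    f_window[f_stim] = "stimulus"
    f_window[f_post] = "post"
    curx = frames["cursorX_px"].to_numpy(dtype=float)
    cury = frames["cursorY_px"].to_numpy(dtype=float)
    both = has_ch & ~np.isnan(curx)
    cdx = np.full(len(ft), np.nan)
    cdy = np.full(len(ft), np.nan)
    if both.any():
        dev = screen_to_visual(
            np.stack([curx[both], cury[both]], axis=-1),
            geometry,
            np.stack([chx[both], chy[both]], axis=-1),
        )
        cdx[both], cdy[both] = dev[:, 0], dev[:, 1]
    frames_labelled = frames.copy()
    frames_labelled["trial"] = np.where(f_window == "none", -1, f_trial)
    frames_labelled["window"] = f_window
    frames_labelled["cursor_dx_deg"] = cdx
    frames_labelled["cursor_dy_deg"] = cdy

    return MergedTimeline(
        samples=samples,
        frames=frames_labelled,
        trials=trials,
        geometry=geometry,
        n_dropped_gaze=n_dropped,
        pre_window_s=pre_window_s,
        post_window_s=post_window_s,
    )


def estimate_calibration_offset(timeline: MergedTimeline) -> CalibrationOffset:
    """Session calibration bias: mean gaze-minus-crosshair over pre samples.

    One offset per observer session, from all gaze samples in the 750 ms
    windows before stimulus onset (75 samples per trial on complete
    10 ms logs).
    """
    pre = timeline.samples[timeline.samples["epoch"] == "pre"]
    if pre.empty:
        raise ValueError("timeline has no pre-stimulus samples; cannot estimate offset")
    return CalibrationOffset(
        dx_deg=float(pre["gaze_x_deg"].mean()),
        dy_deg=float(pre["gaze_y_deg"].mean()),
        n_samples=len(pre),
    )


def apply_offset_correction(timeline: MergedTimeline, offset: CalibrationOffset) -> MergedTimeline:
    """Subtract a constant offset from every gaze sample (visual degrees)."""
    if not (math.isfinite(offset.dx_deg) and math.isfinite(offset.dy_deg)):
        raise ValueError("offset must be finite")
    samples = timeline.samples.copy()
    samples["gaze_x_deg"] = samples["gaze_x_deg"] - offset.dx_deg
    samples["gaze_y_deg"] = samples["gaze_y_deg"] - offset.dy_deg
    return replace(timeline, samples=samples)


def radial_rmse(
    timeline: MergedTimeline,
    pair: str = "gaze",
    epoch: str = "pre",
    aggregation: str = "per_trial",
) -> float:
    """Radial RMS error in degrees for a position pair within an epoch.

    ``pair='cursor'`` measures tracking error (cursor vs crosshair, per
    frame); ``pair='gaze'`` measures pursuit error (gaze vs crosshair
    reference, per gaze sample).  ``aggregation='per_trial'`` computes
    the RMS of radial distances within each trial and averages across
    trials; ``'pooled'`` takes one RMS over all samples.  The two agree
    when every trial contributes equally.
    """
    if pair == "gaze":
        sel = timeline.samples
        sel = sel[(sel["epoch"] == epoch) & (sel["trial"] >= 0)]
        r = np.hypot(sel["gaze_x_deg"].to_numpy(), sel["gaze_y_deg"].to_numpy())
        trial = sel["trial"].to_numpy()
    elif pair == "cursor":
        sel = timeline.frames
        sel = sel[(sel["window"] == epoch) & sel["cursor_dx_deg"].notna()]
        r = np.hypot(sel["cursor_dx_deg"].to_numpy(), sel["cursor_dy_deg"].to_numpy())
        trial = sel["trial"].to_numpy()
    else:
        raise ValueError(f"pair must be 'gaze' or 'cursor', got {pair!r}")
    if len(r) == 0:
        raise ValueError(f"no {pair} samples in epoch {epoch!r}")
    if aggregation == "pooled":
        return float(np.sqrt(np.mean(r**2)))
    if aggregation != "per_trial":
        raise ValueError(f"aggregation must be 'per_trial' or 'pooled', got {aggregation!r}")
    df = pd.DataFrame({"trial": trial, "r2": r**2})
    per_trial = df.groupby("trial")["r2"].mean().pow(0.5)
    return float(per_trial.mean())


def detect_peeks(timeline: MergedTimeline, criterion_deg: float = 1.5) -> PeekReport:
    """Flag trials whose gaze left the crosshair during the stimulus.

    A peek is any stimulus-epoch gaze sample more than ``criterion_deg``
    from the last crosshair center.  Expects an offset-corrected
    timeline (see :func:`apply_offset_correction`).
    """
    stim = timeline.samples[timeline.samples["epoch"] == "stimulus"]
    r = np.hypot(stim["gaze_x_deg"].to_numpy(), stim["gaze_y_deg"].to_numpy())
    exceeded = pd.Series(r > criterion_deg, index=stim.index).groupby(stim["trial"]).any()
    flags = pd.DataFrame({"trial": timeline.trials["trial"]})
    flags["peeked"] = flags["trial"].map(exceeded).fillna(False).astype(bool)
    n = len(flags)
    pct = 100.0 * flags["peeked"].sum() / n if n else float("nan")
    return PeekReport(flags=flags, percentage=float(pct), criterion_deg=criterion_deg, n_trials=n)


def epoch_dispersion(timeline: MergedTimeline) -> pd.DataFrame:
    """Mean and SD of gaze (deg, relative to crosshair) per epoch.

    Rows are the pre / stimulus / post epochs; columns ``mean_x``,
    ``mean_y``, ``sd_x``, ``sd_y``, ``n`` (sample counts).  SDs pool all
    samples of the epoch across trials.
    """
    sel = timeline.samples[timeline.samples["epoch"].isin(["pre", "stimulus", "post"])]
    out = sel.groupby("epoch").agg(
        mean_x=("gaze_x_deg", "mean"),
        mean_y=("gaze_y_deg", "mean"),
        sd_x=("gaze_x_deg", "std"),
        sd_y=("gaze_y_deg", "std"),
        n=("gaze_x_deg", "size"),
    )
    return out.reindex(["pre", "stimulus", "post"])
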