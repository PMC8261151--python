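"""Raw multiplexed ion counts -> one clean, replicate-averaged flux panel.

The pipeline order is fixed:

    normalize -> gap-fill -> blank-subtract -> replicate-average
              -> spline-smooth -> 5-min aggregate

Normalization divides every channel by the primary-ion reference channel
(m/z 21, the H3(18)O+ hydronium isotopologue) and multiplies by 500,
putting all channels on the ncps (normalized counts per second) scale.
Gap filling linearly interpolates the periodic gaps the 10-min-on /
50-min-off chamber rotation leaves, up to a configurable maximum run
(default 50 min); longer runs and leading/trailing gaps stay missing.
The blank chamber is gap-filled before subtraction so the background is
defined at every sample timepoint. Smoothing uses a per-channel cubic
smoothing spline with the penalty chosen by generalized cross-validation
(deterministic, seedless), then values are averaged inside consecutive
5-min windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .panel import FluxPanel, IonCountMatrix, PanelFormatError

__all__ = ["PreprocessConfig", "PreprocessLog", "normalize_primary_ion",
           "fill_gaps", "subtract_background", "average_replicates",
           "smooth_and_aggregate", "ordination_overview", "run_pipeline",
           "OrdinationResult"]


@dataclass
class PreprocessConfig:
    reference_mz: float = 21.0
    normalization_constant: float = 500.0
    max_gap_minutes: float = 50.0
    aggregation_minutes: float = 5.0
    smoothing_lam: float | None = None     # None -> per-channel GCV
    clip_negative: bool = True
    wetup_minutes: float | None = None     # required to label phases
    min_points_per_channel: int = 10
    mz_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.normalization_constant <= 0 or self.reference_mz <= 0:
            raise ValueError("normalization constants must be positive")
        if self.aggregation_minutes <= 0:
            raise ValueError("aggregation step must be positive")


@dataclass
class PreprocessLog:
    """Counts of what each stage did, in pipeline order."""

    steps: list[str] = field(default_factory=list)
    cells_filled: int = 0
    cells_unfilled: int = 0
    cells_clipped: int = 0
    channels_dropped: list[float] = field(default_factory=list)

    def record(self, step: str) -> None:
        self.steps.append(step)


def _find_reference(matrix: IonCountMatrix, cfg: PreprocessConfig) -> float:
    for c in matrix.channels:
        if abs(c - cfg.reference_mz) <= cfg.mz_tolerance:
            return c
    raise PanelFormatError(
        f"reference channel m/z {cfg.reference_mz} absent from {matrix.chamber_id!r}")


def normalize_primary_ion(matrix: IonCountMatrix,
                          cfg: PreprocessConfig | None = None) -> IonCountMatrix:
    """Divide every channel by the m/z 21 reference and scale by 500.

    The reference must be observed and strictly positive wherever any
    other channel is observed; the reference channel is dropped from the
    output.
    """
    cfg = cfg or PreprocessConfig()
    ref_col = _find_reference(matrix, cfg)
    ref = matrix.data[ref_col].to_numpy(dtype=float)
    others = matrix.data.drop(columns=[ref_col])
    observed_any = (~others.isna()).any(axis=1).to_numpy()
    bad = observed_any & (np.isnan(ref) | (ref <= 0))
    if bad.any():
        t = matrix.timestamps[np.argmax(bad)]
        raise PanelFormatError(
            f"reference ion missing or non-positive at t={t:g} s in "
            f"{matrix.chamber_id!r}")
    out = others.div(pd.Series(ref, index=others.index), axis=0) \
        * cfg.normalization_constant
    return IonCountMatrix(out, chamber_id=matrix.chamber_id)


def _fill_column(v: np.ndarray, max_run: int) -> tuple[np.ndarray, int, int]:
    """Linearly fill interior NaN runs of length <= max_run."""
    v = v.copy()
    isnan = np.isnan(v)
    filled = unfilled = 0
    i = 0
    n = len(v)
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if interior and run <= max_run:
            left, right = v[i - 1], v[j]
            v[i:j] = left + (np.arange(1, run + 1) / (run + 1)) * (right - left)
            filled += run
        else:
            unfilled += run
        i = j
    return v, filled, unfilled


def fill_gaps(matrix: IonCountMatrix, cfg: PreprocessConfig | None = None,
              log: PreprocessLog | None = None) -> IonCountMatrix:
    """Fill interior missing runs up to ``max_gap_minutes`` by linear
    interpolation; leading/trailing and over-long runs stay missing."""
    cfg = cfg or PreprocessConfig()
    t = matrix.timestamps
    if len(t) >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise PanelFormatError(
                f"{matrix.chamber_id!r}: timestamps not on a regular grid")
        step_min = steps[0] / 60.0
    else:
        step_min = cfg.aggregation_minutes
    max_run = max(1, int(round(cfg.max_gap_minutes / step_min)))
    out = {}
    filled_total = unfilled_total = 0
    for c in matrix.channels:
        v, filled, unfilled = _fill_column(matrix.data[c].to_numpy(dtype=float),
                                           max_run)
        out[c] = v
        filled_total += filled
        unfilled_total += unfilled
    if log is not None:
        log.cells_filled += filled_total
        log.cells_unfilled += unfilled_total
    return IonCountMatrix(pd.DataFrame(out, index=t), chamber_id=matrix.chamber_id)


def subtract_background(sample: IonCountMatrix, blank: IonCountMatrix,
                        cfg: PreprocessConfig | None = None,
                        log: PreprocessLog | None = None) -> IonCountMatrix:
    """Entrywise sample - blank (blank gap-filled first by the caller);
    negatives clipped at 0 when configured (fluxes are non-negative)."""
    cfg = cfg or PreprocessConfig()
    missing = set(sample.channels) ^ set(blank.channels)
    if missing:
        raise PanelFormatError(f"channel mismatch between sample and blank: "
                               f"{sorted(missing)}")
    if not np.array_equal(sample.timestamps, blank.timestamps):
        raise PanelFormatError("sample and blank must share the time grid")
    diff = sample.data - blank.data[sample.data.columns]
    if cfg.clip_negative:
        neg = (diff < 0).to_numpy()
        n_clip = int(np.nansum(neg))
        diff = diff.clip(lower=0.0)
        if log is not None:
            log.cells_clipped += n_clip
    return IonCountMatrix(diff, chamber_id=sample.chamber_id)


def average_replicates(matrices: list[IonCountMatrix]) -> IonCountMatrix:
    """Pointwise mean over replicates, ignoring missing cells.

    A cell is missing in the output only if missing in every replicate;
    the multiplexed rotation guarantees replicates observe different
    minutes, so propagating NaN would destroy most of the record.
    """
    if len(matrices) < 2:
        warnings.warn("fewer than 2 replicates: passthrough average", stacklevel=2)
        return matrices[0].copy()
    first = matrices[0]
    for m in matrices[1:]:
        if set(m.channels) != set(first.channels) or \
                not np.array_equal(m.timestamps, first.timestamps):
            raise PanelFormatError("replicates must share grid and channel set")
    stack = np.stack([m.data[first.data.columns].to_numpy(dtype=float)
                      for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(stack, axis=0)
    return IonCountMatrix(pd.DataFrame(mean, index=first.timestamps,
                                       columns=first.data.columns),
                          chamber_id="mean")


def smooth_and_aggregate(matrix: IonCountMatrix,
                         cfg: PreprocessConfig | None = None,
                         log: PreprocessLog | None = None) -> FluxPanel:
    """Per-channel smoothing spline (GCV by default), then mean within
    consecutive aggregation windows (default 5 min).

    Channels with fewer than ``min_points_per_channel`` observed points
    are dropped with a warning. The output grid is labelled by window
    start time; phases attach at ``cfg.wetup_minutes``.
    """
    cfg = cfg or PreprocessConfig()
    t_min = matrix.timestamps / 60.0
    agg = cfg.aggregation_minutes
    window = np.floor((t_min - t_min[0]) / agg).astype(int)
    n_windows = window.max() + 1
    grid = t_min[0] + np.arange(n_windows) * agg

    out = {}
    for c in matrix.channels:
        v = matrix.data[c].to_numpy(dtype=float)
        obs = ~np.isnan(v)
        if obs.sum() < cfg.min_points_per_channel:
            warnings.warn(f"channel {c} dropped: only {int(obs.sum())} observed "
                          f"points", stacklevel=2)
            if log is not None:
                log.channels_dropped.append(c)
            continue
        t_obs = t_min[obs]
        v_obs = v[obs]
        if np.ptp(v_obs) == 0:
            smooth = np.full_like(t_min, v_obs[0])  # constants pass through
        else:
            spl = make_smoothing_spline(t_obs, v_obs, lam=cfg.smoothing_lam)
            smooth = np.where((t_min >= t_obs[0]) & (t_min <= t_obs[-1]),
                              spl(t_min), np.nan)
        agg_vals = np.full(n_windows, np.nan)
        for w in range(n_windows):
            vals = smooth[window == w]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                agg_vals[w] = vals.mean()
        if cfg.clip_negative:
            agg_vals = np.clip(agg_vals, 0.0, None)
        out[c] = agg_vals

    if not out:
        raise PanelFormatError("all channels dropped during smoothing")
    df = pd.DataFrame(out, index=grid)
    return FluxPanel(df, wetup_time=cfg.wetup_minutes)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame            # timepoints x components, with 'phase' column
    loadings: pd.DataFrame          # channels x components
    explained_variance_ratio: np.ndarray


def ordination_overview(panel: FluxPanel, n_components: int | None = None,
                        scale: bool = False) -> OrdinationResult:
    """PCA of the timepoint x channel matrix (centered; optionally
    standardized). Scores carry the phase labels; loadings are per
    channel; variance fractions sum to 1 over the full rank."""
    from sklearn.decomposition import PCA

    x = panel.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        keep = ~np.isnan(x).any(axis=1)
        x = x[keep]
        phases = panel.phases[keep]
        times = panel.times[keep]
    else:
        phases = panel.phases
        times = panel.times
    if x.shape[1] < 2:
        raise ValueError("ordination needs at least 2 channels")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("constant panel: no variance to ordinate")
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        xc = xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(xc)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, index=times, columns=comp_names)
    score_df["phase"] = phases
    load_df = pd.DataFrame(pca.components_.T, index=panel.channels,
                           columns=comp_names)
    return OrdinationResult(score_df, load_df, pca.explained_variance_ratio_)


def run_pipeline(samples: list[IonCountMatrix], blank: IonCountMatrix,
                 cfg: PreprocessConfig | None = None) -> tuple[FluxPanel,
                                                               PreprocessLog]:
    """The full fixed-order chain on raw replicate + blank matrices."""
    cfg = cfg or PreprocessConfig()
    log = PreprocessLog()

    norm = [normalize_primary_ion(m, cfg) for m in samples]
    blank_norm = normalize_primary_ion(blank, cfg)
    log.record("normalize_primary_ion")

    filled = [fill_gaps(m, cfg, log) for m in norm]
    blank_filled = fill_gaps(blank_norm, cfg, log)
    log.record("fill_gaps")

    subtracted = [subtract_background(m, blank_filled, cfg, log) for m in filled]
    log.record("subtract_background")

    mean = average_replicates(subtracted)
    log.record("average_replicates")

    panel = smooth_and_aggregate(mean, cfg, log)
    log.record("smooth_and_aggregate")
    return panel, log
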