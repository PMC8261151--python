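"""Core in-memory containers for volatile-compound flux data.

Two tabular containers move between all pipeline stages:

``IonCountMatrix``
    Raw (or partially processed) ion counts from a single measurement
    chamber: rows are timestamps in seconds, columns are m/z channels.
    Missing observations (the multiplexed chamber rotation leaves each
    chamber unobserved 50 minutes out of every 60) are ``NaN``, never 0.

``FluxPanel``
    The clean exchange format: a regular grid in minutes of primary-ion
    normalized signal (ncps), one column per m/z channel, optionally
    split into a pre-wet-up ("dry") and post-wet-up ("wet") phase at a
    single wet-up timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IonCountMatrix", "FluxPanel", "PanelFormatError"]


class PanelFormatError(ValueError):
    """A matrix or panel violates its structural invariants."""


def _check_channels(columns) -> None:
    labels = [float(c) for c in columns]
    if len(set(labels)) != len(labels):
        seen, dupes = set(), []
        for c in labels:
            if c in seen:
                dupes.append(c)
            seen.add(c)
        raise PanelFormatError(f"duplicate m/z channel label(s): {sorted(set(dupes))}")


@dataclass
class IonCountMatrix:
    """Ion counts for one chamber: index = seconds, columns = m/z (float).

    Invariants: strictly increasing timestamps, unique channels,
    non-negative counts where observed (``NaN`` marks missing cells).
    """

    data: pd.DataFrame
    chamber_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.data.index, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise PanelFormatError(
                f"timestamps not strictly increasing (row {bad}, t={t[bad]:g} s)"
            )
        _check_channels(self.data.columns)
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            row = int(np.argwhere(np.nanmin(vals, axis=1) < 0)[0][0])
            raise PanelFormatError(f"negative count at row index {row}")
        self.data.columns = [float(c) for c in self.data.columns]
        self.data.index = t

    @property
    def channels(self) -> list[float]:
        return [float(c) for c in self.data.columns]

    @property
    def timestamps(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    def copy(self) -> "IonCountMatrix":
        return IonCountMatrix(self.data.copy(), self.chamber_id)


@dataclass
class FluxPanel:
    """Regular-grid multichannel flux panel (minutes x m/z, values in ncps).

    Parameters
    ----------
    data
        DataFrame indexed by time in minutes on a constant step, one
        column per m/z channel.
    wetup_time
        Time (minutes) of the wet-up perturbation. Timepoints strictly
        before it are labelled ``"dry"``, the rest ``"wet"``. ``None``
        means a single unlabelled phase (all ``"dry"``).
    annotation
        Optional mapping m/z -> compound name, carried for reporting.
    """

    data: pd.DataFrame
    wetup_time: float | None = None
    annotation: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0:
            raise PanelFormatError("panel has no channels")
        _check_channels(self.data.columns)
        self.data.columns = [float(c) for c in self.data.columns]
        t = np.asarray(self.data.index, dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise PanelFormatError("panel time grid is not a constant positive step")
        self.data.index = t

    @property
    def step(self) -> float:
        """Grid step in minutes."""
        t = self.times
        if len(t) < 2:
            raise PanelFormatError("panel has fewer than 2 timepoints; step undefined")
        return float(t[1] - t[0])

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def channels(self) -> list[float]:
        return [float(c) for c in self.data.columns]

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def phases(self) -> np.ndarray:
        """Per-timepoint phase label, ``"dry"`` or ``"wet"``."""
        if self.wetup_time is None:
            return np.full(self.n_times, "dry", dtype=object)
        return np.where(self.times < self.wetup_time, "dry", "wet").astype(object)

    def select_phase(self, phase: str | None) -> "FluxPanel":
        """Return the sub-panel for one phase (``None`` -> whole panel)."""
        if phase is None:
            return self
        if phase not in ("dry", "wet"):
            raise ValueError(f"phase must be 'dry' or 'wet', got {phase!r}")
        mask = self.phases == phase
        if not mask.any():
            raise ValueError(f"panel contains no {phase!r} timepoints")
        return FluxPanel(self.data.loc[mask].copy(), wetup_time=None,
                         annotation=dict(self.annotation))

    def series(self, channel: float) -> np.ndarray:
        col = self._resolve(channel)
        return self.data[col].to_numpy(dtype=float)

    def _resolve(self, channel: float, tol: float = 0.005) -> float:
        channel = float(channel)
        cols = np.array(self.channels)
        hits = np.where(np.abs(cols - channel) <= tol)[0]
        if len(hits) == 0:
            raise KeyError(f"no channel within {tol} of m/z {channel}")
        return float(cols[hits[np.argmin(np.abs(cols[hits] - channel))]])

    def copy(self) -> "FluxPanel":
        return FluxPanel(self.data.copy(), self.wetup_time, dict(self.annotation))
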