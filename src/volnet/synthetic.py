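"""Synthetic pulse-perturbed, lag-coupled flux panels with known ground truth.

The generator is a statistical stand-in for a soil wet-up experiment, not
a soil model. Each channel carries

* a constant baseline (optional slow linear drift),
* a stochastic AR(1) "activity" fluctuation (the signal the lagged
  couplings act on — without it sources would be flat and couplings
  unidentifiable),
* an optional wet-up pulse (difference of exponentials: fast rise, slow
  decay),
* incoming coupled terms ``form(gain * (source(t - lag) - baseline_src))``
  with linear, quadratic or threshold functional forms,
* additive Gaussian measurement noise (sd = ``noise_sd`` x baseline).

``generate_raw_counts`` then re-expresses a clean panel as the raw data a
multiplexed chamber experiment would produce: five replicate jars plus a
blank, counts scaled by a primary-ion reference channel (m/z 21),
additive blank background, multiplicative log-normal replicate noise, and
a 10-min-on / 50-min-off measurement rotation that masks each jar outside
its slot in every 60-min cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import FluxPanel, IonCountMatrix

__all__ = ["CouplingSpec", "CouplingEdge", "GroundTruth", "SpecValidationError",
           "generate_clean_panel", "generate_raw_counts", "ground_truth",
           "default_mz_labels"]

FORMS = ("linear", "quadratic", "threshold")


class SpecValidationError(ValueError):
    """A CouplingSpec field violates its invariants."""


@dataclass(frozen=True)
class CouplingEdge:
    source: int
    target: int
    lag_steps: int
    gain: float = 1.0
    form: str = "linear"


@dataclass
class CouplingSpec:
    """Generative description of a synthetic flux experiment.

    Defaults emulate the study design: a 9-day run at 5-min resolution
    with the wet-up pulse at day 6 (6 days dry, 3 days wet).
    """

    n_channels: int = 8
    duration: float = 12960.0        # minutes (9 days)
    step: float = 5.0                # minutes
    edges: list[CouplingEdge] = field(default_factory=list)
    pulse_onset: float = 8640.0      # minutes (day 6)
    pulse_channels: tuple[int, ...] = ()
    pulse_rise: float = 30.0         # minutes
    pulse_decay: float = 360.0       # minutes
    pulse_amplitude: float = 20.0    # ncps
    baseline: float = 10.0           # ncps, per channel
    drift: float = 0.0               # ncps per minute (slow linear drift)
    driver_sd: float = 0.2           # AR(1) activity sd, fraction of baseline
    driver_phi: float = 0.3          # AR(1) coefficient per step
    noise_sd: float = 0.05           # measurement noise sd, fraction of baseline
    seed: int = 0

    def __post_init__(self) -> None:
        self.edges = [e if isinstance(e, CouplingEdge) else CouplingEdge(*e)
                      for e in self.edges]
        self.pulse_channels = tuple(int(c) for c in self.pulse_channels)
        self.validate()

    def validate(self) -> None:
        if self.n_channels < 1:
            raise SpecValidationError("n_channels: must be >= 1")
        if self.duration <= 0 or self.step <= 0:
            raise SpecValidationError("duration/step: must be positive")
        if self.duration < self.step:
            raise SpecValidationError("duration: shorter than one step")
        for e in self.edges:
            if e.lag_steps < 1:
                raise SpecValidationError(f"edges: lag must be >= 1 step ({e})")
            if e.source == e.target:
                raise SpecValidationError(f"edges: self-edge forbidden ({e})")
            if not (0 <= e.source < self.n_channels and 0 <= e.target < self.n_channels):
                raise SpecValidationError(f"edges: channel index out of range ({e})")
            if e.form not in FORMS:
                raise SpecValidationError(f"edges: unknown form {e.form!r}")
        if self.pulse_channels and not 0 <= self.pulse_onset < self.duration:
            raise SpecValidationError("pulse_onset: must lie in [0, duration)")
        for c in self.pulse_channels:
            if not 0 <= c < self.n_channels:
                raise SpecValidationError(f"pulse_channels: index {c} out of range")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd: must be >= 0")
        if self.driver_sd < 0:
            raise SpecValidationError("driver_sd: must be >= 0")
        if not 0 <= self.driver_phi < 1:
            raise SpecValidationError("driver_phi: must be in [0, 1)")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.step))

    # -- plain config-file round trip -------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["edges"] = [[e.source, e.target, e.lag_steps, e.gain, e.form]
                      for e in self.edges]
        d["pulse_channels"] = list(self.pulse_channels)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CouplingSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["edges"] = [CouplingEdge(int(a), int(b), int(l), float(g), str(f))
                      for a, b, l, g, f in d.get("edges", [])]
        d["pulse_channels"] = tuple(d.get("pulse_channels", ()))
        return cls(**d)


@dataclass
class GroundTruth:
    """True directed edges (with lags in panel steps) and expected synergy triads."""

    edges: set[tuple[int, int, int]]              # (source, target, lag_steps)
    triads: set[tuple[frozenset, int]]            # ({source1, source2}, target)


def default_mz_labels(n: int) -> list[float]:
    """Synthetic m/z labels at 3-decimal precision, spaced 2 Th apart."""
    return [round(31.018 + 2.0 * i, 3) for i in range(n)]


def _pulse(t: np.ndarray, spec: CouplingSpec) -> np.ndarray:
    """Difference-of-exponentials wet-up pulse, peak-normalized to amplitude."""
    dt = t - spec.pulse_onset
    rise, decay = spec.pulse_rise, spec.pulse_decay
    shape = np.where(dt >= 0,
                     np.exp(-np.maximum(dt, 0) / decay)
                     - np.exp(-np.maximum(dt, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise) if decay != rise \
        else rise
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return spec.pulse_amplitude * shape / peak


def _apply_form(u: np.ndarray, form: str, sigma: float) -> np.ndarray:
    """Coupling response to the source deviation ``u``; scaled to keep
    magnitudes comparable across forms (``sigma`` = nominal driver sd)."""
    if form == "linear":
        return u
    if form == "quadratic":
        s = sigma if sigma > 0 else 1.0
        return u * u / s
    if form == "threshold":
        s = sigma if sigma > 0 else 1.0
        return s * (u > s)
    raise SpecValidationError(f"unknown form {form!r}")


def generate_clean_panel(spec: CouplingSpec) -> FluxPanel:
    """Simulate the clean (already normalized, gap-free) flux panel.

    Deterministic given ``spec.seed``; channels are labelled with
    synthetic m/z values and the panel's wet-up time is the pulse onset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_steps, spec.n_channels
    t = np.arange(n) * spec.step

    sigma = spec.driver_sd * spec.baseline
    drivers = np.zeros((k, n))
    if sigma > 0:
        innov_sd = sigma * np.sqrt(1.0 - spec.driver_phi ** 2)
        eps = rng.normal(0.0, innov_sd, size=(k, n))
        drivers[:, 0] = rng.normal(0.0, sigma, size=k)
        for i in range(1, n):
            drivers[:, i] = spec.driver_phi * drivers[:, i - 1] + eps[:, i]

    pulse = _pulse(t, spec)
    incoming: dict[int, list[CouplingEdge]] = {}
    for e in spec.edges:
        incoming.setdefault(e.target, []).append(e)

    # latent signal built forward in time (all lags >= 1 step)
    latent = np.empty((k, n))
    base = spec.baseline + spec.drift * t  # same baseline for every channel
    for i in range(n):
        for c in range(k):
            v = base[i] + drivers[c, i]
            if c in spec.pulse_channels:
                v += pulse[i]
            for e in incoming.get(c, []):
                if i - e.lag_steps >= 0:
                    u = latent[e.source, i - e.lag_steps] - base[i - e.lag_steps]
                    v += _apply_form(e.gain * u, e.form, sigma)
            latent[c, i] = v

    noise = rng.normal(0.0, spec.noise_sd * spec.baseline, size=(k, n)) \
        if spec.noise_sd > 0 else 0.0
    values = latent + noise

    df = pd.DataFrame(values.T, index=t, columns=default_mz_labels(k))
    wetup = spec.pulse_onset if spec.pulse_channels else None
    return FluxPanel(df, wetup_time=wetup)


REFERENCE_MZ = 21.0
N_REPLICATES = 5
SLOT_MINUTES = 10.0
CYCLE_MINUTES = 60.0


def generate_raw_counts(panel: FluxPanel, spec: CouplingSpec,
                        background: float = 2.0,
                        reference_cps: float = 5000.0,
                        replicate_noise_sd: float = 0.05,
                        masked: bool = True) -> tuple[list[IonCountMatrix],
                                                      IonCountMatrix]:
    """Re-express a clean panel as raw multiplexed ion counts.

    Returns ``(replicates, blank)``: five soil-jar matrices plus one
    blank-jar matrix, each with a primary-ion reference channel at
    m/z 21 and timestamps in seconds. Counts are
    ``(panel + background) * reference / 500`` with per-cell log-normal
    replicate noise; the blank carries the background process only. With
    ``masked=True`` each jar is observed only during its 10-min slot of
    every 60-min rotation cycle (replicates take slots 0-4, blank slot 5).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7001]))
    t_min = panel.times
    t_sec = t_min * 60.0
    values = panel.data.to_numpy(dtype=float)  # (time, channel)
    scale = reference_cps / 500.0

    def _noisy(arr: np.ndarray) -> np.ndarray:
        # ion counters report non-negative values: clip before scaling
        arr = np.maximum(arr, 0.0)
        if replicate_noise_sd <= 0:
            return arr.copy()
        ln_sd = np.sqrt(np.log(1.0 + replicate_noise_sd ** 2))
        factors = rng.lognormal(-ln_sd ** 2 / 2.0, ln_sd, size=arr.shape)
        return arr * factors

    def _slot_mask(slot: int) -> np.ndarray:
        within = np.mod(t_min, CYCLE_MINUTES)
        return (within >= slot * SLOT_MINUTES) & (within < (slot + 1) * SLOT_MINUTES)

    columns = list(panel.channels) + [REFERENCE_MZ]
    replicates = []
    for r in range(N_REPLICATES):
        counts = _noisy((values + background) * scale)
        ref = _noisy(np.full((len(t_min), 1), reference_cps))
        mat = np.hstack([counts, ref])
        if masked:
            mat = np.where(_slot_mask(r)[:, None], mat, np.nan)
        df = pd.DataFrame(mat, index=t_sec, columns=columns)
        replicates.append(IonCountMatrix(df, chamber_id=f"jar{r + 1}"))

    blank_counts = _noisy(np.full_like(values, background) * scale)
    blank_ref = _noisy(np.full((len(t_min), 1), reference_cps))
    blank_mat = np.hstack([blank_counts, blank_ref])
    if masked:
        blank_mat = np.where(_slot_mask(N_REPLICATES)[:, None], blank_mat, np.nan)
    blank = IonCountMatrix(pd.DataFrame(blank_mat, index=t_sec, columns=columns),
                           chamber_id="blank")
    return replicates, blank


def ground_truth(spec: CouplingSpec) -> GroundTruth:
    """True edge/lag list plus triads expected to show synergy.

    A synergy triad is any pair of sources converging on one target.
    """
    spec.validate()
    edges = {(e.source, e.target, e.lag_steps) for e in spec.edges}
    by_target: dict[int, set[int]] = {}
    for s, t, _ in edges:
        by_target.setdefault(t, set()).add(s)
    triads = set()
    for t, sources in by_target.items():
        srcs = sorted(sources)
        for i in range(len(srcs)):
            for j in range(i + 1, len(srcs)):
                triads.add((frozenset({srcs[i], srcs[j]}), t))
    return GroundTruth(edges=edges, triads=triads)
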