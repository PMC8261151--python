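"""Inferred-network assembly: the model/results surface over the
information-partitioning core.

``VolatileNetworkModel`` wraps a flux panel together with the lag grid
and surrogate configuration; ``fit()`` scans every ordered channel pair
for significant lagged mutual information, selects each retained pair's
best synergy partner, and returns a ``NetworkResults`` with the directed
unique-information (U) connections and synergy (S) triads, plus the
top-fraction filter used before pathway projection.

Randomness: the fit seed feeds per-pair substreams
(``SeedSequence([seed, i, j])``), so p-values do not depend on scan
order and the scan could be parallelized without changing results.
Redundant information (R) is computed inside every decomposition but is
never reported as network edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .information import (LagGrid, LaggedMIResult, PIDResult, SurrogateConfig,
                          lagged_mi, pid_decompose)
from .panel import FluxPanel

__all__ = ["VolatileNetworkModel", "NetworkResults", "DirectedConnection",
           "SynergyTriad", "build_u_network", "select_top_fraction",
           "best_synergy_partner"]


@dataclass
class DirectedConnection:
    source: float
    target: float
    best_lag: float          # minutes
    mi: float                # bits at the best lag
    unique: float            # U bits (vs the best synergy partner)
    p_value: float
    phase: str = "all"
    partner: float | None = None


@dataclass
class SynergyTriad:
    source1: float
    source2: float           # the selected partner
    target: float
    synergy: float           # S bits
    lag1: float
    lag2: float
    phase: str = "all"


# ---------------------------------------------------------------------------
# module-level operations (also used by the model)


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(i), int(j)]))


def scan_pairs(panel: FluxPanel, grid: LagGrid, surr: SurrogateConfig,
               seed: int) -> dict[tuple[float, float], LaggedMIResult]:
    """Lagged-MI scan with surrogate p-values over every ordered pair."""
    channels = panel.channels
    out: dict[tuple[float, float], LaggedMIResult] = {}
    for i, s in enumerate(channels):
        for j, t in enumerate(channels):
            if i == j:
                continue
            rng = _pair_rng(seed, i, j)
            out[(s, t)] = lagged_mi(panel, s, t, grid, surr=surr, rng=rng)
    return out


def best_synergy_partner(connection: DirectedConnection, panel: FluxPanel,
                         scan: dict[tuple[float, float], LaggedMIResult],
                         surr: SurrogateConfig | None = None,
                         redundancy: str = "rescaled"
                         ) -> tuple[SynergyTriad | None, PIDResult | None]:
    """Pick the candidate second source with the highest synergy.

    Every channel other than the connection's source and target is a
    candidate; each enters at its own best pairwise lag to the target
    (taken from the scan). Returns ``(None, None)`` when no candidate
    yields S > 0 (logged by the caller). Ties break toward the smaller
    candidate m/z.
    """
    s, t = connection.source, connection.target
    candidates = [c for c in panel.channels if c not in (s, t)]
    best: PIDResult | None = None
    for c in sorted(candidates):
        lag_c = scan[(c, t)].best_lag
        pid = pid_decompose(panel, (s, connection.best_lag), (c, lag_c), t,
                            surr=None, redundancy=redundancy)
        if best is None or pid.synergistic > best.synergistic:
            best = pid
    if best is None or best.synergistic <= 0:
        return None, best
    triad = SynergyTriad(source1=s, source2=best.source2, target=t,
                         synergy=best.synergistic,
                         lag1=best.lag1, lag2=best.lag2,
                         phase=connection.phase)
    return triad, best


def build_u_network(panel: FluxPanel, grid: LagGrid | None = None,
                    surr: SurrogateConfig | None = None,
                    seed: int = 0, phase: str = "all",
                    redundancy: str = "rescaled",
                    ) -> tuple[list[DirectedConnection], list[SynergyTriad], dict]:
    """Significant directed connections plus each one's best synergy triad.

    Every ordered channel pair is tested; pairs with surrogate
    ``p <= alpha`` are retained. Each retained pair's U is the unique
    component of the two-source decomposition that includes its best
    synergy partner (U is only defined relative to a second source); on
    a 2-channel panel U falls back to the pairwise MI at the best lag.
    """
    grid = grid or LagGrid()
    surr = surr or SurrogateConfig()
    channels = panel.channels
    log = {"pairs_evaluated": 0, "pairs_retained": 0, "triads_omitted": 0}
    if len(channels) < 2:
        return [], [], log

    scan = scan_pairs(panel, grid, surr, seed)
    log["pairs_evaluated"] = len(scan)

    connections: list[DirectedConnection] = []
    triads: list[SynergyTriad] = []
    for (s, t), res in scan.items():
        if res.p_value is None or res.p_value > surr.alpha:
            continue
        conn = DirectedConnection(source=s, target=t, best_lag=res.best_lag,
                                  mi=res.mi_at_best, unique=res.mi_at_best,
                                  p_value=res.p_value, phase=phase)
        if len(channels) >= 3:
            triad, pid = best_synergy_partner(conn, panel, scan,
                                              redundancy=redundancy)
            if pid is not None:
                conn.unique = pid.unique1
                conn.partner = pid.source2
            if triad is not None:
                triads.append(triad)
            else:
                log["triads_omitted"] += 1
        connections.append(conn)
    log["pairs_retained"] = len(connections)
    return connections, triads, log


def select_top_fraction(connections: list[DirectedConnection],
                        fraction: float = 0.2,
                        rank_by: str = "unique") -> list[DirectedConnection]:
    """Keep the strongest ``fraction`` of connections (default top 20%).

    Sorted by the ranking quantity descending, ties broken by source then
    target m/z ascending (stable and order-independent); retains
    ``floor(fraction * n)``, minimum 1 when the input is nonempty.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if rank_by not in ("unique", "mi"):
        raise ValueError("rank_by must be 'unique' or 'mi'")
    if not connections:
        return []
    key = (lambda c: (-c.unique, c.source, c.target)) if rank_by == "unique" \
        else (lambda c: (-c.mi, c.source, c.target))
    ranked = sorted(connections, key=key)
    keep = max(1, int(np.floor(fraction * len(ranked))))
    return ranked[:keep]


# ---------------------------------------------------------------------------
# model / results


class VolatileNetworkModel:
    """Directed metabolic-connection model for a flux panel.

    Parameters
    ----------
    panel
        Processed flux panel (regular grid, no gaps in the analysed
        stretch).
    lag_grid
        Lag search grid; defaults to 5-100 min at the panel step.
    surrogate
        Shuffled-surrogate configuration (2500 shuffles, alpha 0.05 by
        default).
    phase
        ``"dry"``, ``"wet"`` or ``None`` for the whole panel. Phases are
        analysed separately because wet-up restructures the couplings.
    redundancy
        Redundancy estimator for the PID: ``"rescaled"`` (default),
        ``"minimum"`` or ``"mmi"``.
    rank_by
        Quantity the top-fraction filter ranks on: ``"unique"``
        (default) or ``"mi"``.
    """

    def __init__(self, panel: FluxPanel, lag_grid: LagGrid | None = None,
                 surrogate: SurrogateConfig | None = None,
                 phase: str | None = None,
                 redundancy: str = "rescaled",
                 rank_by: str = "unique"):
        self.full_panel = panel
        self.phase = phase
        self.panel = panel.select_phase(phase)
        self.lag_grid = lag_grid or LagGrid(step=self.panel.step,
                                            min_lag=self.panel.step,
                                            max_lag=min(100.0, self.panel.step * 20))
        self.surrogate = surrogate or SurrogateConfig()
        self.redundancy = redundancy
        self.rank_by = rank_by

    def fit(self, seed: int = 0) -> "NetworkResults":
        connections, triads, log = build_u_network(
            self.panel, self.lag_grid, self.surrogate, seed=seed,
            phase=self.phase or "all", redundancy=self.redundancy)
        return NetworkResults(self, connections, triads, log, seed)


@dataclass
class NetworkResults:
    """Fitted network: retained connections, triads and diagnostics."""

    model: VolatileNetworkModel
    connections_: list[DirectedConnection]
    triads_: list[SynergyTriad]
    log: dict
    seed: int

    @property
    def connections(self) -> pd.DataFrame:
        rows = [{"source": c.source, "target": c.target,
                 "best_lag_min": c.best_lag, "mi_bits": c.mi,
                 "U_bits": c.unique, "p_value": c.p_value,
                 "partner": c.partner, "phase": c.phase}
                for c in self.connections_]
        df = pd.DataFrame(rows, columns=["source", "target", "best_lag_min",
                                         "mi_bits", "U_bits", "p_value",
                                         "partner", "phase"])
        return df.sort_values(["U_bits", "source", "target"],
                              ascending=[False, True, True],
                              ignore_index=True) if len(df) else df

    @property
    def triads(self) -> pd.DataFrame:
        rows = [{"source1": t.source1, "source2": t.source2, "target": t.target,
                 "S_bits": t.synergy, "lag1_min": t.lag1, "lag2_min": t.lag2,
                 "phase": t.phase}
                for t in self.triads_]
        df = pd.DataFrame(rows, columns=["source1", "source2", "target",
                                         "S_bits", "lag1_min", "lag2_min",
                                         "phase"])
        return df.sort_values(["S_bits", "source1", "target"],
                              ascending=[False, True, True],
                              ignore_index=True) if len(df) else df

    def top_fraction(self, fraction: float = 0.2) -> list[DirectedConnection]:
        """The top-20%-style filter applied to the retained connections."""
        return select_top_fraction(self.connections_, fraction,
                                   rank_by=self.model.rank_by)

    def top_triads(self, fraction: float = 0.2) -> list[SynergyTriad]:
        """Best synergy triad of each top-fraction connection."""
        kept = {(c.source, c.target) for c in self.top_fraction(fraction)}
        return [t for t in self.triads_ if (t.source1, t.target) in kept]

    def summary(self) -> str:
        p = self.model.panel
        lines = [
            "Volatile-compound connection network",
            "=" * 52,
            f"Phase:                {self.model.phase or 'all'}",
            f"Channels:             {len(p.channels)}",
            f"Timepoints:           {p.n_times} ({p.step:g}-min step)",
            f"Lag grid:             {self.model.lag_grid.min_lag:g}-"
            f"{self.model.lag_grid.max_lag:g} min",
            f"Surrogates:           {self.model.surrogate.n_shuffles} "
            f"(alpha={self.model.surrogate.alpha:g}, seed={self.seed})",
            f"Ordered pairs tested: {self.log['pairs_evaluated']}",
            f"Connections retained: {self.log['pairs_retained']}",
            f"Synergy triads:       {len(self.triads_)}",
            "-" * 52,
        ]
        df = self.connections
        if len(df):
            lines.append(f"{'source':>8} {'target':>8} {'lag(min)':>9} "
                         f"{'U(bits)':>9} {'p':>9}")
            for _, r in df.head(15).iterrows():
                lines.append(f"{r['source']:8.3f} {r['target']:8.3f} "
                             f"{r['best_lag_min']:9.0f} {r['U_bits']:9.4f} "
                             f"{r['p_value']:9.4g}")
            if len(df) > 15:
                lines.append(f"... {len(df) - 15} more")
        else:
            lines.append("(no significant connections)")
        return "\n".join(lines)

    def plot(self, ax=None, fraction: float | None = None):
        """Draw the inferred directed network (node labels = m/z)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        conns = self.connections_ if fraction is None else self.top_fraction(fraction)
        g = nx.DiGraph()
        for c in conns:
            g.add_edge(f"{c.source:.3f}", f"{c.target:.3f}", weight=c.unique)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        if g.number_of_nodes() == 0:
            ax.set_axis_off()
            ax.set_title("no significant connections")
            return ax
        pos = nx.circular_layout(g)
        widths = [1 + 4 * d["weight"] for _, _, d in g.edges(data=True)]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color="#c6dbef",
                         width=widths, arrows=True, font_size=8)
        ax.set_axis_off()
        return ax

    def save(self, connections_path, triads_path, sep: str = "\t") -> None:
        """Write connection and triad tables with a config header comment."""
        header = (f"# seed={self.seed} alpha={self.model.surrogate.alpha} "
                  f"n_shuffles={self.model.surrogate.n_shuffles} "
                  f"lag={self.model.lag_grid.min_lag}-"
                  f"{self.model.lag_grid.max_lag}min "
                  f"redundancy={self.model.redundancy}\n")
        for path, df in ((connections_path, self.connections),
                         (triads_path, self.triads)):
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep=sep, index=False)
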