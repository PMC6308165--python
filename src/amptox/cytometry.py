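"""Annexin V / propidium iodide quadrant analysis of flow-cytometry events.

Double staining separates cells into four quadrants: viable (AV- PI-),
early apoptotic (AV+ PI-), late apoptotic / necrotic (AV+ PI+), and the
rarely populated AV- PI+ class (kept as its own category rather than merged
into the necrotic count).  Positivity is a strict threshold comparison per
channel; events exactly on a gate are called negative so that the
classification is deterministic.

On top of the per-condition quadrant fractions, two study-level readouts
are derived:

* a death-mode signature over a (concentration x time) panel — membrane-
  lytic (necrosis-like) killing saturates within the first time point and
  scales with dose, whereas apoptotic killing accumulates with time;
* a caspase-independence comparison of the dead fraction with and without
  a pan-caspase inhibitor (Z-VAD-FMK).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuadrantGates",
    "QuadrantFractions",
    "KineticsPanel",
    "DeathMode",
    "classify_events",
    "trypan_dead_fraction",
    "death_mode_signature",
    "caspase_independence",
]

_QUADRANTS = ("viable", "early_apoptotic", "late_apoptotic_necrotic", "av_neg_pi_pos")


@dataclass(frozen=True)
class QuadrantGates:
    """Per-channel positivity thresholds (arbitrary fluorescence units)."""

    av_threshold: float
    pi_threshold: float

    def __post_init__(self) -> None:
        if self.av_threshold <= 0 or self.pi_threshold <= 0:
            raise ValueError("gate thresholds must be strictly positive")

    @classmethod
    def from_unstained(cls, events: pd.DataFrame, quantile: float = 0.995) -> "QuadrantGates":
        """Set each gate at a high quantile of an unstained-control cloud."""
        return cls(
            av_threshold=float(events["av"].quantile(quantile)),
            pi_threshold=float(events["pi"].quantile(quantile)),
        )


@dataclass(frozen=True)
class QuadrantFractions:
    """Fractions of events per quadrant; always sums to 1."""

    viable: float
    early_apoptotic: float
    late_apoptotic_necrotic: float
    av_neg_pi_pos: float
    n_events: int = 0
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.viable + self.early_apoptotic
                 + self.late_apoptotic_necrotic + self.av_neg_pi_pos)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"quadrant fractions must sum to 1, got {total!r}")
        for name in _QUADRANTS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction {v} outside [0, 1]")

    @property
    def dead(self) -> float:
        """Aggregate dead fraction: complement of the AV- PI- quadrant."""
        return 1.0 - self.viable

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _QUADRANTS}


class DeathMode(enum.Enum):
    NECROSIS_LIKE = "necrosis_like"
    APOPTOSIS_LIKE = "apoptosis_like"
    INCONCLUSIVE = "inconclusive"


def classify_events(events: pd.DataFrame, gates: QuadrantGates) -> QuadrantFractions:
    """Assign each event to one quadrant by strict threshold comparison.

    ``events`` needs columns ``av`` and ``pi``.  Positivity is ``value >
    threshold``; on-gate events count as negative.
    """
    if len(events) == 0:
        raise ValueError("event table is empty")
    av = events["av"].to_numpy(dtype=float)
    pi = events["pi"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(pi))):
        raise ValueError("event intensities must be finite")
    if np.any(av < 0) or np.any(pi < 0):
        raise ValueError("event intensities must be non-negative")
    av_pos = av > gates.av_threshold
    pi_pos = pi > gates.pi_threshold
    n = len(events)
    counts = {
        "viable": int(np.sum(~av_pos & ~pi_pos)),
        "early_apoptotic": int(np.sum(av_pos & ~pi_pos)),
        "late_apoptotic_necrotic": int(np.sum(av_pos & pi_pos)),
        "av_neg_pi_pos": int(np.sum(~av_pos & pi_pos)),
    }
    return QuadrantFractions(
        **{k: c / n for k, c in counts.items()}, n_events=n, counts=counts
    )


def trypan_dead_fraction(stained: int, total: int) -> float:
    """Percent trypan-stained (dead) cells out of the counted total."""
    if total < 1:
        raise ValueError("total count must be at least 1")
    if stained < 0 or stained > total:
        raise ValueError(f"stained count {stained} outside [0, {total}]")
    return 100.0 * stained / total


@dataclass
class KineticsPanel:
    """Quadrant fractions on a (concentration, time) grid, optional inhibitor arm.

    ``fractions`` maps ``(concentration_uM, time_h)`` to QuadrantFractions
    for the uninhibited arm; ``inhibited`` holds the Z-VAD-FMK arm on the
    same keys where measured.
    """

    fractions: dict[tuple[float, float], QuadrantFractions]
    inhibited: dict[tuple[float, float], QuadrantFractions] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.concentrations) < 2 or len(self.times) < 2:
            raise ValueError("panel needs >= 2 concentrations and >= 2 time points")

    @property
    def concentrations(self) -> list[float]:
        return sorted({c for c, _ in self.fractions})

    @property
    def times(self) -> list[float]:
        return sorted({t for _, t in self.fractions})

    def dead_percent(self, concentration: float, time: float) -> float:
        return 100.0 * self.fractions[(concentration, time)].dead

    def dead_table(self) -> pd.DataFrame:
        """Dead percentage as a concentration x time table (rows = concentration)."""
        return pd.DataFrame(
            {t: [self.dead_percent(c, t) for c in self.concentrations] for t in self.times},
            index=self.concentrations,
        )

    @classmethod
    def from_dead_percent(cls, table: dict[tuple[float, float], float]) -> "KineticsPanel":
        """Build a panel directly from dead percentages (AV+/PI+ composition unknown)."""
        fr = {}
        for key, dead in table.items():
            d = dead / 100.0
            fr[key] = QuadrantFractions(
                viable=1.0 - d, early_apoptotic=0.0,
                late_apoptotic_necrotic=d, av_neg_pi_pos=0.0,
            )
        return cls(fractions=fr)


def death_mode_signature(panel: KineticsPanel, time_tol: float = 10.0,
                         conc_min_effect: float = 20.0) -> DeathMode:
    """Classify the kinetic pattern of killing over a concentration x time panel.

    necrosis-like: at every concentration the dead fraction is flat in time
    (range <= ``time_tol`` points) while, at some fixed time, it spreads by
    at least ``conc_min_effect`` points across concentrations — killing is
    immediate and dose-limited.  apoptosis-like: the dead fraction rises
    monotonically with time by more than ``time_tol`` points at some
    concentration.  Anything else is inconclusive.
    """
    table = panel.dead_table()  # rows: concentration, cols: time (sorted)
    time_range_per_conc = table.max(axis=1) - table.min(axis=1)
    conc_range_per_time = table.max(axis=0) - table.min(axis=0)

    flat_in_time = bool((time_range_per_conc <= time_tol).all())
    dose_effect = bool((conc_range_per_time >= conc_min_effect).any())
    if flat_in_time and dose_effect:
        return DeathMode.NECROSIS_LIKE

    for _, row in table.iterrows():
        vals = row.to_numpy()
        if np.all(np.diff(vals) >= 0) and (vals[-1] - vals[0]) > time_tol:
            return DeathMode.APOPTOSIS_LIKE
    return DeathMode.INCONCLUSIVE


def caspase_independence(with_inhibitor: QuadrantFractions, without: QuadrantFractions,
                         tol: float = 5.0) -> tuple[bool, float]:
    """Compare dead fractions with/without a pan-caspase inhibitor.

    Returns ``(independent, delta_points)`` where ``delta_points`` is the
    absolute change in the dead percentage and ``independent`` means the
    killing is unaffected within ``tol`` percentage points — the signature
    of caspase-independent (necrotic) death.
    """
    delta = abs(without.dead - with_inhibitor.dead) * 100.0
    return delta <= tol, delta


def panel_from_events(events: pd.DataFrame, gates: QuadrantGates) -> KineticsPanel:
    """Build a KineticsPanel from a tidy event table.

    Expects columns ``av``, ``pi``, ``concentration_uM``, ``time_h`` and
    optionally ``inhibitor`` (values ``none`` / ``zvadfmk``).
    """
    inhib_col = events["inhibitor"] if "inhibitor" in events.columns else pd.Series("none", index=events.index)
    fractions: dict[tuple[float, float], QuadrantFractions] = {}
    inhibited: dict[tuple[float, float], QuadrantFractions] = {}
    for (conc, time, inhib), sub in events.groupby(
            [events["concentration_uM"], events["time_h"], inhib_col]):
        target = inhibited if inhib == "zvadfmk" else fractions
        target[(float(conc), float(time))] = classify_events(sub, gates)
    return KineticsPanel(fractions=fractions, inhibited=inhibited)
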