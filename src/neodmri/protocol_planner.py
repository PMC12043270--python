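"""Protocol feasibility calculus and acquisition scheduling.

Feasibility over the MB x R acceleration grid rests on a minimal slice-block
timing model: each excited slice block costs ``TE + half echo train +
overhead`` milliseconds, the overhead being calibrated once from a reference
protocol whose TR is known.  The per-volume scan time is ``TR x n_segments``
(one TR per readout segment), and a session budget caps the admissible TR.

Scheduling splits each b-shell's direction set into subsets small enough to
keep the gradients from running at a high duty cycle continuously, and
interleaves low/mid-b subsets with the high-b subsets so that no two high-b
subsets are played back to back.  Each subset opens with a forward-PE b=0
volume and a small block of reversed-PE b=0 volumes closes the session (for
susceptibility-distortion correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epi_geometry import AcquisitionGeometry, echo_train
from .gradients import ShellScheme, direction_set

__all__ = [
    "ProtocolCandidate",
    "ScheduleEntry",
    "AcquisitionSchedule",
    "per_volume_budget",
    "tr_budget",
    "calibrate_overhead",
    "min_tr",
    "sar_fraction",
    "enumerate_grid",
    "partition_shell",
    "interleave",
    "build_schedule",
    "direction_set",
]

#: Default shell design: directions per b-value (s/mm2).
DEFAULT_SHELLS = {3000.0: 64, 6000.0: 88, 9000.0: 128}
DEFAULT_B0_FORWARD = 17
DEFAULT_B0_REVERSED = 4


@dataclass(frozen=True)
class ProtocolCandidate:
    """One point of the acceleration grid with its derived feasibility."""

    MB: int
    R: int
    b_max: float
    TE_ms: float
    n_segments: int
    min_tr_s: float
    per_volume_s: float
    sar_fraction: float | None
    feasible: bool
    exclusion_reason: str | None


def per_volume_budget(session_s: float, n_volumes: int) -> int:
    """Largest whole-second per-volume time fitting n_volumes in session_s."""
    if session_s <= 0 or n_volumes <= 0:
        raise ValueError("session length and volume count must be positive")
    return int(math.floor(session_s / n_volumes))


def tr_budget(per_volume_s: float, n_segments: int) -> tuple[int, float]:
    """Maximum TR given a per-volume budget split over readout segments.

    Returns ``(nearest whole second, unrounded seconds)``.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    exact = per_volume_s / n_segments
    return int(round(exact)), exact


def _slice_blocks(n_slices: int, MB: int) -> int:
    return math.ceil(n_slices / MB)


def calibrate_overhead(tr_s: float, te_ms: float, geom: AcquisitionGeometry) -> float:
    """Per-slice-block overhead (ms) implied by a reference protocol.

    ``overhead = TR / ceil(n_slices/MB) - TE - echo_train_duration/2`` using
    the reference geometry's MB and R.  The overhead is assumed MB- and
    R-independent thereafter.
    """
    blocks = _slice_blocks(geom.n_slices, geom.MB)
    half_train = echo_train(geom).duration_ms / 2.0
    overhead = tr_s * 1000.0 / blocks - te_ms - half_train
    if overhead <= 0:
        raise ValueError(
            f"timing model inconsistent: non-positive overhead {overhead:.2f} ms"
        )
    return overhead


def min_tr(MB: int, R: int, geom: AcquisitionGeometry, te_ms: float, overhead_ms: float) -> float:
    """Minimum TR (s) for an MB x R protocol under the slice-block model."""
    g = geom.with_acceleration(R=R, MB=MB)
    blocks = _slice_blocks(geom.n_slices, MB)
    half_train = echo_train(g).duration_ms / 2.0
    return blocks * (te_ms + half_train + overhead_ms) / 1000.0


def sar_fraction(MB: int, tr_s: float, energy_per_volume: float) -> float:
    """Fraction of the full SAR limit at a given TR.

    The RF energy deposited per volume is an empirical calibration constant
    (not derivable from printed protocol numbers); time-averaged power, and
    hence the SAR fraction, is ``energy_per_volume / TR`` regardless of MB.
    The 'conservative' operating mode corresponds to a 0.8 cap.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    return energy_per_volume / tr_s


def enumerate_grid(
    MBs,
    Rs,
    geom: AcquisitionGeometry,
    te_ms: float,
    tr_budget_s: float,
    overhead_ms: float,
    b_max: float = 9000.0,
    energy_per_volume: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Feasibility table over the MB x R grid.

    A protocol is excluded when its minimum TR exceeds the TR budget
    (exclusion counting follows the volume-count logic only; the SAR
    fraction, if an energy calibration is supplied, is reported but not
    used for exclusion).  Returns the table and the excluded count.
    """
    rows = []
    for mb in MBs:
        for r in Rs:
            tr = min_tr(mb, r, geom, te_ms, overhead_ms)
            sar = sar_fraction(mb, tr, energy_per_volume) if energy_per_volume else None
            feasible = tr <= tr_budget_s
            reason = None if feasible else (
                f"min TR {tr:.2f}s exceeds budget {tr_budget_s:.2f}s"
            )
            rows.append(
                ProtocolCandidate(
                    MB=mb, R=r, b_max=b_max, TE_ms=te_ms,
                    n_segments=geom.n_segments, min_tr_s=tr,
                    per_volume_s=tr * geom.n_segments, sar_fraction=sar,
                    feasible=feasible, exclusion_reason=reason,
                )
            )
    table = pd.DataFrame([vars(c) for c in rows])
    return table, int((~table["feasible"]).sum())


def partition_shell(n_dirs: int, max_subset_size: int = 18) -> list[int]:
    """Balanced subset sizes for one shell under a per-subset cap.

    ``ceil(n_dirs / max_subset_size)`` subsets whose sizes differ by at most
    one.  The default cap of 18 splits the (64, 88, 128) direction design
    into (4, 5, 8) subsets.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    count = math.ceil(n_dirs / max_subset_size)
    base, extra = divmod(n_dirs, count)
    return [base + 1] * extra + [base] * (count - extra)


@dataclass(frozen=True)
class ScheduleEntry:
    """One scheduled volume."""

    position: int
    b: float
    direction_index: int | None  # index into the shell's direction set, None for b=0
    subset: int | None  # subset serial number, None for the closing reversed block
    pe_polarity: int  # +1 forward, -1 reversed


@dataclass
class AcquisitionSchedule:
    """Interleaved acquisition order with subset bookkeeping."""

    entries: list[ScheduleEntry]
    subset_b: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_subsets(self) -> int:
        return len(self.subset_b)

    def subset_members(self, subset: int) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.subset == subset]


def interleave(partitions: dict[float, list[int]]) -> list[tuple[float, int]]:
    """Order shell subsets so no two highest-b subsets are adjacent.

    ``partitions`` maps b-value to its list of subset sizes.  Subsets of the
    highest shell alternate with the remaining shells' subsets, the latter
    taken round-robin in ascending b order (duty-cycle balance).  Returns
    ``(b, subset_size)`` pairs.  Raises if the highest shell has more
    subsets than the others can separate.
    """
    if not partitions:
        raise ValueError("no shells to interleave")
    if len(partitions) == 1:
        b, sizes = next(iter(partitions.items()))
        return [(b, s) for s in sizes]
    b_high = max(partitions)
    highs = [(b_high, s) for s in partitions[b_high]]
    low_queues = {b: list(sizes) for b, sizes in sorted(partitions.items()) if b != b_high}
    others: list[tuple[float, int]] = []
    while any(low_queues.values()):
        for b in sorted(low_queues):
            if low_queues[b]:
                others.append((b, low_queues[b].pop(0)))
    if len(highs) > len(others) + 1:
        raise ValueError(
            f"cannot separate {len(highs)} high-b subsets with only "
            f"{len(others)} lower-b subsets"
        )
    ordered: list[tuple[float, int]] = []
    if len(highs) > len(others):
        ordered.append(highs.pop(0))
    while others or highs:
        if others:
            ordered.append(others.pop(0))
        if highs:
            ordered.append(highs.pop(0))
    return ordered


def build_schedule(
    shells: dict[float, int] | None = None,
    max_subset_size: int = 18,
    n_b0_forward: int | None = None,
    n_b0_reversed: int = DEFAULT_B0_REVERSED,
    seed: int = 0,
) -> tuple[AcquisitionSchedule, ShellScheme]:
    """Full session schedule plus the matching gradient table.

    Each interleaved subset opens with one forward-PE b=0 volume (so
    ``n_b0_forward`` defaults to the subset count) and ``n_b0_reversed``
    reversed-PE b=0 volumes close the session.  Directions come from
    seeded electrostatic-repulsion sets, consumed subset by subset.
    """
    shells = dict(DEFAULT_SHELLS) if shells is None else {float(b): n for b, n in shells.items()}
    partitions = {b: partition_shell(n, max_subset_size) for b, n in shells.items()}
    ordered = interleave(partitions)
    if n_b0_forward is not None and n_b0_forward != len(ordered):
        raise ValueError(
            f"one opening b=0 per subset requires {len(ordered)} forward b=0 "
            f"volumes, got {n_b0_forward}"
        )

    dirs = {b: direction_set(n, seed=seed + i) for i, (b, n) in enumerate(sorted(shells.items()))}
    consumed = {b: 0 for b in shells}
    entries: list[ScheduleEntry] = []
    subset_b: list[float] = []
    bvals: list[float] = []
    bvecs: list[np.ndarray] = []
    pos = 0
    for subset_idx, (b, size) in enumerate(ordered):
        subset_b.append(b)
        entries.append(ScheduleEntry(pos, 0.0, None, subset_idx, +1))
        bvals.append(0.0)
        bvecs.append(np.zeros(3))
        pos += 1
        start = consumed[b]
        for j in range(start, start + size):
            entries.append(ScheduleEntry(pos, b, j, subset_idx, +1))
            bvals.append(b)
            bvecs.append(dirs[b][j])
            pos += 1
        consumed[b] += size
    for _ in range(n_b0_reversed):
        entries.append(ScheduleEntry(pos, 0.0, None, None, -1))
        bvals.append(0.0)
        bvecs.append(np.zeros(3))
        pos += 1

    schedule = AcquisitionSchedule(entries=entries, subset_b=subset_b)
    scheme = ShellScheme(np.asarray(bvals), np.vstack(bvecs))
    return schedule, scheme
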