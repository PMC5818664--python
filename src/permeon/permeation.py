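"""Permeation-event detection, pathway classification and conductance.

Two counting modes are provided:

``full_crossing`` (default)
    An event is an ion whose region sequence runs from one bulk through the
    selectivity filter to the opposite bulk (inward: extracellular ->
    intracellular; outward: the reverse).  Region visits shorter than a
    hysteresis dwell are discarded before the state machine runs, which
    suppresses boundary flicker.  Excursions that enter the filter and
    return to the same side are never events.

``coupled_exchange``
    The literal coupled rule: an event is registered when one ion enters
    the filter from one side and another ion leaves the filter to the other
    side within a configurable frame window (outward: cavity -> SF entry
    paired with an SF exit to the extracellular side; inward: the mirror).

Counts convert to current and conductance via I = n e / t and
G = n e / (t |V|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import ChannelSystem, RegionLabel
from .constants import PA_PER_EVENT_PER_US, PS_PER_EVENT_PER_US_MV
from .trajectory import ION_SPECIES, Species, Trajectory

__all__ = [
    "EventRecord",
    "ConductionSummary",
    "detect_events",
    "classify_pathway",
    "classify_pathways",
    "conductance",
    "current",
    "summarize_conduction",
    "events_to_frame",
]

_EXT_SIDE = {
    int(RegionLabel.EXTRACELLULAR_BULK),
    int(RegionLabel.VESTIBULE),
    int(RegionLabel.SIDE_PORTAL),
}
_INT_SIDE = {int(RegionLabel.INTRACELLULAR_BULK), int(RegionLabel.CAVITY)}
_BULKS = {int(RegionLabel.EXTRACELLULAR_BULK), int(RegionLabel.INTRACELLULAR_BULK)}

#: first-shell ion-oxygen coordination cutoffs for S_side attribution, A
S_SIDE_CUTOFF = {"NA": 3.2, "K": 3.6, "RB": 3.8}


@dataclass
class EventRecord:
    """One counted permeation event."""

    ion_id: int
    species: str
    direction: str  # inward | outward
    pathway: str | None  # axial | side | None (not yet classified)
    entry_frame_time: float  # ps, first frame after leaving the origin bulk
    exit_frame_time: float  # ps, first frame in the destination bulk
    entry_region_sequence: list[int] = field(default_factory=list)
    channel_copy: str = ""
    sf_entry_frame: int = -1
    sf_exit_frame: int = -1

    def __post_init__(self) -> None:
        if self.exit_frame_time < self.entry_frame_time:
            raise ValueError("event entry must precede exit")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label sequence as (label, start, end_exclusive)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _filter_flicker(
    runs: list[tuple[int, int, int]], times: np.ndarray, hysteresis_ps: float
) -> list[tuple[int, int, int]]:
    """Drop visits shorter than the hysteresis dwell, then re-merge."""
    if hysteresis_ps <= 0 or len(runs) <= 2:
        return runs
    dt = times[1] - times[0] if times.size > 1 else 0.0
    kept = [
        r
        for k, r in enumerate(runs)
        if k in (0, len(runs) - 1) or (r[2] - r[1]) * dt >= hysteresis_ps
    ]
    merged: list[tuple[int, int, int]] = []
    for r in kept:
        if merged and merged[-1][0] == r[0]:
            merged[-1] = (r[0], merged[-1][1], r[2])
        else:
            merged.append(r)
    return merged


def detect_events(
    trajectory: Trajectory,
    system: ChannelSystem,
    mode: str = "full_crossing",
    species: str | Species | None = None,
    hysteresis_ps: float = 100.0,
    coupling_window_frames: int = 1,
) -> list[EventRecord]:
    """Detect permeation events for all (or one) permeant ion species."""
    if mode not in ("full_crossing", "coupled_exchange"):
        raise ValueError(f"unknown counting mode: {mode!r}")
    sp_col = trajectory.particles["species"].to_numpy()
    if species is not None:
        s = species.value if isinstance(species, Species) else str(species)
        ion_rows = np.flatnonzero(sp_col == s)
    else:
        ion_rows = np.flatnonzero(np.isin(sp_col, [x for x in ION_SPECIES if x != "CL"]))
    if trajectory.n_frames == 0 or ion_rows.size == 0:
        return []
    pos = np.mod(trajectory.positions[:, ion_rows, :], trajectory.box)
    labels, owner = system.region_labels(pos)  # (F, n_ions)
    names = system.names
    ids = trajectory.particles["id"].to_numpy()[ion_rows]
    if mode == "full_crossing":
        return _detect_full_crossing(
            trajectory, labels, owner, names, ids, sp_col[ion_rows], hysteresis_ps
        )
    return _detect_coupled(
        trajectory, labels, owner, names, ids, sp_col[ion_rows], coupling_window_frames
    )


def _detect_full_crossing(
    traj, labels, owner, names, ids, species, hysteresis_ps
) -> list[EventRecord]:
    times = traj.times
    events: list[EventRecord] = []
    for j in range(labels.shape[1]):
        runs = _filter_flicker(_runs(labels[:, j]), times, hysteresis_ps)
        last_bulk: int | None = None
        last_bulk_end = 0
        sf_run: tuple[int, int, int] | None = None
        for lab, s, e in runs:
            if lab == int(RegionLabel.SF):
                sf_run = (lab, s, e)
            if lab not in _BULKS:
                continue
            if (
                last_bulk is not None
                and lab != last_bulk
                and sf_run is not None
                and sf_run[1] >= last_bulk_end
            ):
                direction = (
                    "inward" if last_bulk == int(RegionLabel.EXTRACELLULAR_BULK) else "outward"
                )
                chan = names[int(owner[sf_run[1], j])]
                seq = [int(v) for v in labels[last_bulk_end : s + 1, j]]
                events.append(
                    EventRecord(
                        ion_id=int(ids[j]),
                        species=str(species[j]),
                        direction=direction,
                        pathway=None,
                        entry_frame_time=float(times[last_bulk_end]),
                        exit_frame_time=float(times[s]),
                        entry_region_sequence=seq,
                        channel_copy=chan,
                        sf_entry_frame=sf_run[1],
                        sf_exit_frame=sf_run[2] - 1,
                    )
                )
            last_bulk = lab
            last_bulk_end = e
            sf_run = None
    events.sort(key=lambda ev: (ev.entry_frame_time, ev.ion_id))
    return events


def _detect_coupled(
    traj, labels, owner, names, ids, species, window
) -> list[EventRecord]:
    sf = int(RegionLabel.SF)
    entries = []  # (frame, ion_col, side, channel)
    exits = []
    for j in range(labels.shape[1]):
        lab = labels[:, j]
        for f in np.flatnonzero((lab[1:] == sf) & (lab[:-1] != sf)) + 1:
            prev = int(lab[f - 1])
            side = "ext" if prev in _EXT_SIDE else "int" if prev in _INT_SIDE else None
            if side:
                entries.append((int(f), j, side, names[int(owner[f, j])]))
        for f in np.flatnonzero((lab[:-1] == sf) & (lab[1:] != sf)) + 1:
            nxt = int(lab[f])
            side = "ext" if nxt in _EXT_SIDE else "int" if nxt in _INT_SIDE else None
            if side:
                exits.append((int(f), j, side, names[int(owner[f - 1, j])]))
    entries.sort()
    exits.sort()
    used = [False] * len(exits)
    events: list[EventRecord] = []
    for f_in, j_in, side_in, chan in entries:
        want_out = "int" if side_in == "ext" else "ext"
        for k, (f_out, j_out, side_out, chan_out) in enumerate(exits):
            if used[k] or j_out == j_in or chan_out != chan:
                continue
            if side_out != want_out or abs(f_out - f_in) > window:
                continue
            used[k] = True
            direction = "inward" if side_in == "ext" else "outward"
            f0, f1 = min(f_in, f_out), max(f_in, f_out)
            events.append(
                EventRecord(
                    ion_id=int(ids[j_in]),
                    species=str(species[j_in]),
                    direction=direction,
                    pathway=None,
                    entry_frame_time=float(traj.times[f0]),
                    exit_frame_time=float(traj.times[f1]),
                    entry_region_sequence=[int(v) for v in labels[f0 : f1 + 1, j_in]],
                    channel_copy=chan,
                    sf_entry_frame=f_in,
                    sf_exit_frame=f_out,
                )
            )
            break
    events.sort(key=lambda ev: (ev.entry_frame_time, ev.ion_id))
    return events


def classify_pathway(
    event: EventRecord,
    trajectory: Trajectory,
    system: ChannelSystem,
    cutoffs: dict[str, float] | None = None,
) -> str:
    """Classify one event as 'axial' or 'side'.

    Side entry is recognized when the ion carries the SIDE_PORTAL label
    anywhere in its transit region sequence, or lies within the species'
    coordination cutoff of any S_side atom set of its channel copy during
    the frames bracketing filter entry/exit.
    """
    if int(RegionLabel.SIDE_PORTAL) in event.entry_region_sequence:
        return "side"
    cutoffs = cutoffs or S_SIDE_CUTOFF
    cutoff = cutoffs.get(event.species, 3.6)
    geom = system.channels[event.channel_copy]
    row = trajectory.index_of_id(event.ion_id)
    f0 = max(0, event.sf_entry_frame - 3)
    f1 = min(trajectory.n_frames - 1, max(event.sf_exit_frame, event.sf_entry_frame) + 3)
    if event.sf_entry_frame < 0:
        raise ValueError("event lacks filter-entry frame information")
    atom_rows = []
    for selectors in geom.s_side_atoms.values():
        for sel in selectors:
            atom_rows.extend(
                trajectory.select_atoms(
                    subunit=sel.subunit,
                    residue_number=sel.residue_number,
                    atom_name=sel.atom_name,
                    channel=event.channel_copy,
                )
            )
    if atom_rows:
        atom_rows = np.unique(np.asarray(atom_rows))
        d = trajectory.positions[f0 : f1 + 1, row, None, :] - trajectory.positions[
            f0 : f1 + 1, atom_rows, :
        ]
        d -= trajectory.box * np.round(d / trajectory.box)
        if np.linalg.norm(d, axis=-1).min() <= cutoff:
            return "side"
    return "axial"


def classify_pathways(
    events: list[EventRecord],
    trajectory: Trajectory,
    system: ChannelSystem,
    cutoffs: dict[str, float] | None = None,
) -> list[EventRecord]:
    """Classify every event in place; returns the same list."""
    for ev in events:
        ev.pathway = classify_pathway(ev, trajectory, system, cutoffs)
    return events


def conductance(n_events: int, total_time_us: float, voltage_mv: float) -> float:
    """Simulated conductance G = n e / (t |V|) in pS."""
    if total_time_us <= 0:
        raise ValueError("total_time must be positive")
    if voltage_mv == 0:
        raise ValueError("voltage must be nonzero")
    return n_events * PS_PER_EVENT_PER_US_MV / (total_time_us * abs(voltage_mv))


def current(n_events: int, total_time_us: float) -> float:
    """Companion current I = n e / t in pA."""
    if total_time_us <= 0:
        raise ValueError("total_time must be positive")
    return n_events * PA_PER_EVENT_PER_US / total_time_us


@dataclass
class ConductionSummary:
    """Event counts and derived current/conductance for one species."""

    species: str
    n_inward: int
    n_outward: int
    total_time_us: float
    voltage_mv: float
    current_inward_pa: float
    current_outward_pa: float
    conductance_inward_ps: float
    conductance_outward_ps: float


def summarize_conduction(
    events: list[EventRecord], total_time_us: float, voltage_mv: float
) -> list[ConductionSummary]:
    out = []
    for sp in sorted({ev.species for ev in events}):
        n_in = sum(1 for ev in events if ev.species == sp and ev.direction == "inward")
        n_out = sum(1 for ev in events if ev.species == sp and ev.direction == "outward")
        out.append(
            ConductionSummary(
                species=sp,
                n_inward=n_in,
                n_outward=n_out,
                total_time_us=total_time_us,
                voltage_mv=voltage_mv,
                current_inward_pa=current(n_in, total_time_us),
                current_outward_pa=current(n_out, total_time_us),
                conductance_inward_ps=conductance(n_in, total_time_us, voltage_mv),
                conductance_outward_ps=conductance(n_out, total_time_us, voltage_mv),
            )
        )
    return out


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    """Tabulate events, one row per record."""
    return pd.DataFrame(
        [
            dict(
                ion_id=ev.ion_id,
                species=ev.species,
                direction=ev.direction,
                pathway=ev.pathway or "",
                entry_frame_time=ev.entry_frame_time,
                exit_frame_time=ev.exit_frame_time,
                channel_copy=ev.channel_copy,
            )
            for ev in events
        ],
        columns=[
            "ion_id", "species", "direction", "pathway",
            "entry_frame_time", "exit_frame_time", "channel_copy",
        ],
    )
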