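"""Clamp–DNA polar contacts and phosphate-switching kinetics.

A polar contact is a side-chain nitrogen within a distance cutoff
(default strictly < 4 Å) of a DNA backbone phosphorus.  Basic residues
lining the clamp channel make and break such contacts continuously; a
residue's contact partner can hop between adjacent phosphates on the same
strand, and the dwell-time statistics of those hops characterise how
loosely the DNA is held.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures_io import AtomSelection, Trajectory

__all__ = [
    "SIDECHAIN_N",
    "ContactRecord",
    "SwitchEvent",
    "sidechain_nitrogen_selection",
    "find_polar_contacts",
    "contact_occupancy",
    "switching_events",
    "classify_switching",
]

# Exhaustive side-chain nitrogen set for the standard amino acids.
# Backbone amide N deliberately excluded.
SIDECHAIN_N: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
}


@dataclass(frozen=True)
class ContactRecord:
    frame: int
    residue: tuple[str, str, int]  # (chain_id, residue_name, residue_number)
    donor_atom: str
    phosphate: tuple[str, int]  # (strand chain_id, nucleotide residue_number)
    distance: float


@dataclass(frozen=True)
class SwitchEvent:
    residue: tuple[str, str, int]
    from_phosphate: tuple[str, int]
    to_phosphate: tuple[str, int]
    frame: int  # first frame with the new partner
    dwell: float  # time spent on from_phosphate (ns, or frames if no times)

    @property
    def adjacent(self) -> bool:
        return (
            self.from_phosphate[0] == self.to_phosphate[0]
            and abs(self.from_phosphate[1] - self.to_phosphate[1]) == 1
        )


def sidechain_nitrogen_selection(traj: Trajectory) -> AtomSelection:
    """All side-chain nitrogen atoms of standard residues in the trajectory."""
    idx = [
        i
        for i, a in enumerate(traj.atoms)
        if a.atom_name in SIDECHAIN_N.get(a.residue_name, ())
    ]
    return AtomSelection(indices=np.array(idx, dtype=int), spec="sidechain-N")


def _phosphorus_indices(traj: Trajectory) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(traj.atoms)
        if a.atom_name == "P" or a.element.upper() == "P"
    ]
    return np.array(idx, dtype=int)


def find_polar_contacts(
    traj: Trajectory,
    frame: int,
    donor_selection: AtomSelection | None = None,
    cutoff: float = 4.0,
) -> list[ContactRecord]:
    """All (side-chain N, DNA P) pairs strictly closer than ``cutoff`` Å.

    Every qualifying pair is reported once with its distance; a donor in
    contact with two phosphates yields two records.
    """
    if donor_selection is None:
        donor_selection = sidechain_nitrogen_selection(traj)
    p_idx = _phosphorus_indices(traj)
    if p_idx.size == 0:
        raise ValueError("no DNA phosphates (P atoms) in trajectory")
    if len(donor_selection) == 0:
        warnings.warn("donor selection is empty; no contacts possible", stacklevel=2)
        return []
    d_idx = donor_selection.indices
    D = cdist(traj.coords[frame, d_idx], traj.coords[frame, p_idx])
    out: list[ContactRecord] = []
    for di, pj in zip(*np.nonzero(D < cutoff)):
        don = traj.atoms[d_idx[di]]
        pho = traj.atoms[p_idx[pj]]
        out.append(
            ContactRecord(
                frame=frame,
                residue=(don.chain_id, don.residue_name, don.residue_number),
                donor_atom=don.atom_name,
                phosphate=(pho.chain_id, pho.residue_number),
                distance=float(D[di, pj]),
            )
        )
    return out


def contact_occupancy(
    traj: Trajectory,
    donor_selection: AtomSelection | None = None,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Fraction of frames each (residue, phosphate) pair is in contact.

    A residue–phosphate pair counts as in contact in a frame if *any* of
    the residue's side-chain nitrogens is within the cutoff of that P.
    Sorted by residue then phosphate; fractions in [0, 1].
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        seen = set()
        for rec in find_polar_contacts(traj, f, donor_selection, cutoff):
            seen.add((rec.residue, rec.phosphate))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "chain_id": res[0],
            "residue_name": res[1],
            "residue_number": res[2],
            "strand": pho[0],
            "nucleotide": pho[1],
            "occupancy": c / traj.n_frames,
        }
        for (res, pho), c in counts.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chain_id",
            "residue_name",
            "residue_number",
            "strand",
            "nucleotide",
            "occupancy",
        ],
    )
    return df.sort_values(
        ["chain_id", "residue_number", "strand", "nucleotide"]
    ).reset_index(drop=True)


def _exclusive_partners(
    traj: Trajectory,
    donor_selection: AtomSelection | None,
    cutoff: float,
) -> dict[tuple, list]:
    """Per residue, the per-frame exclusive partner (nearest contacting P).

    Ties broken by lower nucleotide residue_number, then by strand chain id
    lexicographically.  Frames without a contacting phosphate get None.
    """
    partners: dict[tuple, list] = {}
    for f in range(traj.n_frames):
        best: dict[tuple, tuple] = {}
        for rec in find_polar_contacts(traj, f, donor_selection, cutoff):
            cand = (rec.distance, rec.phosphate[1], rec.phosphate[0])
            if rec.residue not in best or cand < best[rec.residue]:
                best[rec.residue] = cand
        for res in set(partners) | set(best):
            partners.setdefault(res, [None] * f)
        for res, lst in partners.items():
            if res in best:
                _, num, strand = best[res]
                lst.append((strand, num))
            else:
                lst.append(None)
    return partners


def switching_events(
    traj: Trajectory,
    donor_selection: AtomSelection | None = None,
    cutoff: float = 4.0,
) -> tuple[list[SwitchEvent], pd.DataFrame]:
    """Partner-change events and per-event dwell times.

    Per residue and frame the exclusive partner is the nearest contacting
    phosphate.  A switch is emitted when the partner changes between
    consecutive frames with both partners defined; dwell is the time span
    of the ended run.  A frame with no partner ends the current run
    silently (no event).  Without per-frame times, dwell is counted in
    frames and flagged in the returned table attrs.
    """
    if traj.times is not None:
        times = traj.times
        time_units = "ns"
    else:
        times = np.arange(traj.n_frames, dtype=float)
        time_units = "frames"
        warnings.warn("trajectory has no times; dwell reported in frames", stacklevel=2)

    def span(start_f: int, end_f: int) -> float:
        # run covering frames [start_f, end_f] inclusive; dwell spans from
        # entering start_f to leaving end_f (one inter-frame step minimum)
        if end_f + 1 < traj.n_frames:
            return float(times[end_f + 1] - times[start_f])
        return float(times[end_f] - times[start_f]) if end_f > start_f else float(
            times[1] - times[0] if traj.n_frames > 1 else 1.0
        )

    events: list[SwitchEvent] = []
    dwell_rows: list[dict] = []
    for res, seq in _exclusive_partners(traj, donor_selection, cutoff).items():
        run_start: int | None = None
        current = None
        for f, p in enumerate(seq):
            if p == current:
                continue
            if current is not None and run_start is not None:
                dwell = span(run_start, f - 1)
                dwell_rows.append(
                    {
                        "chain_id": res[0],
                        "residue_name": res[1],
                        "residue_number": res[2],
                        "phosphate_strand": current[0],
                        "phosphate_number": current[1],
                        "dwell": dwell,
                        "switched": p is not None,
                    }
                )
                if p is not None:
                    ev = SwitchEvent(
                        residue=res,
                        from_phosphate=current,
                        to_phosphate=p,
                        frame=f,
                        dwell=dwell,
                    )
                    events.append(ev)
            current = p
            run_start = f if p is not None else None
        if current is not None and run_start is not None:
            # censored final run: tabulated (switched=False) but no event
            dwell_rows.append(
                {
                    "chain_id": res[0],
                    "residue_name": res[1],
                    "residue_number": res[2],
                    "phosphate_strand": current[0],
                    "phosphate_number": current[1],
                    "dwell": span(run_start, traj.n_frames - 1),
                    "switched": False,
                }
            )
    df = pd.DataFrame(
        dwell_rows,
        columns=[
            "chain_id",
            "residue_name",
            "residue_number",
            "phosphate_strand",
            "phosphate_number",
            "dwell",
            "switched",
        ],
    )
    df.attrs["time_units"] = time_units
    return events, df


def classify_switching(dwell_table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Label each residue {sub-ns, slow, static} from its switch dwells.

    sub-ns: median dwell over *switch* events < threshold and >= 2 events;
    static: no switch events at all; slow: otherwise.
    """
    cols = ["chain_id", "residue_name", "residue_number"]
    if dwell_table.empty:
        return pd.DataFrame(columns=cols + ["n_events", "median_dwell", "label"])
    rows = []
    for res, grp in dwell_table.groupby(cols, sort=True):
        sw = grp[grp["switched"]]
        n_ev = len(sw)
        med = float(sw["dwell"].median()) if n_ev else float("nan")
        if n_ev == 0:
            label = "static"
        elif n_ev >= 2 and med < threshold:
            label = "sub-ns"
        else:
            label = "slow"
        rows.append(dict(zip(cols, res), n_events=n_ev, median_dwell=med, label=label))
    return pd.DataFrame(rows)
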