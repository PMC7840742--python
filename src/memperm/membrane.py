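"""Membrane-architecture descriptors.

Area per lipid (APL), electron density profiles (EDP), acyl-chain order
parameters (S_CD) and leaflet assignment.  All z-resolved quantities assume
the trajectory has been recentered so the bilayer midplane is at z = 0
(:func:`memperm.core_io.recenter_bilayer`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AtomSelection, TimeSeries, Trajectory, ZProfile

log = logging.getLogger(__name__)


def area_per_lipid(traj: Trajectory, n_lipids_per_leaflet: int,
                   ) -> tuple[TimeSeries, float, float]:
    """Per-frame APL = Lx·Ly / N with N the phospholipids in one leaflet.

    Cholesterol (or other sterols) are not counted in N; the caller passes
    the phospholipid count.  Returns the per-frame series plus its mean and
    standard deviation over frames (Å²).
    """
    if n_lipids_per_leaflet < 1:
        raise ValueError("n_lipids_per_leaflet must be >= 1")
    box = traj.require_box()
    apl = box[:, 0] * box[:, 1] / n_lipids_per_leaflet
    series = TimeSeries(traj.times, apl, label="APL [A^2]")
    return series, float(apl.mean()), float(apl.std())


@dataclass
class EDPResult:
    """Electron density profiles per group plus the out-of-range tally."""

    profiles: dict[str, ZProfile]
    overflow: int


def electron_density_profile(traj: Trajectory,
                             selection: AtomSelection | None = None,
                             z_range: tuple[float, float] | None = None,
                             bin_width: float = 1.0,
                             by_group: bool = False,
                             symmetrize: bool = False) -> EDPResult:
    """z-resolved electron density in electrons/Å³.

    Each atom contributes ``Z − q`` electrons (atomic number minus partial
    charge) to the bin containing its z coordinate; per-frame histograms
    are divided by the frame's bin volume Lx·Ly·Δz and averaged over
    frames.  With ``by_group`` the topology's group map splits the profile
    into component profiles (which sum to the total).  Atoms outside
    ``z_range`` are tallied in ``overflow`` and excluded.

    ``symmetrize`` averages the profile with its z-reflection; off by
    default (a well-equilibrated bilayer is symmetric on its own).
    """
    box = traj.require_box()
    top = traj.topology
    if selection is None:
        idx = np.arange(top.n_atoms)
    else:
        idx = selection.indices
    if z_range is None:
        lz = box[:, 2].max()
        z_range = (-lz / 2.0, lz / 2.0)
    lo, hi = z_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dz = edges[1] - edges[0]

    weights = top.atomic_numbers[idx] - top.charges[idx]
    if by_group:
        if top.groups is None:
            raise ValueError("by_group requires a topology group map")
        group_labels = top.groups[idx]
        group_names = [g for g in pd.unique(group_labels) if g]
    else:
        group_names = []

    n_frames = traj.n_frames
    acc = {name: np.zeros((n_frames, n_bins)) for name in ["all", *group_names]}
    overflow = 0
    for f in range(n_frames):
        z = traj.coords[f, idx, 2]
        in_range = (z >= lo) & (z < hi)
        overflow += int(np.sum(~in_range))
        vol = box[f, 0] * box[f, 1] * dz
        hist, _ = np.histogram(z[in_range], bins=edges,
                               weights=weights[in_range])
        acc["all"][f] = hist / vol
        for name in group_names:
            m = in_range & (group_labels == name)
            hist, _ = np.histogram(z[m], bins=edges, weights=weights[m])
            acc[name][f] = hist / vol
    if overflow:
        log.warning("%d atom observations fell outside the EDP z-range "
                    "and were excluded", overflow)

    profiles = {}
    for name, frames in acc.items():
        values = frames.mean(axis=0)
        errors = frames.std(axis=0) / np.sqrt(n_frames)
        if symmetrize:
            values = 0.5 * (values + values[::-1])
            errors = 0.5 * np.sqrt(errors**2 + errors[::-1] ** 2)
        profiles[name] = ZProfile(centers, dz, values, errors, unit="e/A^3")
    return EDPResult(profiles=profiles, overflow=overflow)


@dataclass
class ChainDefinition:
    """Ordered carbon positions of one acyl chain (sn-1 or sn-2).

    ``positions`` runs head-proximal → terminal; each entry is the carbon
    atom name and the names of its attached hydrogens (deuterium stand-ins).
    """

    label: str
    positions: list[tuple[str, list[str]]] = field(default_factory=list)


def order_parameter(traj: Trajectory, chains: list[ChainDefinition],
                    normal: int = 2) -> pd.DataFrame:
    """Acyl-chain order parameter S_CD per carbon position.

    S_CD = ⟨½(3 cos²θ − 1)⟩ with θ the angle between the bilayer normal and
    each C–H bond, averaged over hydrogens, lipids and frames.  The signed
    ensemble average is returned together with its magnitude (the quantity
    conventionally plotted, as in ²H-NMR practice).
    """
    top = traj.topology
    rows = []
    for chain in chains:
        for pos, (cname, hnames) in enumerate(chain.positions, start=1):
            c_idx = np.nonzero(top.names == cname)[0]
            if len(c_idx) == 0:
                raise ValueError(f"chain {chain.label} position {pos}: carbon "
                                 f"{cname!r} not found in topology")
            c_by_res = {top.resids[i]: i for i in c_idx}
            samples = []
            for hname in hnames:
                h_idx = np.nonzero(top.names == hname)[0]
                if len(h_idx) == 0:
                    raise ValueError(f"chain {chain.label} position {pos}: "
                                     f"hydrogen {hname!r} not found in topology")
                for hi in h_idx:
                    rid = top.resids[hi]
                    if rid not in c_by_res:
                        continue
                    ci = c_by_res[rid]
                    vec = traj.coords[:, hi, :] - traj.coords[:, ci, :]
                    norm = np.linalg.norm(vec, axis=1)
                    if np.any(norm == 0):
                        raise ValueError(f"coincident C/H atoms for {cname}/{hname}")
                    cos2 = (vec[:, normal] / norm) ** 2
                    samples.append(0.5 * (3.0 * cos2 - 1.0))
            if not samples:
                raise ValueError(f"chain {chain.label} position {pos}: no "
                                 f"resolvable C–H pairs")
            s = float(np.mean(np.concatenate(samples)))
            rows.append({"chain": chain.label, "position": pos,
                         "carbon": cname, "s_cd": s, "abs_s_cd": abs(s)})
    return pd.DataFrame(rows)


def assign_leaflets(traj: Trajectory, phosphate_sel: AtomSelection,
                    frame: int = 0) -> tuple[dict[int, str], dict[str, int]]:
    """Assign each lipid (by residue id of its phosphate) to a leaflet.

    A lipid is *upper* if its phosphate z > 0 in the given (recentered)
    frame, else *lower*; z exactly 0 goes upper with a warning.  Returns
    the per-lipid labels and the leaflet counts.
    """
    if len(phosphate_sel) == 0:
        raise ValueError("phosphate selection is empty")
    top = traj.topology
    z = traj.coords[frame, phosphate_sel.indices, 2]
    labels: dict[int, str] = {}
    for i, zi in zip(phosphate_sel.indices, z):
        if zi == 0.0:
            log.warning("phosphate of residue %d exactly at z=0; assigned upper",
                        top.resids[i])
        labels[int(top.resids[i])] = "upper" if zi >= 0 else "lower"
    counts = {"upper": sum(1 for v in labels.values() if v == "upper"),
              "lower": sum(1 for v in labels.values() if v == "lower")}
    return labels, counts
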