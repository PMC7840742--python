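"""Permeant-centric analyses.

Tilt angle of the permeant's molecular axis, insertion depth relative to
the phosphate layer, first-hydration-shell water counts, geometric
hydrogen-bond detection and run-length lifetimes, radial distribution
functions, and the fraction of native permeant–lipid contacts Q(t).

Distances are minimum-image in x and y (the bilayer is laterally periodic)
and direct in z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import GetPeriodicTable

from .core_io import AtomSelection, TimeSeries, Topology, Trajectory, ZProfile

log = logging.getLogger(__name__)

_PT = GetPeriodicTable()


def atom_masses(topology: Topology) -> np.ndarray:
    """Standard atomic masses (g/mol) per atom."""
    return np.array([_PT.GetAtomicWeight(int(z))
                     for z in topology.atomic_numbers])


def center_of_mass(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    """(n_frames, 3) mass-weighted centroid of a selection."""
    if len(sel) == 0:
        raise ValueError("selection is empty")
    m = atom_masses(traj.topology)[sel.indices]
    return (traj.coords[:, sel.indices, :] * m[None, :, None]).sum(axis=1) / m.sum()


def _min_image_xy(disp: np.ndarray, box_xy: np.ndarray | None) -> np.ndarray:
    if box_xy is not None:
        for d in (0, 1):
            disp[..., d] -= box_xy[d] * np.round(disp[..., d] / box_xy[d])
    return disp


# ---------------------------------------------------------------------------
# orientation and depth
# ---------------------------------------------------------------------------


def tilt_angle(traj: Trajectory, head_atom: int, tail_atom: int,
               normal: int = 2, bins: int = 36,
               ) -> tuple[TimeSeries, np.ndarray, np.ndarray]:
    """Tilt of the permeant axis (tail→head vector) versus the +z normal.

    Returns the per-frame angle series (degrees, in [0, 180]) plus a
    normalized histogram and its bin edges.
    """
    if head_atom == tail_atom:
        raise ValueError("head and tail atoms must differ")
    vec = traj.coords[:, head_atom, :] - traj.coords[:, tail_atom, :]
    norm = np.linalg.norm(vec, axis=1)
    bad = np.nonzero(norm == 0)[0]
    if len(bad):
        raise ValueError(f"head and tail atoms coincide in frame {bad[0]}")
    theta = np.degrees(np.arccos(np.clip(vec[:, normal] / norm, -1.0, 1.0)))
    series = TimeSeries(traj.times, theta, label="tilt [deg]")
    hist, edges = np.histogram(theta, bins=bins, range=(0.0, 180.0),
                               density=True)
    return series, hist, edges


@dataclass
class DepthResult:
    """Insertion depth under two conventions (both in Å).

    ``plane``: |z of the permeant COM − mean phosphate z of the nearest
    leaflet|.  ``nearest``: minimum 3-D COM-to-phosphate-atom distance.
    The tabulated value in membrane-location studies may follow either
    convention; both are reported.
    """

    plane: TimeSeries
    nearest: TimeSeries
    plane_mean: float
    plane_sd: float
    nearest_mean: float
    nearest_sd: float


def insertion_depth(traj: Trajectory, permeant_sel: AtomSelection,
                    phosphate_sel: AtomSelection) -> DepthResult:
    """Distance of the permeant from the phosphate layer, per frame."""
    if len(permeant_sel) == 0 or len(phosphate_sel) == 0:
        raise ValueError("selections must be non-empty")
    com = center_of_mass(traj, permeant_sel)
    p = traj.coords[:, phosphate_sel.indices, :]
    pz = p[:, :, 2]

    plane_d = np.empty(traj.n_frames)
    near_d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        upper, lower = pz[f][pz[f] >= 0], pz[f][pz[f] < 0]
        cands = [abs(com[f, 2] - g.mean()) for g in (upper, lower) if len(g)]
        plane_d[f] = min(cands)
        disp = p[f] - com[f]
        box_xy = traj.box[f, :2] if traj.box is not None else None
        disp = _min_image_xy(disp, box_xy)
        near_d[f] = np.linalg.norm(disp, axis=1).min()
    return DepthResult(
        plane=TimeSeries(traj.times, plane_d, "depth(plane) [A]"),
        nearest=TimeSeries(traj.times, near_d, "depth(nearest) [A]"),
        plane_mean=float(plane_d.mean()), plane_sd=float(plane_d.std()),
        nearest_mean=float(near_d.mean()), nearest_sd=float(near_d.std()),
    )


# ---------------------------------------------------------------------------
# solvation
# ---------------------------------------------------------------------------


def hydration_shell(traj: Trajectory, center_sel: AtomSelection,
                    water_oxygen_sel: AtomSelection,
                    radius: float = 3.5,
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """First-hydration-shell water counts per center atom.

    Counts water oxygens within ``radius`` Å (default 3.5 Å, the
    conventional first-shell cutoff) of each center atom, per frame.
    Returns the (n_frames, n_centers) count array plus a boxplot-ready
    summary (mean and quartiles pooled over frames) per center.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(water_oxygen_sel) == 0:
        log.warning("empty water selection; all hydration counts are 0")
        counts = np.zeros((traj.n_frames, len(center_sel)), dtype=int)
    else:
        counts = np.empty((traj.n_frames, len(center_sel)), dtype=int)
        for f in range(traj.n_frames):
            c = traj.coords[f, center_sel.indices, :]
            w = traj.coords[f, water_oxygen_sel.indices, :]
            disp = w[None, :, :] - c[:, None, :]
            box_xy = traj.box[f, :2] if traj.box is not None else None
            disp = _min_image_xy(disp, box_xy)
            counts[f] = np.sum(np.linalg.norm(disp, axis=2) <= radius, axis=1)
    rows = []
    names = traj.topology.names[center_sel.indices]
    for j, name in enumerate(names):
        col = counts[:, j]
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        rows.append({"center": name, "mean": col.mean(), "q1": q1,
                     "median": med, "q3": q3})
    return counts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Present in a frame iff the donor–acceptor distance is ≤
    ``distance_cutoff`` and the donor–hydrogen⋯acceptor angle is ≥
    ``angle_cutoff``.  Defaults (3.5 Å, 135°) follow common practice; no
    single printed criterion exists for lifetime tables, so sensitivity to
    these should be checked, not assumed away.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 135.0
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")
        if self.gap_tolerance < 0:
            raise ValueError("gap tolerance must be >= 0")


@dataclass
class BondEventSeries:
    """Per-pair boolean H-bond presence over frames."""

    donors: np.ndarray      # (n_pairs,)
    hydrogens: np.ndarray
    acceptors: np.ndarray
    presence: np.ndarray    # (n_pairs, n_frames) bool
    frame_interval: float   # ps


def detect_hbonds(traj: Trajectory, donors: AtomSelection,
                  hydrogens: AtomSelection, acceptors: AtomSelection,
                  criteria: HBondCriteria | None = None) -> BondEventSeries:
    """Detect hydrogen bonds between paired (donor, hydrogen) and acceptors.

    ``donors`` and ``hydrogens`` are index-paired (donor i owns hydrogen i);
    the pairing is validated against the first frame's D–H distance
    (< 1.25 Å).  Every donor×acceptor combination is scanned.
    """
    criteria = criteria or HBondCriteria()
    if len(donors) != len(hydrogens):
        raise ValueError("donors and hydrogens must be index-paired")
    dh = np.linalg.norm(traj.coords[0, donors.indices, :]
                        - traj.coords[0, hydrogens.indices, :], axis=1)
    bad = np.nonzero(dh >= 1.25)[0]
    if len(bad):
        raise ValueError(
            f"hydrogen {hydrogens.indices[bad[0]]} is not bonded to donor "
            f"{donors.indices[bad[0]]} (D–H distance {dh[bad[0]]:.2f} Å)")

    n_d, n_a, n_f = len(donors), len(acceptors), traj.n_frames
    presence = np.zeros((n_d * n_a, n_f), dtype=bool)
    cos_cut = np.cos(np.radians(criteria.angle_cutoff))
    for f in range(n_f):
        d = traj.coords[f, donors.indices, :]
        h = traj.coords[f, hydrogens.indices, :]
        a = traj.coords[f, acceptors.indices, :]
        box_xy = traj.box[f, :2] if traj.box is not None else None
        da = _min_image_xy(a[None, :, :] - d[:, None, :], box_xy)
        dist_ok = np.linalg.norm(da, axis=2) <= criteria.distance_cutoff
        hd = d - h
        ha = _min_image_xy(a[None, :, :] - h[:, None, :], box_xy)
        cos_ang = np.einsum("dk,dak->da", hd, ha) / (
            np.linalg.norm(hd, axis=1)[:, None]
            * np.maximum(np.linalg.norm(ha, axis=2), 1e-12))
        # angle(D–H⋯A) >= cutoff  <=>  cos(angle at H) <= cos(cutoff)
        presence[:, f] = (dist_ok & (cos_ang <= cos_cut)).ravel()
    dd, aa = np.meshgrid(donors.indices, acceptors.indices, indexing="ij")
    hh = np.repeat(hydrogens.indices, n_a)
    dt = traj.times[1] - traj.times[0] if n_f > 1 else 1.0
    return BondEventSeries(donors=dd.ravel(), hydrogens=hh,
                           acceptors=aa.ravel(), presence=presence,
                           frame_interval=float(dt))


def run_lengths(presence: np.ndarray, gap_tolerance: int = 0) -> list[int]:
    """Contiguous-presence run lengths (frames), merging gaps ≤ tolerance.

    A merged run spans from its first to its last present frame inclusive,
    so bridged gaps count toward the lifetime.
    """
    on = np.nonzero(np.asarray(presence, dtype=bool))[0]
    if len(on) == 0:
        return []
    runs = []
    start = prev = on[0]
    for i in on[1:]:
        if i - prev - 1 > gap_tolerance:
            runs.append(prev - start + 1)
            start = i
        prev = i
    runs.append(prev - start + 1)
    return runs


def hbond_lifetimes(events: BondEventSeries,
                    gap_tolerance: int | None = None,
                    group_by: str = "acceptor") -> pd.DataFrame:
    """Mean and maximum H-bond lifetimes (ps) per acceptor (or donor) atom.

    The maximum is the single longest contiguous run over all pairs sharing
    the group atom — the convention behind one-number-per-oxygen lifetime
    tables.
    """
    if gap_tolerance is None:
        gap_tolerance = 0
    key = events.acceptors if group_by == "acceptor" else events.donors
    rows = []
    for atom in np.unique(key):
        runs: list[int] = []
        for p in events.presence[key == atom]:
            runs.extend(run_lengths(p, gap_tolerance))
        if runs:
            arr = np.array(runs) * events.frame_interval
            rows.append({group_by: int(atom), "n_events": len(runs),
                         "mean_lifetime": float(arr.mean()),
                         "max_lifetime": float(arr.max())})
        else:
            rows.append({group_by: int(atom), "n_events": 0,
                         "mean_lifetime": 0.0, "max_lifetime": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------


def rdf(traj: Trajectory, sel_a: AtomSelection, sel_b: AtomSelection,
        r_max: float, dr: float, density: str = "slab") -> ZProfile:
    """Radial distribution function g(r) between two selections.

    g(r) = ⟨pair count in [r, r+dr)⟩ / (N_a · ρ_b · 4π r² dr), with
    minimum-image in x, y.  The reference density ρ_b defaults to the
    b-selection's occupied z-slab (selections like phosphate atoms are
    confined to planes, and whole-box normalization would depress g);
    ``density="box"`` switches to the whole instantaneous box volume.
    """
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("selections must be non-empty")
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("selections must be disjoint")
    box = traj.require_box()
    if r_max > 0.5 * box[:, :2].min():
        raise ValueError("r_max exceeds half the smallest lateral box length")
    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * dr

    g_acc = np.zeros(n_bins)
    for f in range(traj.n_frames):
        a = traj.coords[f, sel_a.indices, :]
        b = traj.coords[f, sel_b.indices, :]
        counts = np.zeros(n_bins)
        for start in range(0, len(a), 256):
            chunk = a[start:start + 256]
            disp = _min_image_xy(b[None, :, :] - chunk[:, None, :],
                                 box[f, :2])
            r = np.linalg.norm(disp, axis=2).ravel()
            counts += np.histogram(r, bins=edges)[0]
        if density == "slab":
            zb = b[:, 2]
            height = (zb.max() - zb.min()) + 2 * dr
        else:
            height = box[f, 2]
        rho_b = len(b) / (box[f, 0] * box[f, 1] * height)
        g_acc += counts / (len(a) * rho_b * shell_vol)
    return ZProfile(centers, dr, g_acc / traj.n_frames, unit="g(r)")


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------


def native_contacts(traj: Trajectory, permeant_sel: AtomSelection,
                    partner_sels: dict[str, AtomSelection],
                    cutoff: float = 4.5,
                    reference_frame: int | None = None,
                    phosphate_sel: AtomSelection | None = None,
                    ) -> dict[str, TimeSeries | None]:
    """Fraction of native contacts Q(t) per named partner region.

    Contacts are heavy-atom pairs within ``cutoff`` Å in the reference
    frame; Q(t) is the fraction of those pairs still within cutoff at t.
    When ``reference_frame`` is None it defaults to the first frame whose
    permeant COM z lies below the phosphate plane (membrane entry), or 0
    if no phosphate selection is given.  Regions with zero reference
    contacts report None with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if reference_frame is None:
        reference_frame = 0
        if phosphate_sel is not None and len(phosphate_sel):
            com_z = center_of_mass(traj, permeant_sel)[:, 2]
            for f in range(traj.n_frames):
                pz = traj.coords[f, phosphate_sel.indices, 2]
                plane = np.abs(pz).mean()
                if abs(com_z[f]) < plane:
                    reference_frame = f
                    break
    if not 0 <= reference_frame < traj.n_frames:
        raise ValueError(f"reference frame {reference_frame} out of range")

    out: dict[str, TimeSeries | None] = {}
    heavy = traj.topology.atomic_numbers > 1
    perm_idx = permeant_sel.indices[heavy[permeant_sel.indices]]
    for region, sel in partner_sels.items():
        part_idx = sel.indices[heavy[sel.indices]]
        box_xy = (traj.box[reference_frame, :2]
                  if traj.box is not None else None)
        disp = _min_image_xy(
            traj.coords[reference_frame, part_idx, :][None, :, :]
            - traj.coords[reference_frame, perm_idx, :][:, None, :], box_xy)
        ref_pairs = np.argwhere(np.linalg.norm(disp, axis=2) <= cutoff)
        if len(ref_pairs) == 0:
            log.warning("region %r has no reference contacts; Q undefined",
                        region)
            out[region] = None
            continue
        pi = perm_idx[ref_pairs[:, 0]]
        pj = part_idx[ref_pairs[:, 1]]
        q = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            box_xy = traj.box[f, :2] if traj.box is not None else None
            d = _min_image_xy(traj.coords[f, pj, :] - traj.coords[f, pi, :],
                              box_xy)
            q[f] = np.mean(np.linalg.norm(d, axis=1) <= cutoff)
        out[region] = TimeSeries(traj.times, q, f"Q({region})")
    return out
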