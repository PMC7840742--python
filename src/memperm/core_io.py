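"""Structure, trajectory and time-series containers and their file I/O.

The mandatory structure format is PDB (ATOM/HETATM/CRYST1), the mandatory
trajectory format multi-model PDB; both are read and written through
biotite.  PDB cannot carry partial charges portably, so charges arrive in a
two-column sidecar table (atom index, charge in e).  Umbrella-window
metadata follows the common WHAM convention: one line per window holding
``series-path  center(Å)  spring-constant(kcal/mol/Å²)``, with ``#``
comments; each series file is whitespace-delimited ``time(ps)  z(Å)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from rdkit.Chem import GetPeriodicTable

log = logging.getLogger(__name__)

_PT = GetPeriodicTable()


def atomic_number(element: str) -> int:
    """Atomic number of an element symbol (case-insensitive)."""
    sym = element.strip().capitalize()
    try:
        z = _PT.GetAtomicNumber(sym) if sym else 0
    except Exception:
        z = 0
    if z < 1:
        raise ValueError(f"unknown element symbol: {element!r}")
    return z


def molecular_weight(formula: Mapping[str, int]) -> float:
    """Molecular weight (g/mol) of an element→count composition.

    Uses standard atomic masses and reports to 2 decimals, e.g.
    ``{"H": 2, "O": 1}`` → 18.02 and the withanolide composition
    ``{"C": 28, "H": 38, "O": 6}`` → 470.61.
    """
    total = 0.0
    for sym, count in formula.items():
        if count < 1:
            raise ValueError(f"count for {sym!r} must be >= 1, got {count}")
        z = atomic_number(sym)
        total += count * _PT.GetAtomicWeight(z)
    return round(total, 2)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Per-atom labels shared by all frames of a trajectory.

    ``groups`` optionally maps atoms to named chemical groups (choline,
    phosphate, glycerol, carbonyl, CH2, CH=CH, CH3, water, drug) for
    decomposed profiles; unmapped atoms carry an empty string.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    charges: np.ndarray
    atomic_numbers: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resnames", "resids", "charges", "atomic_numbers"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr} has wrong length")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("group map length mismatch")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    """Ordered frames of coordinates with orthorhombic boxes.

    coords : (n_frames, n_atoms, 3) in Å; box : (n_frames, 3) lengths in Å
    or None when the source had no CRYST1; times : (n_frames,) in ps,
    strictly increasing.
    """

    coords: np.ndarray
    box: np.ndarray | None
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length does not match frame count")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def require_box(self) -> np.ndarray:
        if self.box is None:
            raise ValueError("this analysis requires box dimensions, but the "
                             "trajectory has none (no CRYST1 record?)")
        return self.box


@dataclass
class AtomSelection:
    """Ordered, unique atom indices into a Topology."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TimeSeries:
    """A scalar time series: times in ps, values in the label's units."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least two samples to define a frame interval")
        return float(self.times[1] - self.times[0])


@dataclass
class ZProfile:
    """A z-binned scalar profile (PMF, density, D, R ...).

    Bins are uniform and contiguous; ``centers`` strictly increasing,
    ``width`` the common bin width Δz.
    """

    centers: np.ndarray
    width: float
    values: np.ndarray
    errors: np.ndarray | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.centers) != len(self.values):
            raise ValueError("centers and values must have equal length")
        if len(self.centers) > 1:
            d = np.diff(self.centers)
            if np.any(d <= 0):
                raise ValueError("bin centers must be strictly increasing")
            if not np.allclose(d, self.width, rtol=1e-6, atol=1e-9):
                raise ValueError("bins must be uniform with spacing equal to width")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if len(self.errors) != len(self.values):
                raise ValueError("errors length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path, quantity: str = "value") -> None:
        header = (f"# z[A] {quantity}[{self.unit}]"
                  + (" stderr" if self.errors is not None else ""))
        cols = [self.centers, self.values]
        if self.errors is not None:
            cols.append(self.errors)
        np.savetxt(path, np.column_stack(cols), header=header, comments="")


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window along the membrane normal.

    The harmonic restraint is ``U = k (z - z0)²`` under the default
    ``"k"`` convention (the AMBER restraint form) or ``U = ½ k (z - z0)²``
    under ``"half-k"``.  ``discard`` frames are dropped from the start of
    the series before any estimate (burn-in).
    """

    center: float
    k: float
    series: TimeSeries | None = None
    series_path: Path | None = None
    convention: str = "k"
    discard: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"spring constant must be positive, got {self.k}")
        if self.convention not in ("k", "half-k"):
            raise ValueError(f"unknown bias convention {self.convention!r}")

    def load(self) -> TimeSeries:
        """The window series after burn-in discard (lazily read from disk)."""
        if self.series is None:
            if self.series_path is None:
                raise ValueError("window has neither an in-memory series nor a path")
            data = np.loadtxt(self.series_path, ndmin=2)
            self.series = TimeSeries(data[:, 0], data[:, 1], label="z")
        if self.discard >= len(self.series):
            raise ValueError("burn-in discard leaves an empty series")
        if self.discard:
            return TimeSeries(self.series.times[self.discard:],
                              self.series.values[self.discard:],
                              label=self.series.label)
        return self.series

    def bias_energy(self, z: np.ndarray) -> np.ndarray:
        """Restraint energy U(z) in kcal/mol under this window's convention."""
        pref = self.k if self.convention == "k" else 0.5 * self.k
        return pref * (np.asarray(z, dtype=float) - self.center) ** 2


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _stack_to_containers(stack: AtomArray | AtomArrayStack,
                         charges: np.ndarray | None) -> tuple[Topology, Trajectory]:
    if isinstance(stack, AtomArray):
        coords = stack.coord[None, :, :]
        box = stack.box[None] if stack.box is not None else None
        n_atoms = stack.array_length()
        template = stack
    else:
        coords = stack.coord
        box = stack.box
        n_atoms = stack.array_length()
        template = stack[0]

    elements = np.array([e if e else "C" for e in template.element])
    if charges is None:
        charges = np.zeros(n_atoms)
        log.warning("no partial charges supplied; defaulting all charges to 0")
    elif len(charges) != n_atoms:
        raise ValueError(f"charge table has {len(charges)} entries for "
                         f"{n_atoms} atoms")
    numbers = np.array([atomic_number(e) for e in elements])
    top = Topology(
        names=np.asarray(template.atom_name),
        elements=elements,
        resnames=np.asarray(template.res_name),
        resids=np.asarray(template.res_id, dtype=int),
        charges=np.asarray(charges, dtype=float),
        atomic_numbers=numbers,
    )
    if box is not None:
        # orthorhombic convention: keep diagonal lengths
        box_lengths = np.stack([np.diag(b) for b in box])
        if np.any(box_lengths <= 0):
            box_lengths = None
    else:
        box_lengths = None
    traj = Trajectory(coords=coords, box=box_lengths,
                      times=np.arange(coords.shape[0], dtype=float),
                      topology=top)
    return top, traj


def read_charges(path: str | Path) -> np.ndarray:
    """Read a charge sidecar TSV of ``atom-index  charge`` (0-based index)."""
    data = np.loadtxt(path, ndmin=2, comments="#")
    idx = data[:, 0].astype(int)
    charges = np.zeros(int(idx.max()) + 1)
    charges[idx] = data[:, 1]
    return charges


def read_structure(path: str | Path,
                   charges: str | Path | np.ndarray | None = None,
                   ) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-model) PDB file into Topology + Trajectory.

    ``charges`` may be a sidecar table path or an array; absent charges
    default to zero with a warning.  A missing CRYST1 record leaves the
    trajectory box as None; analyses needing a box will refuse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # biotite warns on absent CRYST1
            stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on malformed records
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if isinstance(charges, (str, Path)):
        charges = read_charges(charges)
    return _stack_to_containers(stack, charges)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-model PDB (coordinates at 1e-3 Å)."""
    top = traj.topology
    n = top.n_atoms
    stack = AtomArrayStack(traj.n_frames, n)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.atom_name = top.names
    stack.element = np.char.upper(top.elements.astype(str))
    stack.res_name = top.resnames
    stack.res_id = top.resids
    stack.chain_id = np.full(n, "A")
    stack.hetero = np.full(n, False)
    if traj.box is not None:
        stack.box = np.stack([np.diag(b) for b in traj.box])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# umbrella-window metadata
# ---------------------------------------------------------------------------


def read_window_metadata(path: str | Path, convention: str = "k",
                         discard_fraction: float = 0.0) -> list[UmbrellaWindow]:
    """Read a window metadata file: one ``series-path center k`` line each.

    Paths are resolved relative to the metadata file.  Series are loaded
    lazily.  ``discard_fraction`` sets each window's burn-in as a fraction
    of its series length at load time (applied by the PMF/diffusion stages).
    """
    path = Path(path)
    windows: list[UmbrellaWindow] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'path center k', got {raw!r}")
        series_path = (path.parent / parts[0]).resolve()
        try:
            center, k = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric center or spring "
                             f"constant in {raw!r}") from exc
        if k <= 0:
            raise ValueError(f"{path}:{lineno}: spring constant must be positive, "
                             f"got {k}")
        if not series_path.exists():
            raise FileNotFoundError(f"{path}:{lineno}: series file "
                                    f"{series_path} does not exist")
        w = UmbrellaWindow(center=center, k=k, series_path=series_path,
                           convention=convention)
        if discard_fraction:
            n_lines = sum(1 for ln in series_path.read_text().splitlines()
                          if ln.strip() and not ln.lstrip().startswith("#"))
            w.discard = int(discard_fraction * n_lines)
        windows.append(w)
    return windows


def write_window_metadata(windows: Sequence[UmbrellaWindow],
                          path: str | Path) -> None:
    path = Path(path)
    lines = ["# series-path  center[A]  k[kcal/mol/A^2]"]
    for w in windows:
        if w.series_path is None:
            raise ValueError("window has no series path; write its series first")
        rel = Path(w.series_path)
        try:
            rel = rel.relative_to(path.parent.resolve())
        except ValueError:
            pass
        lines.append(f"{rel}  {w.center:.6g}  {w.k:.6g}")
    path.write_text("\n".join(lines) + "\n")


def write_series(series: TimeSeries, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([series.times, series.values]),
               header="# time[ps] z[A]", comments="", fmt="%.6f")


# ---------------------------------------------------------------------------
# frame conventions
# ---------------------------------------------------------------------------


def recenter_bilayer(traj: Trajectory, midplane_sel: AtomSelection) -> Trajectory:
    """Shift each frame in z so the selection's mean z is 0 (bilayer center).

    x, y and the box are untouched; this establishes the convention that the
    bilayer midplane sits at z = 0 with bulk water toward the box edges.
    """
    if len(midplane_sel) == 0:
        raise ValueError("midplane selection is empty")
    coords = traj.coords.copy()
    mean_z = coords[:, midplane_sel.indices, 2].mean(axis=1)
    coords[:, :, 2] -= mean_z[:, None]
    return replace(traj, coords=coords)
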