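"""Ground-truth generators standing in for MD trajectories.

Every analysis in the package can be exercised against data whose answer
is known by construction:

* a 1-D overdamped Langevin simulator on a prescribed free-energy
  landscape w(z) and diffusivity D(z), with optional harmonic umbrella
  biases — its stationary law is exactly ∝ exp(−β(w + U_bias));
* a coarse bead bilayer builder (head/tail-bead lipids, sterol-like and
  water-like particles) with controllable chain tilt, whose APL, S_CD,
  leaflet counts and group map are recorded as ground truth;
* telegraph (two-state) and Ornstein–Uhlenbeck series generators for the
  H-bond-lifetime and diffusion-estimator machinery.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter

from . import units
from .core_io import (TimeSeries, Topology, Trajectory, UmbrellaWindow,
                      write_series, write_window_metadata)

# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


@dataclass
class LandscapeSpec:
    """Prescribed w(z) (kcal/mol) and D(z) (Å²/ps) on [z_lo, z_hi].

    Potential forms (``w_form`` / ``w_params``):
      flat {}, harmonic {kappa, z0}, rectangular {height, z_a, z_b},
      gaussian {height, center, width2} → h·exp(−(z−c)²/width2),
      double_well {height, center, half_sep} →
      h·((z−c)² − b²)²/b⁴ (wells at c±b, barrier h),
      tabulated {z, w} (cubic spline).
    Diffusivity forms (``d_form`` / ``d_params``):
      constant {d0}, cosine {a, b, length} → a + b·cos(πz/length),
      tabulated {z, d}.
    The boundary condition for dynamics is reflecting at z_lo and z_hi.
    """

    z_lo: float
    z_hi: float
    w_form: str = "flat"
    w_params: dict = field(default_factory=dict)
    d_form: str = "constant"
    d_params: dict = field(default_factory=lambda: {"d0": 0.1})

    def __post_init__(self) -> None:
        if self.z_hi <= self.z_lo:
            raise ValueError("empty domain")
        if self.w_form == "tabulated":
            p = self.w_params
            self._w_spline = CubicSpline(p["z"], p["w"])
        if self.d_form == "tabulated":
            p = self.d_params
            self._d_spline = CubicSpline(p["z"], p["d"])
        zz = np.linspace(self.z_lo, self.z_hi, 201)
        if np.any(self.d(zz) <= 0):
            raise ValueError("D(z) must be positive on the domain")
        if np.any(~np.isfinite(self.w(zz))):
            raise ValueError("w(z) must be finite on the domain")

    # potential ------------------------------------------------------------
    def w(self, z):
        p = self.w_params
        z = np.asarray(z, dtype=float)
        if self.w_form == "flat":
            return np.zeros_like(z)
        if self.w_form == "harmonic":
            return 0.5 * p["kappa"] * (z - p["z0"]) ** 2
        if self.w_form == "rectangular":
            return np.where((z >= p["z_a"]) & (z <= p["z_b"]),
                            p["height"], 0.0)
        if self.w_form == "gaussian":
            return p["height"] * np.exp(-(z - p["center"]) ** 2 / p["width2"])
        if self.w_form == "double_well":
            b = p["half_sep"]
            return p["height"] * ((z - p["center"]) ** 2 - b**2) ** 2 / b**4
        if self.w_form == "tabulated":
            return self._w_spline(z)
        raise ValueError(f"unknown potential form {self.w_form!r}")

    def w_grad(self, z):
        p = self.w_params
        z = np.asarray(z, dtype=float)
        if self.w_form == "flat":
            return np.zeros_like(z)
        if self.w_form == "harmonic":
            return p["kappa"] * (z - p["z0"])
        if self.w_form == "rectangular":
            return np.zeros_like(z)  # force is a boundary impulse; see docs
        if self.w_form == "gaussian":
            g = np.exp(-(z - p["center"]) ** 2 / p["width2"])
            return p["height"] * g * (-2.0 * (z - p["center"]) / p["width2"])
        if self.w_form == "double_well":
            b, c = p["half_sep"], p["center"]
            return p["height"] * 4.0 * ((z - c) ** 2 - b**2) * (z - c) / b**4
        if self.w_form == "tabulated":
            return self._w_spline(z, 1)
        raise ValueError(f"unknown potential form {self.w_form!r}")

    # diffusivity ----------------------------------------------------------
    def d(self, z):
        p = self.d_params
        z = np.asarray(z, dtype=float)
        if self.d_form == "constant":
            return np.full_like(z, p["d0"])
        if self.d_form == "cosine":
            return p["a"] + p["b"] * np.cos(np.pi * z / p["length"])
        if self.d_form == "tabulated":
            return self._d_spline(z)
        raise ValueError(f"unknown diffusivity form {self.d_form!r}")

    def d_grad(self, z):
        p = self.d_params
        z = np.asarray(z, dtype=float)
        if self.d_form == "constant":
            return np.zeros_like(z)
        if self.d_form == "cosine":
            return -p["b"] * np.pi / p["length"] * np.sin(np.pi * z / p["length"])
        if self.d_form == "tabulated":
            return self._d_spline(z, 1)
        raise ValueError(f"unknown diffusivity form {self.d_form!r}")

    # scalar closures for the integrator hot loop --------------------------
    def scalar_funcs(self):
        """(w′, D, D′) as plain-float closures for the Langevin inner loop."""
        p, q = self.w_params, self.d_params
        if self.w_form == "flat":
            w_grad = lambda z: 0.0  # noqa: E731
        elif self.w_form == "harmonic":
            kappa, z0 = p["kappa"], p["z0"]
            w_grad = lambda z: kappa * (z - z0)  # noqa: E731
        elif self.w_form == "rectangular":
            w_grad = lambda z: 0.0  # noqa: E731
        elif self.w_form == "gaussian":
            h, c0, w2 = p["height"], p["center"], p["width2"]
            w_grad = lambda z: h * math.exp(-(z - c0) ** 2 / w2) * (  # noqa: E731
                -2.0 * (z - c0) / w2)
        elif self.w_form == "double_well":
            h, c0, b = p["height"], p["center"], p["half_sep"]
            b4 = b**4
            w_grad = lambda z: 4.0 * h * ((z - c0) ** 2 - b * b) * (z - c0) / b4  # noqa: E731
        else:
            spl = self._w_spline
            w_grad = lambda z: float(spl(z, 1))  # noqa: E731
        if self.d_form == "constant":
            d0 = q["d0"]
            d_fun = lambda z: d0  # noqa: E731
            d_grad = lambda z: 0.0  # noqa: E731
        elif self.d_form == "cosine":
            a, b, ln = q["a"], q["b"], q["length"]
            pi_l = math.pi / ln
            d_fun = lambda z: a + b * math.cos(pi_l * z)  # noqa: E731
            d_grad = lambda z: -b * pi_l * math.sin(pi_l * z)  # noqa: E731
        else:
            spl = self._d_spline
            d_fun = lambda z: float(spl(z))  # noqa: E731
            d_grad = lambda z: float(spl(z, 1))  # noqa: E731
        return w_grad, d_fun, d_grad


def _reflect(z: float, lo: float, hi: float) -> float:
    span = 2.0 * (hi - lo)
    z = (z - lo) % span
    if z > hi - lo:
        z = span - z
    return z + lo


def langevin_1d(spec: LandscapeSpec,
                bias: tuple[float, float, str] | None = None,
                dt: float = 0.01, n_steps: int = 100_000,
                seed: int = 0, save_stride: int = 1,
                z_init: float | None = None,
                temperature: float = units.DEFAULT_TEMPERATURE) -> TimeSeries:
    """Overdamped Langevin dynamics on (w, D) with reflecting boundaries.

    Itô–Euler update
        z ← z + [−β D(z) (w′(z) + U′(z)) + D′(z)] dt + √(2 D(z) dt) ξ
    with the spurious-drift term D′(z) included, so the stationary law is
    exactly ∝ exp(−β (w + U_bias)) for any positive D(z).  ``bias`` is an
    optional harmonic restraint (z₀, k, convention) with convention "k"
    (U = k(z−z₀)²) or "half-k".
    """
    beta = units.beta(temperature)
    lo, hi = spec.z_lo, spec.z_hi
    rng = np.random.default_rng(seed)
    if z_init is None:
        z_init = bias[0] if bias is not None else 0.5 * (lo + hi)
    z = _reflect(float(z_init), lo, hi)

    if bias is not None:
        z0, k, conv = bias
        pref = 2.0 * k if conv == "k" else k
        u_grad = lambda x: pref * (x - z0)  # noqa: E731
    else:
        u_grad = lambda x: 0.0  # noqa: E731

    # stability check: the deterministic step must stay well inside the domain
    zz = np.linspace(lo, hi, 101)
    max_step = np.max(np.abs(beta * spec.d(zz) * spec.w_grad(zz))) * dt
    if max_step > 0.1 * (hi - lo):
        import logging
        logging.getLogger(__name__).warning(
            "Langevin dt may be too large: max deterministic step %.3g vs "
            "domain width %.3g", max_step, hi - lo)

    n_out = n_steps // save_stride
    out = np.empty(n_out)
    noise = rng.standard_normal(n_steps)

    flat_const = (spec.w_form == "flat" and spec.d_form == "constant"
                  and bias is None)
    if flat_const:
        # exact vectorized path for free diffusion
        d0 = spec.d_params["d0"]
        steps = math.sqrt(2.0 * d0 * dt) * noise
        path = z + np.cumsum(steps)
        span = 2.0 * (hi - lo)
        path = np.mod(path - lo, span)
        path = np.where(path > hi - lo, span - path, path) + lo
        out = path[save_stride - 1::save_stride][:n_out]
    else:
        w_grad, d_fun, d_grad = spec.scalar_funcs()
        sqrt2dt = math.sqrt(2.0 * dt)
        j = 0
        for i in range(n_steps):
            dz = d_fun(z)
            if dz <= 0:
                raise ValueError(f"D <= 0 encountered at z={z} (step {i})")
            drift = -beta * dz * (w_grad(z) + u_grad(z)) + d_grad(z)
            z = z + drift * dt + sqrt2dt * math.sqrt(dz) * noise[i]
            if not math.isfinite(z):
                raise ValueError(f"NaN/Inf position at step {i}")
            if z < lo or z > hi:
                z = _reflect(z, lo, hi)
            if (i + 1) % save_stride == 0:
                out[j] = z
                j += 1
    times = dt * save_stride * np.arange(1, n_out + 1)
    return TimeSeries(times, out, label="z")


def generate_umbrella_set(spec: LandscapeSpec, centers: np.ndarray,
                          k: float, convention: str = "k",
                          n_steps: int = 50_000, dt: float = 0.01,
                          seed: int = 0, save_stride: int = 1,
                          temperature: float = units.DEFAULT_TEMPERATURE,
                          out_dir: str | Path | None = None,
                          ) -> list[UmbrellaWindow]:
    """One biased Langevin run per window center, seeded deterministically.

    Per-window seeds derive from (seed, window index) via SeedSequence, so
    the set is reproducible byte-for-byte and windows are independent.
    With ``out_dir`` the series and a shared-format metadata file are
    written alongside the returned windows.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any((centers < spec.z_lo) | (centers > spec.z_hi)):
        raise ValueError("window centers must lie inside the domain")
    windows = []
    for i, c in enumerate(centers):
        child_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        sub_rng_seed = int(child_seed.generate_state(1)[0])
        series = langevin_1d(spec, bias=(float(c), k, convention), dt=dt,
                             n_steps=n_steps, seed=sub_rng_seed,
                             save_stride=save_stride, z_init=float(c),
                             temperature=temperature)
        windows.append(UmbrellaWindow(center=float(c), k=k, series=series,
                                      convention=convention))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, w in enumerate(windows):
            p = out_dir / f"window_{i:03d}.dat"
            write_series(w.series, p)
            w.series_path = p
        write_window_metadata(windows, out_dir / "metadata.dat")
    return windows


# ---------------------------------------------------------------------------
# coarse bilayer builder
# ---------------------------------------------------------------------------

#: fixed internal charge table for the bead model (e)
BEAD_CHARGES = {"P": 1.4, "N": -0.4, "O": -0.8, "C": -0.1, "H": 0.1}

_ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15}


@dataclass
class BilayerSpec:
    """Geometry of the coarse synthetic bilayer.

    Two leaflets of head/tail-bead lipids (choline-like N + phosphate P
    head beads at ±``head_z``, ``chain_beads`` carbons each carrying one
    hydrogen along the chain direction, tilted by ``tilt_deg`` from the
    normal), optional sterol-like particles, and water-like oxygens
    uniform outside the membrane slab.  Not chemically realistic: element
    labels exist to make selections, EDP weights and S_CD geometry
    meaningful.
    """

    n_lipids_per_leaflet: int = 10
    n_chol_per_leaflet: int = 0
    n_waters: int = 100
    box: tuple[float, float, float] = (25.0, 25.0, 60.0)
    head_z: float = 18.0
    chain_beads: int = 6
    tilt_mode: str = "fixed"     # "fixed" | "gaussian"
    tilt_deg: float = 0.0
    tilt_sigma: float = 10.0
    bond_length: float = 1.5
    jitter: float = 0.0          # Gaussian positional noise, Å
    n_frames: int = 1
    midplane_drift: float = 0.0  # per-frame uniform z shift amplitude, Å
    permeant_path: np.ndarray | None = None  # scripted permeant z per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_z >= self.box[2] / 2:
            raise ValueError("head plane must lie inside the box")
        if min(self.n_lipids_per_leaflet, self.n_chol_per_leaflet,
               self.n_waters) < 0:
            raise ValueError("particle counts must be >= 0")


def build_bilayer(spec: BilayerSpec) -> tuple[Topology, Trajectory, dict]:
    """Build the bead bilayer; returns topology, trajectory, ground truth.

    The ground-truth record predicts, without running any analysis, the
    exact area per lipid (box area / lipids per leaflet), the per-lipid
    tilt angles, the fixed-tilt S_CD = ½(3cos²θ − 1), and the leaflet and
    group bookkeeping.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    n_lip = spec.n_lipids_per_leaflet
    grid = int(np.ceil(np.sqrt(max(n_lip, spec.n_chol_per_leaflet, 1))))
    spacing = min(lx, ly) / grid
    if n_lip and spacing < 2.0:
        raise ValueError(f"box overfilled: lattice spacing {spacing:.2f} Å "
                         f"below bead diameter 2 Å")

    names, elements, resnames, resids, groups = [], [], [], [], []
    base_coords = []
    tilt_angles = []
    resid = 0

    def add_atom(name, element, resname, group, xyz):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resids.append(resid)
        groups.append(group)
        base_coords.append(xyz)

    sites = [((i + 0.5) * lx / grid, (j + 0.5) * ly / grid)
             for i in range(grid) for j in range(grid)]
    for leaflet_sign in (+1, -1):
        for m in range(n_lip):
            resid += 1
            x, y = sites[m]
            if spec.tilt_mode == "fixed":
                theta = math.radians(spec.tilt_deg)
            else:
                theta = abs(rng.normal(0.0, math.radians(spec.tilt_sigma)))
            phi = rng.uniform(0, 2 * math.pi)
            tilt_angles.append(math.degrees(theta))
            # chain direction points from the head plane toward z = 0
            direction = np.array([math.sin(theta) * math.cos(phi),
                                  math.sin(theta) * math.sin(phi),
                                  -leaflet_sign * math.cos(theta)])
            head = np.array([x, y, leaflet_sign * spec.head_z])
            add_atom("N", "N", "LIP", "choline",
                     head + np.array([0.0, 0.0, leaflet_sign * 1.0]))
            add_atom("P", "P", "LIP", "phosphate", head)
            pos = head.copy()
            for c in range(1, spec.chain_beads + 1):
                pos = pos + spec.bond_length * direction
                grp = "CH3" if c == spec.chain_beads else "CH2"
                add_atom(f"C{c}", "C", "LIP", grp, pos.copy())
                add_atom(f"H{c}", "H", "LIP", grp, pos + 1.0 * direction)
        for m in range(spec.n_chol_per_leaflet):
            resid += 1
            x, y = sites[m]
            x = (x + 0.5 * spacing) % lx
            y = (y + 0.5 * spacing) % ly
            top_z = leaflet_sign * (spec.head_z - 2.0)
            add_atom("O3", "O", "CHL", "sterol", np.array([x, y, top_z]))
            for c in range(1, 4):
                add_atom(f"C{c}", "C", "CHL", "sterol",
                         np.array([x, y, top_z - leaflet_sign * 1.5 * c]))
    water_gap = lz / 2 - (spec.head_z + 2.0)
    for m in range(spec.n_waters):
        resid += 1
        sign = 1 if m % 2 == 0 else -1
        zw = sign * (spec.head_z + 2.0 + rng.uniform(0, max(water_gap, 0.1)))
        add_atom("O", "O", "WAT", "water",
                 np.array([rng.uniform(0, lx), rng.uniform(0, ly), zw]))
    permeant_resid = None
    if spec.permeant_path is not None:
        resid += 1
        permeant_resid = resid
        # a small rigid permeant: two oxygens flanking three carbons
        offsets = [("O1", "O", (-1.5, 0.0, 0.0)), ("C1", "C", (0.0, 0.0, 0.0)),
                   ("C2", "C", (1.4, 0.0, 0.0)), ("C3", "C", (0.0, 1.4, 0.0)),
                   ("O2", "O", (2.9, 0.0, 0.0))]
        for name, el, off in offsets:
            add_atom(name, el, "DRG", "drug",
                     np.array([lx / 2 + off[0], ly / 2 + off[1], off[2]]))

    base = np.array(base_coords)
    n_atoms = len(base)
    elements = np.array(elements)
    charges = np.array([BEAD_CHARGES[e] for e in elements])
    top = Topology(
        names=np.array(names), elements=elements,
        resnames=np.array(resnames), resids=np.array(resids, dtype=int),
        charges=charges,
        atomic_numbers=np.array([_ELEMENT_Z[e] for e in elements]),
        groups=np.array(groups),
    )

    n_frames = spec.n_frames
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    drifts = (rng.uniform(-spec.midplane_drift, spec.midplane_drift, n_frames)
              if spec.midplane_drift else np.zeros(n_frames))
    coords[:, :, 2] += drifts[:, None]
    if spec.jitter:
        coords += rng.normal(0.0, spec.jitter, coords.shape)
    if spec.permeant_path is not None:
        path = np.asarray(spec.permeant_path, dtype=float)
        if len(path) != n_frames:
            raise ValueError("permeant path length must equal n_frames")
        drug = top.resids == permeant_resid
        coords[:, drug, 2] += (path - 0.0)[:, None]
    box = np.tile(np.array(spec.box), (n_frames, 1))
    traj = Trajectory(coords=coords, box=box,
                      times=np.arange(n_frames, dtype=float), topology=top)

    theta = math.radians(spec.tilt_deg)
    truth = {
        "apl": lx * ly / n_lip if n_lip else None,
        "tilt_angles_deg": np.array(tilt_angles),
        "s_cd_fixed_tilt": 0.5 * (3.0 * math.cos(theta) ** 2 - 1.0)
        if spec.tilt_mode == "fixed" else None,
        "leaflet_counts": {"upper": n_lip, "lower": n_lip},
        "n_waters": spec.n_waters,
        "head_z": spec.head_z,
        "midplane_drifts": drifts,
        "permeant_resid": permeant_resid,
        "total_electrons": float(np.sum(top.atomic_numbers - charges)),
    }
    return top, traj, truth


# ---------------------------------------------------------------------------
# stochastic series generators
# ---------------------------------------------------------------------------


def telegraph_series(mean_on: float, mean_off: float, dt: float, n: int,
                     seed: int = 0) -> tuple[TimeSeries, dict]:
    """Two-state telegraph signal with exponential dwell times.

    Returns the discretized boolean series (sampled at the frame times)
    plus a ground-truth record of the continuous dwells actually drawn —
    the oracle for lifetime-estimator tests.
    """
    if mean_on <= 0 or mean_off <= 0:
        raise ValueError("dwell means must be positive")
    rng = np.random.default_rng(seed)
    total = n * dt
    t, state = 0.0, False  # start in the off state
    switch_times, on_dwells, off_dwells = [], [], []
    while t < total:
        dwell = rng.exponential(mean_on if state else mean_off)
        (on_dwells if state else off_dwells).append(dwell)
        t += dwell
        switch_times.append(t)
        state = not state
    times = dt * np.arange(1, n + 1)
    # state at time t: even number of switches passed => off
    n_switches = np.searchsorted(np.array(switch_times), times, side="right")
    values = (n_switches % 2).astype(float)
    truth = {"mean_on": float(np.mean(on_dwells)) if on_dwells else 0.0,
             "mean_off": float(np.mean(off_dwells)) if off_dwells else 0.0,
             "n_on_dwells": len(on_dwells)}
    return TimeSeries(times, values, label="on"), truth


def ou_series(variance: float, tau: float, dt: float, n: int,
              seed: int = 0) -> TimeSeries:
    """Exact discrete Ornstein–Uhlenbeck series.

    z_{t+dt} = z_t e^{−dt/τ} + √(var (1 − e^{−2dt/τ})) ξ with a stationary
    start; the autocovariance is var·e^{−t/τ} and the implied diffusion
    coefficient is D = var/τ.
    """
    if not tau > dt > 0:
        raise ValueError("need tau > dt > 0")
    rng = np.random.default_rng(seed)
    a = math.exp(-dt / tau)
    innov = math.sqrt(variance * (1.0 - a * a)) * rng.standard_normal(n)
    z0 = math.sqrt(variance) * rng.standard_normal()
    values, _ = lfilter([1.0], [1.0, -a], innov, zi=[a * z0])
    times = dt * np.arange(1, n + 1)
    return TimeSeries(times, values, label="z")
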