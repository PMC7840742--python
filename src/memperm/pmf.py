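"""Free-energy and permeability core.

Umbrella-window bookkeeping, WHAM unbiasing of restrained z-histograms into
a potential of mean force w(z), z-reflection symmetrization, per-window
position-dependent diffusion coefficients D(z) from the positional
autocorrelation function, and the inhomogeneous solubility–diffusion
permeability

    1/P = R = ∫_{z1}^{z2} exp(β w(z)) / D(z) dz

whose integrand exp(βw)/D is the local resistivity R(z).  Units: w in
kcal/mol, D in Å²/ps, R in ps/Å, P in Å/ps (1 Å/ps = 10⁴ cm/s).

The harmonic restraint convention defaults to U = k (z − z₀)² (the AMBER
restraint form); a per-window flag switches to U = ½ k (z − z₀)².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import units
from .core_io import TimeSeries, UmbrellaWindow, ZProfile

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# window layout
# ---------------------------------------------------------------------------


def make_window_centers(z_top: float, z_center: float, spacing: float,
                        include_center: bool = True) -> np.ndarray:
    """Arithmetic ladder of window centers from z_top toward z_center.

    With ``include_center`` both endpoints are kept (a 1 Å grid from 38 to
    0 gives 39 centers); excluding the center endpoint gives one fewer.
    The returned count is always explicit via ``len``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if z_top <= z_center:
        raise ValueError("z_top must exceed z_center")
    n = int(np.floor((z_top - z_center) / spacing + 1e-9)) + 1
    centers = z_top - spacing * np.arange(n)
    if not include_center and abs(centers[-1] - z_center) < 1e-9:
        centers = centers[:-1]
    return centers


def reflect_windows(windows: list[UmbrellaWindow],
                    include_center: bool = False) -> list[UmbrellaWindow]:
    """Mirror one-sided windows across z = 0 (membrane symmetry).

    Each window at center z₀ > 0 gains a twin at −z₀ with its series
    negated; the z = 0 window is duplicated only when ``include_center``.
    """
    out = list(windows)
    for w in windows:
        if abs(w.center) < 1e-9 and not include_center:
            continue
        s = w.load()
        out.append(UmbrellaWindow(center=-w.center, k=w.k,
                                  series=TimeSeries(s.times, -s.values,
                                                    label=s.label),
                                  convention=w.convention))
    return out


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


@dataclass
class PMFResult:
    """WHAM output: w(z) profile, window offsets, convergence metadata."""

    profile: ZProfile            # w(z), kcal/mol; errors from bootstrap if run
    offsets: np.ndarray          # per-window free energies F_i, kcal/mol
    converged: bool
    iterations: int
    residual: float              # last max |ΔF_i|, kcal/mol
    anchor: str
    temperature: float


def _wham_fixed_point(counts: np.ndarray, n_tot: np.ndarray,
                      bias_beta: np.ndarray, tol_f: float, max_iter: int,
                      f_init: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Solve the WHAM self-consistency equations.

    counts: (n_windows, n_bins) histograms; n_tot: per-window totals;
    bias_beta: (n_windows, n_bins) βU_i(z_b).  Returns the normalized
    unbiased bin probabilities, the dimensionless window offsets βF_i,
    the iteration count and the final residual (dimensionless).
    """
    m = counts.sum(axis=0)
    c = np.exp(-bias_beta)
    f = np.zeros(len(n_tot)) if f_init is None else f_init.copy()
    it, resid = 0, np.inf
    for it in range(1, max_iter + 1):
        denom = (n_tot * np.exp(f)) @ c          # (n_bins,)
        p = np.where(denom > 0, m / np.maximum(denom, 1e-300), 0.0)
        p /= p.sum()
        f_new = -np.log(np.maximum(c @ p, 1e-300))
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid <= tol_f:
            break
    denom = (n_tot * np.exp(f)) @ c
    p = np.where(denom > 0, m / np.maximum(denom, 1e-300), 0.0)
    p /= p.sum()
    return p, f, it, resid


def _anchor_profile(w: np.ndarray, anchor: str) -> np.ndarray:
    if anchor == "min":
        return w - np.nanmin(w)
    if anchor == "bulk":
        edge = np.concatenate([w[:3], w[-3:]])
        return w - np.nanmean(edge)
    if anchor == "bulk-upper":
        return w - np.nanmean(w[-3:])
    if anchor == "none":
        return w
    raise ValueError(f"unknown anchor convention {anchor!r}")


def wham(windows: list[UmbrellaWindow],
         z_bins: int | np.ndarray = 50,
         temperature: float = units.DEFAULT_TEMPERATURE,
         tolerance: float = 1e-7,
         max_iter: int = 100_000,
         anchor: str = "min",
         n_bootstrap: int = 0,
         seed: int | None = None,
         f_init: np.ndarray | None = None) -> PMFResult:
    """Unbias umbrella-window histograms into a PMF by WHAM.

    Solves  P(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp(β(F_i − U_i(z_b)))  and
    exp(−βF_i) = Σ_b P(z_b) exp(−βU_i(z_b))  self-consistently until
    max|ΔF_i| ≤ ``tolerance`` (kcal/mol), then w(z_b) = −k_B T ln P(z_b)
    anchored per ``anchor`` ("min", "bulk", "bulk-upper", "none").

    ``z_bins`` is either explicit bin edges or a bin count over the pooled
    sampled range.  Interior bins never visited by any window indicate a
    sampling gap and raise.  With ``n_bootstrap`` > 0, per-bin standard
    errors are estimated by resampling each window's histogram with an
    autocorrelation-corrected effective sample size.
    """
    if not windows:
        raise ValueError("need at least one window")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = units.beta(temperature)

    samples = [w.load().values for w in windows]
    if isinstance(z_bins, (int, np.integer)):
        lo = min(s.min() for s in samples)
        hi = max(s.max() for s in samples)
        edges = np.linspace(lo, hi + 1e-9 * max(1.0, abs(hi)), int(z_bins) + 1)
    else:
        edges = np.asarray(z_bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    counts = np.stack([np.histogram(s, bins=edges)[0] for s in samples]
                      ).astype(float)
    n_tot = counts.sum(axis=1)
    if np.any(n_tot == 0):
        bad = int(np.nonzero(n_tot == 0)[0][0])
        raise ValueError(f"window {bad} (center {windows[bad].center}) has no "
                         f"samples inside the binning range")

    m = counts.sum(axis=0)
    visited = np.nonzero(m > 0)[0]
    gaps = np.nonzero(m[visited[0]:visited[-1] + 1] == 0)[0]
    if len(gaps):
        z_gap = centers[visited[0] + gaps[0]]
        raise ValueError(f"sampling gap between windows near z = {z_gap:.2f} Å; "
                         f"adjacent windows do not overlap")
    sl = slice(visited[0], visited[-1] + 1)
    counts, centers = counts[:, sl], centers[sl]

    bias_beta = beta * np.stack([w.bias_energy(centers) for w in windows])
    tol_f = tolerance * beta  # tolerance is stated in kcal/mol
    p, f, it, resid = _wham_fixed_point(counts, n_tot, bias_beta, tol_f,
                                        max_iter, f_init)
    converged = resid <= tol_f
    if not converged:
        log.warning("WHAM did not converge in %d iterations "
                    "(residual %.3g kcal/mol)", max_iter, resid / beta)

    kt = units.K_B * temperature
    w_vals = np.where(p > 0, -kt * np.log(np.maximum(p, 1e-300)), np.nan)
    w_vals = _anchor_profile(w_vals, anchor)

    errors = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        g = np.array([_statistical_inefficiency(s) for s in samples])
        boots = np.empty((n_bootstrap, len(centers)))
        for b in range(n_bootstrap):
            bc = np.empty_like(counts)
            for i in range(len(windows)):
                n_eff = max(2, int(round(n_tot[i] / g[i])))
                draw = rng.multinomial(n_eff, counts[i] / counts[i].sum())
                bc[i] = draw * (n_tot[i] / n_eff)
            pb, _, _, _ = _wham_fixed_point(bc, bc.sum(axis=1), bias_beta,
                                            tol_f, max_iter, f_init=f)
            wb = np.where(pb > 0, -kt * np.log(np.maximum(pb, 1e-300)), np.nan)
            boots[b] = _anchor_profile(wb, anchor)
        errors = np.nanstd(boots, axis=0)

    profile = ZProfile(centers, width, w_vals, errors, unit="kcal/mol")
    return PMFResult(profile=profile, offsets=f / beta, converged=converged,
                     iterations=it, residual=resid / beta, anchor=anchor,
                     temperature=temperature)


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------


def symmetrize(profile: ZProfile, reflect_center: str = "exclude") -> ZProfile:
    """Reflect a one-sided z-profile across z = 0 (membrane symmetry).

    Input must be defined on a one-sided range [0, z_max] (a bin centered
    at 0 is allowed); output covers [−z_max, z_max] with v(−z) = v(z).
    ``reflect_center`` records whether the z = 0 bin is conceptually
    duplicated ("include") or kept single ("exclude") — for a binned
    profile both yield the same symmetric values.  An already-symmetric
    profile passes through unchanged (idempotence); a two-sided asymmetric
    profile is rejected.
    """
    if reflect_center not in ("include", "exclude"):
        raise ValueError("reflect_center must be 'include' or 'exclude'")
    c, v = profile.centers, profile.values
    tol = 1e-9 * max(1.0, profile.width)
    if c[0] < -tol and c[-1] > tol:
        if len(c) % 2 == 1 and np.allclose(c, -c[::-1]) \
                and np.allclose(v, v[::-1], equal_nan=True):
            return profile
        raise ValueError("profile already spans both signs of z and is not "
                         "symmetric; refusing to symmetrize")
    if c[-1] < tol:  # negative-sided input: flip to [0, z_max] first
        c, v = -c[::-1], v[::-1]
        e = profile.errors[::-1] if profile.errors is not None else None
    else:
        e = profile.errors
    has_center = abs(c[0]) <= tol
    mirror = slice(1, None) if has_center else slice(0, None)
    new_c = np.concatenate([-c[mirror][::-1], c])
    new_v = np.concatenate([v[mirror][::-1], v])
    new_e = None
    if e is not None:
        new_e = np.concatenate([e[mirror][::-1], e])
    return ZProfile(new_c, profile.width, new_v, new_e, unit=profile.unit)


# ---------------------------------------------------------------------------
# diffusion from positional autocorrelation
# ---------------------------------------------------------------------------


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased sample autocovariance C(k) = ⟨δx(0) δx(k)⟩ via FFT."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    dx = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    if max_lag is not None:
        acov = acov[:max_lag + 1]
    return acov


def _integrate_acf(acov: np.ndarray, dt: float,
                   truncation: str = "auto-window",
                   window_factor: float = 5.0) -> tuple[float, str]:
    """∫C dt by left-Riemann sum with a truncation rule.

    ``auto-window`` (default) truncates at the smallest lag k with
    k·Δt ≥ ``window_factor`` × the running correlation-time estimate
    I(k)/C(0) — the standard automatic-windowing rule, whose error shrinks
    with series length.  ``first-zero`` stops at the first non-positive
    lag; if C never crosses zero a single exponential is fitted to
    C(t)/C(0) and integrated analytically (``exp-fit``).  Every rule gives
    ∫C dt = var·Δt in the white-noise limit (only the lag-0 rectangle
    survives).
    """
    c0 = acov[0]
    if truncation == "auto-window":
        run = dt * np.cumsum(acov)               # I(k+1), left-Riemann
        lags_t = dt * np.arange(1, len(acov) + 1)
        hit = np.nonzero(lags_t >= window_factor * np.maximum(run, dt * c0)
                         / c0)[0]
        k_star = hit[0] if len(hit) else len(acov) - 1
        return float(run[k_star]), "auto-window"
    if truncation == "first-zero":
        nonpos = np.nonzero(acov <= 0)[0]
        if len(nonpos) and nonpos[0] > 0:
            return dt * float(acov[:nonpos[0]].sum()), "first-zero"
        mask = acov > 0.05 * c0
        lags = np.arange(len(acov))[mask]
        slope = np.polyfit(lags, np.log(acov[mask] / c0), 1)[0]
        if slope >= 0:
            return dt * float(acov.sum()), "sum-all"
        return float(c0 * (-dt / slope)), "exp-fit"
    raise ValueError(f"unknown ACF truncation rule {truncation!r}")


def _statistical_inefficiency(x: np.ndarray) -> float:
    """g = 1 + 2 τ_int (in frames); the factor by which correlation
    inflates the variance of the sample mean."""
    acov = autocorrelation(x, max_lag=min(len(x) // 2, 5000))
    if acov[0] <= 0:
        return 1.0
    integral, _ = _integrate_acf(acov, 1.0)
    tau_int = integral / acov[0] - 1.0  # subtract the lag-0 rectangle
    return max(1.0, 1.0 + 2.0 * tau_int)


@dataclass
class WindowDiffusion:
    """Diffusion estimate for one umbrella window."""

    z_mean: float                # Å
    d: float                     # Å²/ps
    variance: float              # Å²
    correlation_time: float      # ps, ∫C dt / var
    method: str                  # ACF truncation used
    drift: float                 # |linear drift over the run| / sd(z)
    drift_flag: bool


def window_diffusion(window: UmbrellaWindow,
                     temperature: float = units.DEFAULT_TEMPERATURE,
                     min_length: int = 1000,
                     max_lag: int | None = None,
                     truncation: str = "auto-window",
                     drift_threshold: float = 1.0) -> WindowDiffusion:
    """Local diffusion coefficient from the restrained z time series.

    Uses the positional-autocorrelation estimator
    D = var(z)² / ∫₀^T* C(t) dt with C(t) = ⟨δz(0) δz(t)⟩ and the
    truncation rule of ``truncation`` ("auto-window" default,
    "first-zero"/"exp-fit" optional).  For an Ornstein–Uhlenbeck process
    this reduces to D = var/τ.  A normalized linear-drift diagnostic flags
    grossly non-stationary windows.
    """
    s = window.load()
    z = s.values
    if len(z) < min_length:
        raise ValueError(f"window series too short ({len(z)} < {min_length})")
    dt = s.dt
    var = float(z.var())
    if var <= 0:
        raise ValueError("window series has zero variance; unusable")
    acov = autocorrelation(z, max_lag=max_lag or len(z) // 2)
    integral, method = _integrate_acf(acov, dt, truncation)
    if integral <= 0:
        raise ValueError("non-positive integrated autocorrelation; window "
                         "flagged as unusable")
    d = var**2 / integral
    t = s.times - s.times[0]
    slope = np.polyfit(t, z, 1)[0]
    drift = abs(slope) * (t[-1] - t[0]) / np.sqrt(var)
    return WindowDiffusion(z_mean=float(z.mean()), d=float(d), variance=var,
                           correlation_time=float(integral / var),
                           method=method, drift=float(drift),
                           drift_flag=bool(drift > drift_threshold))


@dataclass
class DiffusionProfile:
    """Per-window diffusion coefficients assembled into D(z)."""

    z: np.ndarray                # sorted window mean positions, Å
    d: np.ndarray                # Å²/ps
    diagnostics: list[WindowDiffusion] = field(default_factory=list)

    def interp(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Monotone piecewise-linear D on a grid; flat beyond the outermost
        window means, with the extrapolated points flagged."""
        grid = np.asarray(grid, dtype=float)
        vals = np.interp(grid, self.z, self.d)  # np.interp clamps ends
        extrapolated = (grid < self.z[0]) | (grid > self.z[-1])
        return vals, extrapolated


def diffusion_profile(windows: list[UmbrellaWindow],
                      temperature: float = units.DEFAULT_TEMPERATURE,
                      min_length: int = 1000,
                      truncation: str = "auto-window",
                      skip_unusable: bool = True) -> DiffusionProfile:
    """Estimate D in every window and sort the profile by mean position."""
    diags: list[WindowDiffusion] = []
    for w in windows:
        try:
            diags.append(window_diffusion(w, temperature, min_length,
                                          truncation=truncation))
        except ValueError:
            if not skip_unusable:
                raise
            log.warning("window at center %.2f unusable for diffusion; skipped",
                        w.center)
    if len(diags) < 2:
        raise ValueError("fewer than 2 usable windows for a diffusion profile")
    order = np.argsort([d.z_mean for d in diags])
    diags = [diags[i] for i in order]
    return DiffusionProfile(z=np.array([d.z_mean for d in diags]),
                            d=np.array([d.d for d in diags]),
                            diagnostics=diags)


# ---------------------------------------------------------------------------
# permeability
# ---------------------------------------------------------------------------


@dataclass
class PermeabilityResult:
    """Solubility–diffusion permeability over [z1, z2]."""

    resistivity: ZProfile        # R(z) = exp(βw)/D, ps/Å²
    resistance: float            # ps/Å
    permeability: float          # Å/ps
    permeability_cm_s: float
    z1: float
    z2: float
    temperature: float


def permeability(pmf: PMFResult | ZProfile, dprof: DiffusionProfile,
                 z1: float, z2: float,
                 temperature: float = units.DEFAULT_TEMPERATURE,
                 ) -> PermeabilityResult:
    """Integrate the resistivity exp(β w(z))/D(z) over [z1, z2].

    The PMF must already be anchored so the bulk-water plateau is the zero
    of energy — the integral is not gauge invariant.  The profile grid
    restricted to [z1, z2] (with the exact endpoints added by linear
    interpolation) carries the trapezoidal integral; P = 1/R.
    """
    profile = pmf.profile if isinstance(pmf, PMFResult) else pmf
    if z2 <= z1:
        raise ValueError("need z1 < z2")
    c, v = profile.centers, profile.values
    if z1 < c[0] - profile.width / 2 or z2 > c[-1] + profile.width / 2:
        raise ValueError("PMF profile does not cover the integration range")
    if np.any(~np.isfinite(v)):
        raise ValueError("PMF contains unsampled (non-finite) bins in range")
    inner = c[(c > z1) & (c < z2)]
    grid = np.unique(np.concatenate([[z1], inner, [z2]]))
    w_grid = np.interp(grid, c, v)
    d_grid, extrap = dprof.interp(grid)
    if np.any(extrap):
        log.warning("D(z) flat-extrapolated over %d of %d grid points",
                    int(extrap.sum()), len(grid))
    if np.any(d_grid <= 0):
        raise ValueError("non-positive D(z) on the integration grid")
    b = units.beta(temperature)
    r_z = np.exp(b * w_grid) / d_grid
    resistance = float(np.trapezoid(r_z, grid))
    p = 1.0 / resistance
    # resistivity reported on the (possibly non-uniform) grid midpoints is
    # less useful than on the PMF bins; keep the PMF grid portion
    width = profile.width
    mask = (c >= z1 - width / 2) & (c <= z2 + width / 2)
    d_bins, _ = dprof.interp(c[mask])
    r_profile = ZProfile(c[mask], width,
                         np.exp(b * v[mask]) / d_bins, unit="ps/A^2")
    return PermeabilityResult(resistivity=r_profile, resistance=resistance,
                              permeability=p,
                              permeability_cm_s=p * units.ANGSTROM_PER_PS_TO_CM_PER_S,
                              z1=z1, z2=z2, temperature=temperature)
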