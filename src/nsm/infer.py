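"""Per-trajectory estimators and population statistics.

Each trajectory yields two numbers: its integrated optical contrast (the
mean of the per-frame ioc_n), converted to molecular weight through the
contrast–mass relation, and its diffusivity from the covariance-based
estimator (CVE)

    D = <dx_n^2> / (2 dt) + <dx_n dx_{n+1}> / dt,

whose covariance term cancels the bias from static localization noise (and,
for motion-blurred centroids, the blur-induced correlations), converted to
a hydrodynamic radius through the hindered Stokes–Einstein inversion.
Negative CVE estimates — expected for noise-dominated short trajectories —
are preserved and flagged rather than truncated, so population means stay
unbiased.

Populations are summarized by histograms in which each trajectory
contributes N_i / sum(N) counts (longer trajectories carry more evidence),
fitted with Gaussians whose center is the population mean and whose FWHM
(= 2 sqrt(2 ln 2) sigma) defines the resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import ChannelGeometry
from .hydro import HydroContext, stokes_radius_from_diffusivity
from .optics import OpticalModel, mw_from_ioc
from .track import Trajectory

__all__ = [
    "TrajectoryEstimate",
    "PopulationComponent",
    "PopulationResult",
    "trajectory_ioc",
    "cve_diffusivity",
    "characterize",
    "estimates_frame",
    "population_histogram",
    "fit_population",
    "FWHM_FACTOR",
]

#: FWHM of a Gaussian in units of its sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class TrajectoryEstimate:
    """Per-molecule readout: contrast, diffusivity, mass, size."""

    traj_id: int
    N: int
    ioc_nm: float
    D_m2_s: float
    mw_kda: float
    rs_nm: float  # nan when flagged invalid
    weight: float = math.nan  # N / sum(N), assigned at population level
    flags: tuple[str, ...] = ()


def trajectory_ioc(traj: Trajectory) -> float:
    """Integrated optical contrast of a molecule: mean of its ioc_n (nm)."""
    if traj.N < 1:
        raise ValueError("empty trajectory")
    return float(np.mean(traj.ioc_n))


def cve_diffusivity(
    x_nm: np.ndarray,
    dt: float,
    subtract_drift: bool = False,
    frames: np.ndarray | None = None,
    band: tuple[float, float] | None = None,
    band_sigma_factor: float = 4.0,
) -> float:
    """Covariance-based diffusivity estimate in m^2/s.

    ``x_nm`` are positions at uniform intervals ``dt``; with ``frames``
    given, only displacements between consecutive frames enter (gaps from
    missed detections are skipped, both in the square and covariance
    terms).  ``subtract_drift`` removes the mean displacement first (flow
    mode).  The result may be negative for noise-dominated input; it is
    returned as-is so downstream code can flag it.

    ``band`` is the spatial interval over which the molecule was
    observable (the detection band of the field of view).  Displacements
    are only observed when their endpoint stays in the band, which censors
    large outward steps near the edges and biases the estimate low for
    fast molecules.  When the band is given, only displacements *starting*
    more than ``band_sigma_factor`` step-sigmas inside it are used, where
    endpoint censoring is negligible.
    """
    x = np.asarray(x_nm, dtype=float)
    if x.size < 3:
        raise ValueError("CVE needs at least 3 positions (2 displacements)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    dx = np.diff(x)
    if frames is not None:
        frames = np.asarray(frames)
        contiguous = np.diff(frames) == 1
    else:
        contiguous = np.ones(len(dx), dtype=bool)
    if contiguous.sum() < 2:
        raise ValueError("CVE needs at least 2 consecutive-frame displacements")
    if subtract_drift:
        dx = dx - np.mean(dx[contiguous])

    m_sq = contiguous
    m_pair = contiguous[:-1] & contiguous[1:]
    if band is not None:
        sig_step = 1.4826 * float(np.median(np.abs(dx[contiguous])))
        lo = band[0] + band_sigma_factor * sig_step
        hi = band[1] - band_sigma_factor * sig_step
        start_in = (x[:-1] > lo) & (x[:-1] < hi)
        if (m_sq & start_in).sum() >= 10 and (m_pair & start_in[:-1]).sum() >= 5:
            m_sq = m_sq & start_in
            m_pair = m_pair & start_in[:-1]

    sq = float(np.mean(dx[m_sq] ** 2))
    cov = (
        float(np.mean(dx[:-1][m_pair] * dx[1:][m_pair])) if m_pair.sum() else 0.0
    )
    d_nm2_s = sq / (2.0 * dt) + cov / dt
    return d_nm2_s * 1e-18


def characterize(
    traj: Trajectory,
    channel: ChannelGeometry,
    optics: OpticalModel | None = None,
    ctx: HydroContext | None = None,
    flow: bool = False,
) -> TrajectoryEstimate:
    """Full per-trajectory readout: (iOC, D) -> (MW, R_s).

    Conversion failures (non-positive D, confinement out of range) yield a
    flagged estimate with ``rs_nm`` = nan, never a silent drop.
    """
    import dataclasses as _dc

    optics = optics if optics is not None else OpticalModel()
    base = ctx if ctx is not None else HydroContext()
    ctx_eff = _dc.replace(base, equivalent_radius_nm=channel.equivalent_radius_nm)

    ioc = trajectory_ioc(traj)
    mw_kda = mw_from_ioc(ioc, channel.area_nm2, optics) / 1e3
    flags: list[str] = []
    band = traj.flags.get("detection_band")
    try:
        D = cve_diffusivity(
            traj.x, traj.dt, subtract_drift=flow, frames=traj.frames, band=band
        )
    except ValueError:
        D = math.nan
        flags.append("cve_failed")
    rs = math.nan
    if math.isnan(D):
        pass
    elif D <= 0:
        flags.append("nonpositive_D")
    else:
        try:
            rs = stokes_radius_from_diffusivity(D, ctx_eff)
        except ValueError:
            flags.append("unresolvable_confinement")
    return TrajectoryEstimate(
        traj_id=traj.id,
        N=traj.N,
        ioc_nm=ioc,
        D_m2_s=D,
        mw_kda=mw_kda,
        rs_nm=rs,
        flags=tuple(flags),
    )


def estimates_frame(estimates: list[TrajectoryEstimate]) -> pd.DataFrame:
    """Tabulate estimates with N/sum(N) weights (the on-disk CSV layout)."""
    df = pd.DataFrame(
        {
            "traj_id": [e.traj_id for e in estimates],
            "N": [e.N for e in estimates],
            "ioc_nm": [e.ioc_nm for e in estimates],
            "D_um2_s": [e.D_m2_s * 1e12 for e in estimates],
            "mw_kda": [e.mw_kda for e in estimates],
            "rs_nm": [e.rs_nm for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
    total = df["N"].sum()
    df["weight"] = df["N"] / total if total > 0 else np.nan
    return df


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return float(np.interp(q, cw, v))


def population_histogram(
    estimates: list[TrajectoryEstimate] | pd.DataFrame,
    field: str = "mw_kda",
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """N/sum(N)-weighted histogram of a per-trajectory quantity.

    Each trajectory contributes its weight N_i/sum(N) to the bin containing
    its estimate; weights are normalized over the *valid* (finite)
    estimates so the returned counts sum to exactly 1.  Bin width defaults
    to Freedman–Diaconis on the weighted sample (with an effective sample
    size (sum w)^2 / sum w^2).

    Returns (bin_edges, weighted_counts).
    """
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_frame(estimates)
    if field not in df.columns:
        raise KeyError(f"unknown estimate field {field!r}")
    vals = df[field].to_numpy(dtype=float)
    ns = df["N"].to_numpy(dtype=float)
    ok = np.isfinite(vals) & (ns > 0)
    if not ok.any():
        raise ValueError("no valid estimates to histogram")
    vals, ns = vals[ok], ns[ok]
    w = ns / ns.sum()

    if bin_width is None:
        q25 = _weighted_quantile(vals, w, 0.25)
        q75 = _weighted_quantile(vals, w, 0.75)
        iqr = q75 - q25
        n_eff = w.sum() ** 2 / np.sum(w**2)
        bin_width = 2.0 * iqr / n_eff ** (1.0 / 3.0)
        if bin_width <= 0:
            span = vals.max() - vals.min()
            bin_width = span / 10.0 if span > 0 else max(abs(vals[0]) * 1e-3, 1e-12)
    lo, hi = vals.min(), vals.max()
    n_bins = max(int(math.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi * (1 + 1e-12) if hi > 0 else hi + 1e-12)
    counts, edges = np.histogram(vals, bins=edges, weights=w)
    return edges, counts


@dataclass(frozen=True)
class PopulationComponent:
    """One fitted Gaussian population."""

    center: float
    sigma: float
    area: float

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


@dataclass
class PopulationResult:
    """Gaussian decomposition of a weighted population histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[PopulationComponent]
    moment_fallback: bool = False

    @property
    def resolution(self) -> float:
        """FWHM of the principal (largest-area) component."""
        main = max(self.components, key=lambda c: c.area)
        return main.fwhm

    @property
    def mean(self) -> float:
        main = max(self.components, key=lambda c: c.area)
        return main.center

    def summary(self) -> dict:
        return {
            "components": [
                {"center": c.center, "sigma": c.sigma, "fwhm": c.fwhm, "area": c.area}
                for c in self.components
            ],
            "mean": self.mean,
            "resolution_fwhm": self.resolution,
            "moment_fallback": self.moment_fallback,
        }


def _gauss_mixture(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sig = params[i : i + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_population(
    histogram: tuple[np.ndarray, np.ndarray],
    n_components: int = 1,
    init: list[tuple[float, float, float]] | None = None,
) -> PopulationResult:
    """Least-squares Gaussian fit to a weighted histogram.

    ``init`` supplies per-component (area, center, sigma) starting values;
    required for ``n_components`` >= 2 (no automatic model selection).  For
    a single component the fit is seeded from the histogram mode.  When the
    histogram has too few populated bins to constrain a fit (< 5 per
    component) the result falls back to weighted moments with the FWHM
    floored at one bin width, and is marked ``moment_fallback``.
    """
    edges, counts = histogram
    edges = np.asarray(edges, float)
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("degenerate (empty) histogram")
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    populated = int(np.count_nonzero(counts))

    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components >= 2 and init is None:
        raise ValueError("multi-component fits require explicit initialization")

    bw = float(np.median(widths))
    if populated < 5 * n_components:
        mean = float(np.sum(centers * counts) / counts.sum())
        var = float(np.sum((centers - mean) ** 2 * counts) / counts.sum())
        sigma = max(math.sqrt(var), bw / FWHM_FACTOR)
        comp = PopulationComponent(center=mean, sigma=sigma, area=float(counts.sum()))
        return PopulationResult(edges, counts, [comp], moment_fallback=True)

    if init is None:
        imode = int(np.argmax(counts))
        mu0 = float(centers[imode])
        # second-moment width around the mode as a starting sigma
        mean = float(np.sum(centers * counts) / counts.sum())
        var = float(np.sum((centers - mean) ** 2 * counts) / counts.sum())
        sig0 = max(math.sqrt(var), bw / 2.0)
        a0 = float(counts.max())
        p0 = [a0, mu0, sig0]
    else:
        p0 = []
        for area, mu, sig in init:
            p0 += [area / (sig * math.sqrt(2 * math.pi)) * bw, mu, sig]

    lower = [0.0, -np.inf, bw * 1e-3] * n_components
    upper = [np.inf, np.inf, np.inf] * n_components
    try:
        popt, _ = curve_fit(
            _gauss_mixture, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as err:
        raise ValueError(f"population fit did not converge: {err}") from err

    comps = []
    for i in range(0, len(popt), 3):
        a, mu, sig = popt[i : i + 3]
        comps.append(
            PopulationComponent(
                center=float(mu),
                sigma=float(sig),
                area=float(a * sig * math.sqrt(2 * math.pi) / bw),
            )
        )
    comps.sort(key=lambda c: -c.area)
    return PopulationResult(edges, counts, comps)
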