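"""Synthetic data with known ground truth: electrophysiology runs and junction meshes.

The monolayer simulator is a phenomenological stand-in for an MDCK-II-like
epithelium.  Its latent state is the selectivity ratio beta(t) = P_Na/P_Cl and
the transepithelial conductance G(t); both relax exponentially toward a
condition-dependent target within each bath epoch: under a relative apical
hyposmotic gradient beta decays from its resting value (~9-22) toward a low
plateau (~3) over ~2 h, and recovers within minutes once the gradient is
removed.  Measured series add volt-ohm-meter noise and blank-filter offsets
(series resistance, liquid-junction potential surrogate); the noiseless latent
series is returned alongside as ground truth.

The mesh generator emulates ZO-1-traced junction networks: a seeded Voronoi
tessellation whose straight edges are replaced by symmetric sawtooth polylines
with slope 2a/p, so the exact zigzag index sqrt(1 + (2a/p)^2) is known by
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import KDTree, QhullError, Voronoi

from .ghk import ghk_forward_potential, kk_conductance, kk_split_permeabilities
from .morphometry import ContactEdge, ContactGraph
from .physics import BODY_TEMP, PhysicalContext
from .protocols import CONDITION_PRESETS, ConditionPreset, ISOSMOTIC_BAND
from .series import MeasurementSeries
from .solutions import BathPair

__all__ = [
    "MonolayerModel",
    "NoiseModel",
    "MeshSpec",
    "simulate_run",
    "preset_library",
    "generate_mesh",
    "label_mask",
]


@dataclass(frozen=True)
class MonolayerModel:
    """Latent monolayer state: piecewise-exponential beta(t) and G(t).

    Within a bath epoch carrying the osmotic stimulus (apical-minus-basal
    nominal osmolarity below -50 mOsm/L), beta relaxes from its epoch-start
    value toward ``beta_inf`` with time constant ``tau`` and G toward
    ``g_inf`` alike; in unstimulated epochs both relax toward their resting
    targets (``beta_rec``/``g_rec``, defaulting to the initial values) with
    the fast recovery constant ``tau_rec``.  A monolayer starting at rest
    under no gradient therefore stays constant.
    """

    beta0: float
    beta_inf: float
    tau: float
    g0: float
    g_inf: float
    condition: ConditionPreset
    tau_rec: float = 1.0
    beta_rec: float | None = None
    g_rec: float | None = None

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_inf", "tau", "g0", "g_inf", "tau_rec"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def _targets(self, baths: BathPair) -> tuple[float, float, float]:
        """(beta_target, g_target, tau) for an epoch under the given baths."""
        if baths.osmotic_gradient < -ISOSMOTIC_BAND:
            return self.beta_inf, self.g_inf, self.tau
        beta_rest = self.beta0 if self.beta_rec is None else self.beta_rec
        g_rest = self.g0 if self.g_rec is None else self.g_rec
        return beta_rest, g_rest, self.tau_rec

    def latent(self, time: np.ndarray) -> pd.DataFrame:
        """Noise-free (beta, G) at the given times (minutes, ascending)."""
        time = np.asarray(time, dtype=float)
        if time.size and (np.any(np.diff(time) <= 0) or time[0] < 0):
            raise ValueError("time grid must be strictly increasing and >= 0")
        schedule = self.condition.schedule()
        t_end = float(time[-1]) + 1.0 if time.size else 1.0
        beta_vals = np.empty_like(time)
        g_vals = np.empty_like(time)
        beta_start, g_start = self.beta0, self.g0
        for t0, t1, baths in schedule.epochs(t_end):
            b_tgt, g_tgt, tau = self._targets(baths)
            sel = (time >= t0) & (time < t1)
            decay = np.exp(-(time[sel] - t0) / tau)
            beta_vals[sel] = b_tgt + (beta_start - b_tgt) * decay
            g_vals[sel] = g_tgt + (g_start - g_tgt) * decay
            end_decay = math.exp(-(t1 - t0) / tau)
            beta_start = b_tgt + (beta_start - b_tgt) * end_decay
            g_start = g_tgt + (g_start - g_tgt) * end_decay
        return pd.DataFrame({"time_min": time, "beta": beta_vals, "g_s_cm2": g_vals})


@dataclass(frozen=True)
class NoiseModel:
    """Measurement artifacts: meter noise plus blank-filter offsets.

    sigma_v/sigma_r are Gaussian SDs on each potential (mV) and resistance
    (Ohm cm^2) reading; ``blank_r`` is the cell-free filter's series
    resistance and ``blank_v_offset`` a liquid-junction potential surrogate,
    optionally drifting linearly at ``blank_v_drift`` mV/min.
    """

    sigma_v: float = 0.2
    sigma_r: float = 1.0
    blank_r: float = 25.0
    blank_v_offset: float = -1.5
    blank_v_drift: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_v < 0 or self.sigma_r < 0:
            raise ValueError("noise SDs must be >= 0")


def simulate_run(
    model: MonolayerModel,
    noise: NoiseModel,
    grid: np.ndarray,
    rng: np.random.Generator | None = None,
    ctx: PhysicalContext = BODY_TEMP,
    kk_variant: str = "log_mean",
) -> tuple[MeasurementSeries, MeasurementSeries, pd.DataFrame]:
    """Simulate one run: (sample series, blank series, ground-truth table).

    The latent (beta, G) at each grid time map to the true dilution potential
    (GHK forward) and TER = 1/G; the sample reading adds the blank filter's
    resistance and potential offset plus Gaussian meter noise, and the blank
    series carries the offsets with independent noise.  Fully reproducible
    from ``rng`` (or ``noise.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    grid = np.asarray(grid, dtype=float)
    truth = model.latent(grid)
    schedule = model.condition.schedule()

    v_true = np.empty_like(grid)
    p_na = np.empty_like(grid)
    p_cl = np.empty_like(grid)
    for i, t in enumerate(grid):
        baths = schedule.baths_at(t)
        beta = truth["beta"].iloc[i]
        v_true[i] = ghk_forward_potential(beta, baths, ctx)
        split = kk_split_permeabilities(1.0 / truth["g_s_cm2"].iloc[i], beta,
                                        baths, ctx, kk_variant)
        p_na[i], p_cl[i] = split.p_na, split.p_cl
    ter_true = 1.0 / truth["g_s_cm2"].to_numpy()
    truth = truth.assign(ter_ohm_cm2=ter_true, dilution_potential_mV=v_true,
                         p_na_cm_s=p_na, p_cl_cm_s=p_cl)

    blank_v = noise.blank_v_offset + noise.blank_v_drift * grid
    sample = MeasurementSeries(
        time=grid,
        resistance=ter_true + noise.blank_r + rng.normal(0, noise.sigma_r, grid.size),
        potential=v_true + blank_v + rng.normal(0, noise.sigma_v, grid.size),
        label="sample",
    )
    blank = MeasurementSeries(
        time=grid,
        resistance=noise.blank_r + rng.normal(0, noise.sigma_r, grid.size),
        potential=blank_v + rng.normal(0, noise.sigma_v, grid.size),
        label="blank",
    )
    return sample, blank, truth


def _two_point_exponential(t1: float, y1: float, t2: float, y2: float,
                           tau: float) -> tuple[float, float]:
    """(y0, y_inf) of y(t) = y_inf + (y0 - y_inf) e^(-t/tau) through two anchors."""
    e1, e2 = math.exp(-t1 / tau), math.exp(-t2 / tau)
    amp = (y1 - y2) / (e1 - e2)
    y_inf = y1 - amp * e1
    return y_inf + amp, y_inf


def _recovery_target(y_switch: float, y_post: float, dt: float, tau_rec: float) -> float:
    """Resting target hit so that y(switch + dt) equals ``y_post``."""
    e = math.exp(-dt / tau_rec)
    return (y_post - y_switch * e) / (1.0 - e)


def preset_library(ctx: PhysicalContext = BODY_TEMP) -> dict[str, MonolayerModel]:
    """Named illustrative monolayer models for the main experimental patterns.

    The conductance levels are chosen so absolute permeabilities fall in the
    few x 10^-5 cm/s range typical of a leaky claudin-2-positive monolayer
    (TER ~ 50 Ohm cm^2); the knockout model is a tight, gradient-insensitive
    monolayer (low G, beta ~ 1).  The reversibility model is anchored so the
    noise-free pipeline reproduces the characteristic selectivity triple
    (22.41 / 3.40 / 16.55 at 5 / 120 / 125 min) and the matching P_Na values.
    The values parameterize plausible runs; they are not fits to data.
    """
    hypo = CONDITION_PRESETS["apical_hyposmotic"]
    iso = CONDITION_PRESETS["apical_isosmotic"]
    rev = CONDITION_PRESETS["reversibility"]
    baths_hypo = BathPair(hypo.apical, hypo.basal)
    baths_iso_after = rev.switch_events[0][1]

    tau = 30.0       # min; beta roughly plateaus within the 2-h observation
    tau_rec = 1.0    # min; recovery is essentially complete within 5 min

    g_wt = kk_conductance(45e-6, 9.32, baths_hypo, ctx)

    # reversibility model anchored to the characteristic triples
    b0_rev, binf_rev = _two_point_exponential(5.0, 22.41, 120.0, 3.40, tau)
    g5 = kk_conductance(46.20e-6, 22.41, baths_hypo, ctx)
    g120 = kk_conductance(33.46e-6, 3.40, baths_hypo, ctx)
    g0_rev, ginf_rev = _two_point_exponential(5.0, g5, 120.0, g120, tau)
    beta_switch = binf_rev + (b0_rev - binf_rev) * math.exp(-120.0 / tau)
    g_switch = ginf_rev + (g0_rev - ginf_rev) * math.exp(-120.0 / tau)
    beta_rec = _recovery_target(beta_switch, 16.55, 5.0, tau_rec)
    g125 = kk_conductance(27.13e-6, 16.55, baths_iso_after, ctx)
    g_rec = _recovery_target(g_switch, g125, 5.0, tau_rec)

    g_ko = kk_conductance(2e-6, 1.1, baths_hypo, ctx)

    return {
        "wt_iso": MonolayerModel(beta0=9.32, beta_inf=9.32, tau=tau,
                                 g0=g_wt, g_inf=g_wt, condition=iso,
                                 tau_rec=tau_rec),
        "wt_hypo": MonolayerModel(beta0=9.0, beta_inf=3.0, tau=tau,
                                  g0=g_wt, g_inf=0.8 * g_wt, condition=hypo,
                                  tau_rec=tau_rec),
        "wt_reversibility": MonolayerModel(beta0=b0_rev, beta_inf=binf_rev, tau=tau,
                                           g0=g0_rev, g_inf=ginf_rev, condition=rev,
                                           tau_rec=tau_rec, beta_rec=beta_rec,
                                           g_rec=g_rec),
        "ko": MonolayerModel(beta0=1.1, beta_inf=1.1, tau=tau,
                             g0=g_ko, g_inf=g_ko, condition=hypo,
                             tau_rec=tau_rec),
        "rescue": MonolayerModel(beta0=9.0, beta_inf=3.0, tau=tau,
                                 g0=g_wt, g_inf=0.8 * g_wt, condition=hypo,
                                 tau_rec=tau_rec),
    }


# ---------------------------------------------------------------------------
# junction meshes


@dataclass(frozen=True)
class MeshSpec:
    """Voronoi mesh of an epithelial sheet with sawtooth edge jaggedness.

    ``jag_amplitude`` (a, um) and ``jag_period`` (p, um) set the sawtooth
    slope 2a/p of every edge; a = 0 yields straight edges.  The analytic
    zigzag index of the resulting network is sqrt(1 + (2a/p)^2).
    """

    n_cells: int = 600
    field: tuple[float, float] = (200.0, 200.0)
    jag_amplitude: float = 0.75
    jag_period: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.jag_amplitude < 0 or self.jag_period <= 0:
            raise ValueError("need jag_amplitude >= 0 and jag_period > 0")

    @property
    def expected_index(self) -> float:
        return math.sqrt(1.0 + (2.0 * self.jag_amplitude / self.jag_period) ** 2)


def _sawtooth(p0: np.ndarray, p1: np.ndarray, amplitude: float,
              period: float) -> np.ndarray:
    """Symmetric sawtooth polyline from p0 to p1 with exact slope 2a/p.

    The number of half-periods is rounded to the chord length and kept even so
    the polyline starts and ends on the chord; the amplitude is rescaled with
    the rounded period so every segment has lateral slope exactly 2a/p,
    making the arc/chord ratio sqrt(1 + (2a/p)^2) independent of edge length.
    """
    chord = p1 - p0
    length = float(np.hypot(*chord))
    if amplitude == 0.0 or length == 0.0:
        return np.vstack([p0, p1])
    n_seg = max(2, 2 * round(length / period))
    a_eff = (2.0 * amplitude / period) * (length / n_seg)
    tangent = chord / length
    normal = np.array([-tangent[1], tangent[0]])
    along = np.linspace(0.0, length, n_seg + 1)
    lateral = np.where(np.arange(n_seg + 1) % 2 == 1, a_eff, 0.0)
    return p0 + along[:, None] * tangent + lateral[:, None] * normal


def generate_mesh(spec: MeshSpec, rng: np.random.Generator | None = None) -> ContactGraph:
    """Seeded Voronoi tessellation with sawtooth-jagged edges.

    Only ridges whose both vertices fall inside the field are kept (border
    cells with unbounded ridges are trimmed away).  Degenerate seeding is
    retried with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w, h = spec.field
    for attempt in range(5):
        points = rng.uniform((0.0, 0.0), (w, h), size=(spec.n_cells, 2))
        try:
            vor = Voronoi(points)
            break
        except QhullError:
            warnings.warn("degenerate Voronoi seeding; re-drawing points")
    else:
        raise RuntimeError("could not build a non-degenerate tessellation")

    inside = ((vor.vertices[:, 0] >= 0) & (vor.vertices[:, 0] <= w)
              & (vor.vertices[:, 1] >= 0) & (vor.vertices[:, 1] <= h))
    vertices: dict[int, tuple[float, float]] = {}
    edges: list[ContactEdge] = []
    for v1, v2 in vor.ridge_vertices:
        if v1 < 0 or v2 < 0 or not (inside[v1] and inside[v2]):
            continue
        p0, p1 = vor.vertices[v1], vor.vertices[v2]
        poly = _sawtooth(p0, p1, spec.jag_amplitude, spec.jag_period)
        for vid, pt in ((v1, p0), (v2, p1)):
            vertices.setdefault(vid, (float(pt[0]), float(pt[1])))
        edges.append(ContactEdge(int(v1), int(v2), poly))
    return ContactGraph(vertices=vertices, edges=edges, field_extent=(0.0, 0.0, w, h))


def label_mask(spec: MeshSpec, pixel_size: float = 0.25) -> np.ndarray:
    """Rasterized cell-label image of the tessellation (labels 1..n_cells).

    Pixels take the label of the nearest Voronoi seed, i.e. the straight-edge
    (a = 0) tessellation; edge jaggedness is a polyline-level property and is
    not rasterized.  Uses the same seeded point draw as :func:`generate_mesh`.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.field
    points = rng.uniform((0.0, 0.0), (w, h), size=(spec.n_cells, 2))
    nx, ny = int(round(w / pixel_size)), int(round(h / pixel_size))
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    _, idx = KDTree(points).query(np.column_stack([gx.ravel(), gy.ravel()]))
    return (idx.reshape(ny, nx) + 1).astype(np.int32)
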