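"""Synthetic phantoms and cohorts with the structure the pipeline assumes.

Two generators are provided:

* velocity phantoms plus a forward advection-decay tracer simulator, used to
  validate the transport-equation velocity reconstruction; and
* a cohort generator emulating a three-group (NC / MCI / AD) memory-clinic
  study: group-dependent cognitive-score distributions, regional perfusion
  velocities carrying a planted lag-1 driver structure along the cognition
  ordering, group-level velocity reductions in the non-vertebrobasilar
  territories, and an interstitial-fluid (ALPS) index with a weak positive
  association to mean velocity.

The forward simulator uses conservative flux-form first-order upwind
advection with explicit sub-stepping (CFL number <= 0.5) and exact
exponential decay per sub-step, so that the zero-velocity case reproduces
pure T1 decay to machine precision and closed or periodic boundaries
conserve total tracer exactly when the decay rate is zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .qtm_model import TracerSeries, VelocityField, velocity_magnitude

PHANTOM_PATTERNS = ("zero", "uniform", "piecewise_blocks", "rotational")

# Recruitment bookkeeping the default cohort emulates: 168 volunteers, 12
# unable to complete neuropsychological testing, 6 with unusable MRI.
RECRUITED = 168
EXCLUDED_NEUROPSYCH = 12
EXCLUDED_IMAGING = 6

#: 26 arterial-territory abbreviations (13 per hemisphere), emulating the
#: conventions of public arterial atlases: anterior/middle/posterior cerebral
#: artery subdivisions, perforator territories and vertebrobasilar regions.
TERRITORY_NAMES = [
    "ACAL", "ACAR", "MCAFL", "MCAFR", "MCAIL", "MCAIR", "MCAPL", "MCAPR",
    "MCATL", "MCATR", "MCAOL", "MCAOR", "MLSL", "MLSR", "LLSL", "LLSR",
    "ACTPL", "ACTPR", "PCATL", "PCATR", "PCAOL", "PCAOR",
    "VBL", "VBR", "CBLL", "CBLR",
]

#: Territories supplied by the vertebrobasilar system; by default these carry
#: no group effect, mirroring a cortical-predominant disease pattern.
VB_TERRITORIES = ("VBL", "VBR", "CBLL", "CBLR")

# Per-group demographics and cognition: (mean, sd) or counts.
GROUP_PARAMS = {
    "NC": {
        "n": 28, "age": (69.61, 6.65), "female_frac": 17 / 28,
        "education_years": (13.68, 3.95), "mmse": (28.54, 1.55),
        "ravlt_immediate": (6.37, 1.69), "ravlt_delayed": (6.14, 2.01),
        "tmt_a": (65.36, 25.21), "tmt_b": (148.07, 42.52), "vft": (19.93, 4.07),
    },
    "MCI": {
        "n": 85, "age": (67.56, 5.82), "female_frac": 48 / 85,
        "education_years": (10.10, 3.81), "mmse": (24.80, 3.80),
        "ravlt_immediate": (4.23, 1.63), "ravlt_delayed": (3.40, 2.44),
        "tmt_a": (94.59, 44.05), "tmt_b": (199.87, 55.12), "vft": (13.95, 5.13),
    },
    "AD": {
        "n": 37, "age": (71.78, 8.41), "female_frac": 27 / 37,
        "education_years": (9.58, 3.95), "mmse": (16.57, 7.40),
        "ravlt_immediate": (2.86, 1.94), "ravlt_delayed": (2.19, 2.61),
        "tmt_a": (167.03, 79.96), "tmt_b": (274.05, 35.33), "vft": (9.03, 4.23),
    },
}


@dataclass
class PhantomSpec:
    grid_shape: tuple = (16, 16, 16)
    voxel_size: tuple = (2.5, 2.5, 3.0)
    pattern: str = "piecewise_blocks"
    peak_speed: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.grid_shape) != 3 or any(n < 3 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, each >= 3")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")
        if self.pattern not in PHANTOM_PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PHANTOM_PATTERNS}")


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    The planted lag-1 structure lives on the cognition ordering: after
    subjects are ranked by MMSE (ties broken by immediate recall), the
    driver region's velocity series leads each target region by one rank
    step with standardized coefficient ``driver_coefficient``.  Target
    innovations are scaled by sqrt(1 - coef^2) so every regional series has
    marginal SD ``noise_sd`` and the standardized lag-1 coefficient equals
    the planted value.
    """

    n_per_group: tuple = (28, 85, 37)  # NC, MCI, AD
    n_regions: int = 26
    driver_region: int = 8  # MCATL in the default 26-territory layout
    driver_coefficient: float = 0.6
    driver_targets: Optional[Sequence[int]] = None  # default: all other regions
    noise_sd: float = 1.0
    alps_association: float = 0.25
    base_velocity: float = 5.0
    group_effect: tuple = (0.0, -0.5, -1.0)  # NC, MCI, AD shifts (in noise_sd units)
    affected_regions: Optional[Sequence[int]] = None  # default: non-VB territories
    seed: int = 0

    def __post_init__(self):
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group counts must be >= 0")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 0 <= self.driver_region < self.n_regions:
            raise ValueError("driver_region out of range")
        if abs(self.driver_coefficient) >= 1:
            raise ValueError("|driver_coefficient| must be < 1 for stationarity")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


# ---------------------------------------------------------------------------
# velocity phantoms


def region_names(n_regions: int) -> list:
    """Territory abbreviations when the full 26-region layout is used,
    the 22 non-vertebrobasilar names for n=22, generic names otherwise."""
    if n_regions == 26:
        return list(TERRITORY_NAMES)
    non_vb = [n for n in TERRITORY_NAMES if n not in VB_TERRITORIES]
    if n_regions == len(non_vb):
        return non_vb
    return [f"R{i+1:02d}" for i in range(n_regions)]


def generate_phantom_velocity(spec: PhantomSpec) -> VelocityField:
    """Seeded synthetic velocity field on the phantom grid."""
    shape = spec.grid_shape
    mask = np.ones(shape, dtype=bool)
    comps = np.zeros(shape + (3,))
    rng = np.random.default_rng(spec.seed)

    if spec.pattern == "zero":
        pass
    elif spec.pattern == "uniform":
        comps[...] = spec.peak_speed / np.sqrt(3.0)
    elif spec.pattern == "piecewise_blocks":
        # constant random vector per octant, scaled so the peak magnitude
        # equals peak_speed
        halves = [s // 2 for s in shape]
        vecs = rng.standard_normal((2, 2, 2, 3))
        mags = np.linalg.norm(vecs, axis=-1)
        vecs *= spec.peak_speed / mags.max()
        for bx in range(2):
            for by in range(2):
                for bz in range(2):
                    sl = tuple(
                        slice(b * h, None if b else h)
                        for b, h in zip((bx, by, bz), halves)
                    )
                    comps[sl] = vecs[bx, by, bz]
    elif spec.pattern == "rotational":
        # solid-body rotation about the z axis: divergence free
        axes = [(np.arange(n) - (n - 1) / 2) * v for n, v in zip(shape, spec.voxel_size)]
        X, Y, _ = np.meshgrid(*axes, indexing="ij")
        rmax = np.sqrt(X**2 + Y**2).max()
        omega = spec.peak_speed / max(rmax, 1e-12)
        comps[..., 0] = -omega * Y
        comps[..., 1] = omega * X
    return VelocityField(comps, velocity_magnitude(comps, mask), mask)


def smooth_random_concentration(
    shape, seed: int = 0, smooth_vox: float = 2.5, low: float = 0.2, high: float = 1.0
) -> np.ndarray:
    """Positive smoothly varying concentration with structure at every voxel,
    built by Gaussian-filtering white noise and rescaling to [low, high]."""
    rng = np.random.default_rng(seed)
    c = gaussian_filter(rng.standard_normal(shape), smooth_vox, mode="nearest")
    c = (c - c.min()) / max(c.max() - c.min(), 1e-12)
    return low + (high - low) * c


# ---------------------------------------------------------------------------
# forward tracer simulation


def _axis_flux_divergence(c, u, axis, dx, boundary, mask):
    """Divergence of the upwind flux along one axis (flux form)."""
    cm = np.moveaxis(c, axis, 0)
    um = np.moveaxis(u[..., axis], axis, 0)
    n = cm.shape[0]
    if boundary == "periodic":
        c_r = np.roll(cm, -1, axis=0)
        uf = 0.5 * (um + np.roll(um, -1, axis=0))  # face between k and k+1
        flux = np.where(uf > 0, uf * cm, uf * c_r)
        if mask is not None:
            mm = np.moveaxis(mask, axis, 0)
            open_face = mm & np.roll(mm, -1, axis=0)
            flux = np.where(open_face, flux, 0.0)
        div = (flux - np.roll(flux, 1, axis=0)) / dx
    else:  # closed: zero flux through the domain (and mask) boundary
        uf = 0.5 * (um[:-1] + um[1:])
        flux = np.where(uf > 0, uf * cm[:-1], uf * cm[1:])
        if mask is not None:
            mm = np.moveaxis(mask, axis, 0)
            open_face = mm[:-1] & mm[1:]
            flux = np.where(open_face, flux, 0.0)
        div = np.zeros_like(cm)
        div[:-1] += flux / dx
        div[1:] -= flux / dx
    return np.moveaxis(div, 0, axis)


def simulate_tracer_series(
    velocity: VelocityField,
    initial: np.ndarray,
    pld_times: Sequence[float],
    decay_rate: float = 1.0 / 1.65,
    voxel_size: Sequence[float] = (2.5, 2.5, 3.0),
    boundary: str = "closed",
    cfl: float = 0.5,
    max_substeps: int = 100_000,
) -> TracerSeries:
    """Advect and decay an initial concentration to each post-labeling delay.

    Conservative first-order upwind advection with explicit sub-stepping;
    the sub-step satisfies sum_axes max|u_a| * dt / dx_a <= ``cfl``.  Decay
    is applied as an exact exponential factor per sub-step, so u = 0
    reproduces initial * exp(-decay_rate * t) to machine precision.
    """
    if boundary not in ("closed", "periodic"):
        raise ValueError("boundary must be 'closed' or 'periodic'")
    pld_times = np.asarray(pld_times, dtype=float)
    if np.any(np.diff(pld_times) <= 0) or np.any(pld_times <= 0):
        raise ValueError("pld_times must be positive and strictly increasing")
    voxel_size = np.asarray(voxel_size, dtype=float)
    c = np.asarray(initial, dtype=float).copy()
    if c.shape != velocity.components.shape[:3]:
        raise ValueError("initial volume does not match the velocity grid")
    u = velocity.components
    mask = velocity.mask
    mask_is_full = bool(mask.all())
    face_mask = None if mask_is_full else mask

    rate = sum(
        np.max(np.abs(u[..., a])) / voxel_size[a] for a in range(3)
    )
    times = np.concatenate([[0.0], pld_times])
    volumes = []
    for k in range(pld_times.size):
        span = times[k + 1] - times[k]
        if rate > 0:
            n_sub = int(np.ceil(span * rate / cfl))
            if n_sub > max_substeps:
                raise ValueError(
                    f"velocity too large: {n_sub} sub-steps needed, cap is {max_substeps}"
                )
        else:
            n_sub = 1
        dt = span / n_sub
        decay = np.exp(-decay_rate * dt)
        for _ in range(n_sub):
            div = sum(
                _axis_flux_divergence(c, u, a, voxel_size[a], boundary, face_mask)
                for a in range(3)
            )
            c = (c - dt * div) * decay
        volumes.append(c.copy())

    return TracerSeries(
        np.stack(volumes, axis=-1), mask, pld_times, voxel_size
    )


def block_phantom_experiment(
    grid: int = 32,
    seed: int = 0,
    peak_speed: float = 2.0,
    pld_times: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5),
    decay_rate: float = 1.0 / 1.65,
    voxel_size: Sequence[float] = (2.5, 2.5, 3.0),
    snr: Optional[float] = None,
    supersample: int = 2,
):
    """Standard recovery experiment: piecewise-block velocity phantom and the
    tracer series it generates at the 5-delay schedule (0.5-2.5 s).

    Returns (tracer, truth).  ``snr`` adds Gaussian noise with SD equal to
    the mean signal divided by snr.  The forward simulation runs on a grid
    refined by ``supersample`` per axis and is block-averaged back to the
    observation grid, which curbs the upwind scheme's numerical diffusion
    and avoids committing an inverse crime.
    """
    spec = PhantomSpec(
        grid_shape=(grid, grid, grid),
        voxel_size=tuple(voxel_size),
        pattern="piecewise_blocks",
        peak_speed=peak_speed,
        seed=seed,
    )
    truth = generate_phantom_velocity(spec)
    initial = smooth_random_concentration(spec.grid_shape, seed=seed + 1)

    s = int(supersample)
    if s > 1:
        fine_shape = tuple(s * n for n in spec.grid_shape)
        fine_voxel = tuple(v / s for v in voxel_size)
        comps_f = np.repeat(
            np.repeat(np.repeat(truth.components, s, 0), s, 1), s, 2
        )
        mask_f = np.ones(fine_shape, dtype=bool)
        truth_f = VelocityField(comps_f, velocity_magnitude(comps_f, mask_f), mask_f)
        init_f = np.repeat(np.repeat(np.repeat(initial, s, 0), s, 1), s, 2)
        tracer_f = simulate_tracer_series(
            truth_f, init_f, pld_times, decay_rate=decay_rate, voxel_size=fine_voxel
        )
        # block-average back to the observation grid
        cf = tracer_f.concentration.reshape(grid, s, grid, s, grid, s, -1)
        coarse = cf.mean(axis=(1, 3, 5))
        tracer = TracerSeries(coarse, truth.mask, np.asarray(pld_times), np.asarray(voxel_size))
    else:
        tracer = simulate_tracer_series(
            truth, initial, pld_times, decay_rate=decay_rate, voxel_size=voxel_size
        )
    if snr is not None:
        rng = np.random.default_rng(seed + 2)
        sigma = np.mean(np.abs(tracer.concentration)) / snr
        tracer = TracerSeries(
            tracer.concentration + rng.normal(0, sigma, tracer.concentration.shape),
            tracer.mask,
            tracer.pld_times,
            tracer.voxel_size,
        )
    return tracer, truth


# ---------------------------------------------------------------------------
# cohort generation


def _truncnorm(rng, mean, sd, size, lo=None, hi=None, decimals=None):
    x = rng.normal(mean, sd, size)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    if decimals is not None:
        x = np.round(x, decimals)
    return x


def rank_order(mmse, recall, ids):
    """Indices sorting subjects best-to-worst cognition: MMSE descending,
    ties broken by immediate recall descending, then id ascending."""
    df = pd.DataFrame({"mmse": mmse, "recall": recall, "id": ids})
    return df.sort_values(
        ["mmse", "recall", "id"], ascending=[False, False, True], kind="mergesort"
    ).index.to_numpy()


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic cohort table: demographics, cognition, regional velocities
    and ALPS index, one row per subject.

    Regional velocity columns are named ``vel_<territory>``.  The planted
    lag-1 driver structure is laid down along the cognition ranking computed
    with the same rule the analysis uses, so downstream ranking recovers it.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ("NC", "MCI", "AD")
    rows = []
    sid = 0
    for g, n in zip(groups, spec.n_per_group):
        p = GROUP_PARAMS[g]
        female = rng.random(n) < p["female_frac"]
        age = _truncnorm(rng, *p["age"], n, 55, 90, 1)
        edu = _truncnorm(rng, *p["education_years"], n, 0, 25, 0)
        mmse = _truncnorm(rng, *p["mmse"], n, 0, 30, 0)
        imm = _truncnorm(rng, *p["ravlt_immediate"], n, 0, 15, 1)
        dly = _truncnorm(rng, *p["ravlt_delayed"], n, 0, 15, 0)
        tmta = _truncnorm(rng, *p["tmt_a"], n, 10, 400, 0)
        tmtb = _truncnorm(rng, *p["tmt_b"], n, 20, 500, 0)
        vft = _truncnorm(rng, *p["vft"], n, 0, 40, 0)
        for i in range(n):
            sid += 1
            rows.append(
                dict(
                    subject_id=f"S{sid:03d}",
                    diagnosis=g,
                    age=age[i],
                    sex="F" if female[i] else "M",
                    education_years=edu[i],
                    mmse=mmse[i],
                    ravlt_immediate=imm[i],
                    ravlt_delayed=dly[i],
                    tmt_a=tmta[i],
                    tmt_b=tmtb[i],
                    vft=vft[i],
                )
            )
    cohort = pd.DataFrame(rows)
    n_total = len(cohort)
    R = spec.n_regions
    names = region_names(R)

    if n_total > 0:
        order = rank_order(
            cohort["mmse"].to_numpy(),
            cohort["ravlt_immediate"].to_numpy(),
            cohort["subject_id"].to_numpy(),
        )

        # lag-1 driver structure along the cognition ordering
        a = spec.driver_coefficient
        d = spec.driver_region
        targets = (
            sorted(set(range(R)) - {d})
            if spec.driver_targets is None
            else sorted(set(int(t) for t in spec.driver_targets) - {d})
        )
        if any(t >= R or t < 0 for t in targets):
            raise ValueError("driver target out of range")
        X = rng.normal(0.0, spec.noise_sd, (n_total, R))
        for t in range(1, n_total):
            for j in targets:
                X[t, j] = a * X[t - 1, d] + np.sqrt(1 - a**2) * X[t, j]

        # group-level velocity shifts in the affected territories
        affected = (
            [i for i, nm in enumerate(names) if nm not in VB_TERRITORIES]
            if spec.affected_regions is None
            else list(spec.affected_regions)
        )
        shift = dict(zip(groups, spec.group_effect))
        diag_ranked = cohort["diagnosis"].to_numpy()[order]
        offsets = np.zeros((n_total, R))
        for t in range(n_total):
            offsets[t, affected] = shift[diag_ranked[t]] * spec.noise_sd
        vel_ranked = np.maximum(spec.base_velocity + offsets + X, 0.0)

        vel = np.empty_like(vel_ranked)
        vel[order] = vel_ranked
        for j, nm in enumerate(names):
            cohort[f"vel_{nm}"] = vel[:, j]

        # ALPS index correlated with subject-mean velocity
        rho = spec.alps_association
        mean_vel = vel.mean(axis=1)
        zv = (mean_vel - mean_vel.mean()) / max(mean_vel.std(), 1e-12)
        noise = rng.standard_normal(n_total)
        cohort["alps_index"] = 1.5 + 0.2 * (rho * zv + np.sqrt(1 - rho**2) * noise)
    else:
        for nm in names:
            cohort[f"vel_{nm}"] = pd.Series(dtype=float)
        cohort["alps_index"] = pd.Series(dtype=float)

    return cohort


def synthetic_atlas(shape, n_regions: int = 26) -> np.ndarray:
    """Integer-labeled volume partitioning the grid into ``n_regions``
    contiguous chunks (labels 1..n_regions, 0 reserved for background)."""
    nvox = int(np.prod(shape))
    flat = 1 + (np.arange(nvox) * n_regions) // nvox
    return flat.reshape(shape).astype(np.int32)


def cohort_hash(cohort: pd.DataFrame) -> str:
    """Stable content hash of a cohort table (provenance records)."""
    payload = cohort.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
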