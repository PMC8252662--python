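"""Ground-truthed synthetic fluorescence time-lapse data.

The generator emulates a lawn of mesenchymal cells co-transfected with two
plasmids — P1 (transactivator + nuclear iRFP reporter) and P2 (UAS-driven
mCherry + constitutive EGFP) — under a pulsed-violet-light induction
protocol:

* cells are a homogeneous hard-disk point process; plasmid uptake is drawn
  from a Gaussian-copula competence model so the *relative* co-introduction
  rate (co-transfected / at-least-one) can be high (~0.8) while the
  *absolute* rate stays ~0.18;
* the photoswitchable transactivator follows a one-variable pulse-increment /
  exponential-dark-reversion model ``A(t)``;
* each co-transfected cell carries a lognormal activation threshold on the
  time-averaged activity (cooperative, switch-like activation); switched-on
  cells accumulate mCherry toward a per-cell plateau, delayed by the
  reporter-maturation onset; a Bernoulli fraction of co-transfected cells
  leak mCherry without light;
* an endpoint antibody-stain channel is linearly coupled to final mCherry
  ("P2B" mode) or flat ("P2A" control mode); an EdU channel marks S-phase
  nuclei;
* channels are rendered as Gaussian blobs over a shallow Z spread with
  Poisson–Gaussian camera noise.

An acquisition *field* is one camera frame and may contain several
rectangular analysis regions — typically an irradiated/unirradiated pair
sharing the frame, as in the experiment this emulates (a 512 × 512 px field
holding two 512 × 256 px region units).  All randomness flows from the
single mandatory seed; identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .conditions import IrradiationCondition, PulseSchedule, make_schedule  # noqa: F401 (PulseSchedule is part of the public signature)
from .ops import ImageStack, RegionSpec

__all__ = [
    "GeneratorConfig",
    "FieldSpec",
    "GroundTruth",
    "PackingError",
    "calibrate_uptake",
    "sample_cells",
    "photoswitch_activity",
    "time_averaged_activity",
    "express_reporter",
    "render_field",
    "render_stack",
    "simulate_experiment",
    "paired_field",
    "single_region_field",
]

CHANNELS = ("nuclei", "iRFP", "EGFP", "mCherry", "stain", "edu")


class PackingError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic experiment.  Units in field names/docs.

    Defaults reproduce the study conditions: a 636.4 × 318.2 µm region unit
    at 1.243 µm/pixel (512 × 256 px), absolute co-introduction ≈ 0.18 with
    relative co-introduction ≈ 0.80, leak probability 0.05, dark-reversion
    time constant 30 min, reporter onset delay 90 min, and an activation
    threshold placed so that the reference condition (η = 0.022, δ = 8,
    τ = 20) switches on ≈ 60% of co-transfected cells.
    """

    seed: int
    # geometry of one region unit
    region_width_um: float = 636.4
    region_height_um: float = 318.2
    pixel_size_um: float = 1.243
    n_z: int = 3
    z_step_um: float = 2.0
    z_sigma_um: float = 1.5
    # cells
    cell_density_per_mm2: float = 8000.0
    nucleus_radius_um: float = 3.0
    nucleus_radius_sd_um: float = 0.3
    # plasmid uptake (either give marginal rates + correlation, or targets)
    co_absolute_target: float = 0.18
    co_relative_target: float = 0.80
    p1_rate: float | None = None
    p2_rate: float | None = None
    uptake_correlation: float | None = None
    # leak / induction
    f_leak: float = 0.05
    kappa: float = 2.8  # activity jump per unit η·δ, 1/(W/cm² · µs/px)
    t_off_min: float = 30.0  # dark-reversion time constant
    onset_delay_min: float = 90.0  # reporter onset delay
    activation_threshold_median: float = 0.645  # on time-averaged activity
    activation_threshold_sigma: float = 0.5  # lognormal shape
    detect_threshold: float = 40.0  # trace a.u. defining "mCherry-positive"
    on_plateau_median: float = 320.0  # trace a.u.
    on_plateau_sigma: float = 0.5
    leak_plateau_median: float = 320.0  # same family as induced: one promoter, one reporter
    leak_plateau_sigma: float = 0.5
    k_expr_per_min: float = 0.0115  # accumulation rate per unit activity
    k_leak_per_min: float = 1.0 / 240.0
    baseline: float = 0.0
    # stain / EdU
    stain_mode: str = "P2B"  # "P2B": stain = β·mCherry + noise; "P2A": flat
    stain_slope: float = 2.0
    stain_noise_sd: float = 8.0
    stain_offset: float = 60.0  # P2A control level
    edu_rate: float = 0.35
    # rendering
    psf_sigma_um: float = 1.5  # peaked profile width of the counting channels
    edge_sigma_um: float = 1.0  # soft-edge width of nucleus-filling channels
    nuclear_amp: float = 150.0
    irfp_amp: float = 140.0
    egfp_amp: float = 140.0
    edu_amp: float = 150.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    poisson_scale: float = 2.0  # photons per a.u.; 0 disables shot noise

    def __post_init__(self) -> None:
        for name in ("co_absolute_target", "co_relative_target", "f_leak", "edu_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.kappa < 0 or self.t_off_min <= 0 or self.onset_delay_min < 0:
            raise ValueError("photoswitch parameters must be non-negative (t_off > 0)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def uptake_params(self) -> tuple[float, float, float]:
        """(p1, p2, correlation), deriving them from the co-rate targets if unset."""
        if self.p1_rate is not None:
            p1 = self.p1_rate
            p2 = self.p2_rate if self.p2_rate is not None else self.p1_rate
            rho = self.uptake_correlation if self.uptake_correlation is not None else 0.0
            return p1, p2, rho
        p, rho = calibrate_uptake(self.co_absolute_target, self.co_relative_target)
        return p, p, rho


@dataclass(frozen=True)
class FieldSpec:
    """One acquisition frame with its analysis regions (µm, field-local).

    Regions must lie inside the field and be pairwise disjoint.
    """

    name: str
    width_um: float
    height_um: float
    regions: tuple[RegionSpec, ...]

    def __post_init__(self) -> None:
        rects = []
        for r in self.regions:
            x, y = r.origin
            if x < -1e-9 or y < -1e-9 or x + r.width > self.width_um + 1e-9 \
                    or y + r.height > self.height_um + 1e-9:
                raise ValueError(f"region {r.name!r} lies outside field {self.name!r}")
            rects.append((x, y, x + r.width, y + r.height))
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                if a[0] < b[2] - 1e-9 and b[0] < a[2] - 1e-9 \
                        and a[1] < b[3] - 1e-9 and b[1] < a[3] - 1e-9:
                    raise ValueError(f"regions overlap in field {self.name!r}")

    def frame_shape(self, pixel_size_um: float) -> tuple[int, int]:
        ny = int(round(self.height_um / pixel_size_um))
        nx = int(round(self.width_um / pixel_size_um))
        if ny < 8 or nx < 8:
            raise ValueError("pixel grid too small for the configured field")
        return ny, nx


def paired_field(config: GeneratorConfig, condition_label: str, index: int = 0) -> FieldSpec:
    """A field holding one irradiated region above one unirradiated control.

    With the default geometry this is the 512 × 512 px frame containing two
    512 × 256 px region units.
    """
    w, h = config.region_width_um, config.region_height_um
    name = f"field_c{condition_label}_{index}"
    return FieldSpec(
        name,
        w,
        2 * h,
        (
            RegionSpec((0.0, 0.0), w, h, True, condition_label, name=f"{name}/irr"),
            RegionSpec((0.0, h), w, h, False, "0", name=f"{name}/ctrl"),
        ),
    )


def single_region_field(
    config: GeneratorConfig, condition_label: str, irradiated: bool = True, index: int = 0
) -> FieldSpec:
    """A field that is exactly one region unit (512 × 256 px by default)."""
    w, h = config.region_width_um, config.region_height_um
    tag = "irr" if irradiated else "ctrl"
    name = f"field1_c{condition_label}_{tag}_{index}"
    label = condition_label if irradiated else "0"
    return FieldSpec(
        name, w, h, (RegionSpec((0.0, 0.0), w, h, irradiated, label, name=f"{name}/{tag}"),)
    )


@dataclass
class GroundTruth:
    """Per-cell and per-region truth tables for a simulated experiment.

    ``cells`` has one row per cell (position, plasmid flags, leak flag,
    switching state, final mCherry and its leak/light decomposition, stain
    level, EdU flag, field and region assignment).  ``regions`` aggregates
    the model frequencies per region: N_cell, co-introduction counts/rates,
    realized f_leak (co-transfected cells whose leak component ends above
    the detection threshold) and realized f_induce (same, for the
    light-driven component — zero in unirradiated regions by construction).
    """

    cells: pd.DataFrame
    regions: pd.DataFrame


def calibrate_uptake(absolute_co: float, relative_co: float) -> tuple[float, float]:
    """Marginal uptake probability and copula correlation hitting both co-rates.

    With equal marginals p and a Gaussian-copula competence coupling ρ,
    solves ``P(both) = absolute_co`` and ``P(both)/P(either) = relative_co``.
    """
    if not 0 < absolute_co < relative_co <= 1:
        raise ValueError("need 0 < absolute co-rate < relative co-rate ≤ 1")
    p_either = absolute_co / relative_co
    p = (absolute_co + p_either) / 2.0  # P(either) = 2p − P(both)
    if p >= 1:
        raise ValueError("targets imply a marginal rate ≥ 1")
    z = stats.norm.ppf(p)

    def both(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        return stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True).cdf([z, z])

    if absolute_co <= p * p:
        rho = optimize.brentq(lambda r: both(r) - absolute_co, -0.999, 0.0)
    else:
        rho = optimize.brentq(lambda r: both(r) - absolute_co, 0.0, 0.9999)
    return float(p), float(rho)


# ---------------------------------------------------------------------------
# cells


def _place_nuclei(rng: np.random.Generator, config: GeneratorConfig,
                  width: float, height: float) -> np.ndarray:
    """Hard-disk dart throwing on a neighbour grid.  Returns (n, 3) x, y, r in µm."""
    area_mm2 = width * height / 1e6
    n_target = int(rng.poisson(config.cell_density_per_mm2 * area_mm2))
    r_mean, r_sd = config.nucleus_radius_um, config.nucleus_radius_sd_um
    cell = 2 * (r_mean + 3 * r_sd)
    nx, ny = max(1, int(width // cell)), max(1, int(height // cell))
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(n_target)
    ys = np.empty(n_target)
    rs = np.empty(n_target)
    placed = 0
    attempts_left = 200 * n_target + 1000
    while placed < n_target and attempts_left > 0:
        attempts_left -= 1
        x = rng.uniform(0, width)
        y = rng.uniform(0, height)
        r = float(np.clip(rng.normal(r_mean, r_sd), 0.3 * r_mean, 2 * r_mean))
        gx, gy = min(int(x / width * nx), nx - 1), min(int(y / height * ny), ny - 1)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < (r + rs[j]) ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            xs[placed], ys[placed], rs[placed] = x, y, r
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    if placed < n_target:
        raise PackingError(
            f"placed only {placed}/{n_target} nuclei; density too high for "
            f"non-overlapping placement"
        )
    return np.column_stack([xs, ys, rs])


def sample_cells(
    config: GeneratorConfig,
    field_spec: FieldSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the cell population of one field.

    Cells are placed as non-overlapping hard disks over the whole field and
    assigned to the analysis region containing their centre (empty string if
    none).  Returns a per-cell DataFrame with positions (field-local µm),
    nucleus radii, z positions, plasmid flags from the competence copula,
    the leak flag, the per-cell activation threshold and expression
    plateaus, and the EdU flag.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.cell_density_per_mm2 <= 0:
        raise ValueError("cell density must be > 0")
    p1, p2, rho = config.uptake_params()
    z_extent = (config.n_z - 1) * config.z_step_um
    pos = _place_nuclei(rng, config, field_spec.width_um, field_spec.height_um)
    n = len(pos)
    u = rng.standard_normal(n)
    v = rho * u + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    has_p1 = u < stats.norm.ppf(p1)
    has_p2 = v < stats.norm.ppf(p2)
    region = np.full(n, "", dtype=object)
    irradiated = np.zeros(n, dtype=bool)
    cond_label = np.full(n, "0", dtype=object)
    for reg in field_spec.regions:
        x0, y0 = reg.origin
        inside = (
            (pos[:, 0] >= x0) & (pos[:, 0] < x0 + reg.width)
            & (pos[:, 1] >= y0) & (pos[:, 1] < y0 + reg.height)
        )
        region[inside] = reg.name
        irradiated[inside] = reg.irradiated
        cond_label[inside] = reg.condition_label
    cells = pd.DataFrame(
        {
            "field": field_spec.name,
            "region": region,
            "irradiated": irradiated,
            "condition_label": cond_label,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": np.clip(rng.normal(z_extent / 2, config.z_sigma_um, n), 0, z_extent),
            "radius_um": pos[:, 2],
            "has_p1": has_p1,
            "has_p2": has_p2,
            "leak_on": rng.uniform(size=n) < config.f_leak,
            "theta_act": rng.lognormal(
                np.log(config.activation_threshold_median),
                config.activation_threshold_sigma,
                n,
            ),
            "on_plateau": rng.lognormal(
                np.log(config.on_plateau_median), config.on_plateau_sigma, n
            ),
            "leak_plateau": rng.lognormal(
                np.log(config.leak_plateau_median), config.leak_plateau_sigma, n
            ),
            "edu_positive": rng.uniform(size=n) < config.edu_rate,
        }
    )
    cells.insert(0, "cell_id", np.arange(n))
    cells["co_transfected"] = cells.has_p1 & cells.has_p2
    return cells


# ---------------------------------------------------------------------------
# photoswitch and reporter kinetics


def photoswitch_activity(
    schedule: PulseSchedule,
    kappa: float,
    t_off_min: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Photoswitch activity A(t) ∈ [0, 1] on ``t_grid`` (minutes).

    A jumps by ``min(1 − A, κ·η·δ)`` at each pulse and decays exponentially
    with time constant ``t_off_min`` in between; exact piecewise-exponential
    evaluation, A ≡ 0 for an empty schedule.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing")
    if kappa < 0 or t_off_min <= 0:
        raise ValueError("need κ ≥ 0 and T_off > 0")
    A = np.zeros_like(t_grid)
    if schedule.n_pulses == 0 or kappa == 0:
        return A
    jump = kappa * schedule.pulse_energy
    a = 0.0
    pulse_times = np.asarray(schedule.pulse_times)
    post_pulse = np.empty(len(pulse_times))
    for k, tk in enumerate(pulse_times):
        if k > 0:
            a *= np.exp(-(tk - pulse_times[k - 1]) / t_off_min)
        a = min(1.0, a + jump)
        post_pulse[k] = a
    idx = np.searchsorted(pulse_times, t_grid, side="right") - 1
    inside = idx >= 0
    A[inside] = post_pulse[idx[inside]] * np.exp(
        -(t_grid[inside] - pulse_times[idx[inside]]) / t_off_min
    )
    return A


def time_averaged_activity(A: np.ndarray, t_grid: np.ndarray) -> float:
    """Trapezoidal mean of A over the grid (0 for a single point)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2:
        return 0.0
    return float(np.trapezoid(A, t_grid) / (t_grid[-1] - t_grid[0]))


def express_reporter(
    cells: pd.DataFrame,
    A: np.ndarray,
    t_grid: np.ndarray,
    config: GeneratorConfig,
    timestamps: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mCherry traces at the acquisition timestamps.

    Returns ``(light, leak)`` arrays of shape (n_cells, n_timestamps); the
    full trace is ``baseline + light + leak``.  Only co-transfected cells
    express at all.  A switched-on cell (activation threshold below the
    time-averaged activity) accumulates toward its plateau M with
    ``M·(1 − exp(−k·I(t)))`` where ``I(t) = ∫ A(s − onset_delay) ds``; the
    leak term rises from t = 0 with the leak rate constant.  Traces are
    non-decreasing; no photobleaching is modelled.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    co = cells["co_transfected"].to_numpy()
    abar = time_averaged_activity(A, t_grid)
    on = co & (cells["theta_act"].to_numpy() < abar)
    # cumulative ∫A with onset delay
    cumA = np.concatenate([[0.0], np.cumsum(np.diff(t_grid) * (A[1:] + A[:-1]) / 2)])
    I_ts = np.interp(np.maximum(ts - config.onset_delay_min, 0.0), t_grid, cumA)
    light = np.where(
        on[:, None],
        cells["on_plateau"].to_numpy()[:, None]
        * (1.0 - np.exp(-config.k_expr_per_min * I_ts[None, :])),
        0.0,
    )
    leak_cells = co & cells["leak_on"].to_numpy()
    leak = np.where(
        leak_cells[:, None],
        cells["leak_plateau"].to_numpy()[:, None]
        * (1.0 - np.exp(-config.k_leak_per_min * ts[None, :])),
        0.0,
    )
    return light, leak


# ---------------------------------------------------------------------------
# rendering


def _splat(frame: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
           amp: np.ndarray, sigma_px: float,
           disk_r_px: np.ndarray | None = None) -> None:
    """Add cell blobs (peak ≈ amp) in place.

    Without ``disk_r_px`` the profile is a Gaussian of width ``sigma_px``
    (centrally peaked, used for the chromatin-textured counting channels).
    With ``disk_r_px`` the profile is a flat disk of that per-cell radius
    with a soft edge of width ``sigma_px`` (nucleus-filling reporters), so
    within-nucleus intensity is approximately constant.
    """
    from scipy.special import erf

    ny, nx = frame.shape
    for i, (x, y, a) in enumerate(zip(x_px, y_px, amp)):
        if a <= 0:
            continue
        r0 = 0.0 if disk_r_px is None else float(disk_r_px[i])
        half = max(2, int(np.ceil(r0 + 3 * sigma_px)))
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(nx, cx + half + 1)
        y0, y1 = max(0, cy - half), min(ny, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gy = np.arange(y0, y1) - y
        gx = np.arange(x0, x1) - x
        if disk_r_px is None:
            patch = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma_px**2))
        else:
            r = np.sqrt(gy[:, None] ** 2 + gx[None, :] ** 2)
            patch = 0.5 * (1.0 + erf((r0 - r) / (np.sqrt(2) * sigma_px)))
        frame[y0:y1, x0:x1] += a * patch


def _camera(rng: np.random.Generator, img: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    out = img
    if config.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) * config.poisson_scale) / config.poisson_scale
    if config.read_noise_sd > 0:
        out = out + rng.normal(0, config.read_noise_sd, img.shape)
    return np.maximum(out, 0.0).astype(np.float32)


def render_field(
    cells: pd.DataFrame,
    field_spec: FieldSpec,
    config: GeneratorConfig,
    timestamps: Sequence[float],
    conditions: Mapping[str, IrradiationCondition],
    rng: np.random.Generator | None = None,
    channels: Sequence[str] = CHANNELS,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render one field's cells into a (T, Z, C, Y, X) stack.

    Each irradiated region's condition label is expanded into a pulse
    schedule; cells receive the activity trace of the region containing
    them (zero outside irradiated regions).  The mCherry channel is rendered
    at every timestamp; the structural channels (nuclei, iRFP, EGFP) are
    snapshots at the first timestamp and the endpoint channels (stain, EdU)
    at the last — other frames of those channels contain background only,
    mirroring an acquisition protocol in which only the reporter is
    monitored through time.

    Returns the stack and the per-cell truth table augmented with final
    mCherry, its light/leak decomposition and detection flags.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ts = np.asarray(timestamps, dtype=float)
    if ts.size == 0 or (ts.size > 1 and np.any(np.diff(ts) <= 0)):
        raise ValueError("timestamps must be non-empty and increasing")
    cells = cells.reset_index(drop=True)
    duration = ts[-1] + 1.0
    t_grid = np.arange(0.0, duration + 1.0, 1.0)
    control = IrradiationCondition("0", 0.0, 0.0, 0.0, 0)
    A_zero = np.zeros_like(t_grid)

    n = len(cells)
    nt = len(ts)
    light = np.zeros((n, nt))
    leak = np.zeros((n, nt))
    abar = np.zeros(n)
    groups = [("", control)] + [
        (reg.name, conditions[reg.condition_label] if reg.irradiated else control)
        for reg in field_spec.regions
    ]
    for reg_name, cond in groups:
        idx = np.flatnonzero(cells.region.to_numpy() == reg_name)
        if idx.size == 0:
            continue
        if cond.is_control:
            A = A_zero
        else:
            schedule = make_schedule(cond, duration)
            A = photoswitch_activity(schedule, config.kappa, config.t_off_min, t_grid)
        l_part, k_part = express_reporter(cells.iloc[idx], A, t_grid, config, ts)
        light[idx] = l_part
        leak[idx] = k_part
        abar[idx] = time_averaged_activity(A, t_grid)
    m = config.baseline + light + leak

    truth = cells.copy()
    truth["abar"] = abar
    truth["switched_on"] = truth.co_transfected & (truth.theta_act < abar)
    truth["mcherry_final"] = m[:, -1]
    truth["mcherry_light_final"] = light[:, -1]
    truth["mcherry_leak_final"] = leak[:, -1]
    truth["detect_light"] = light[:, -1] > config.detect_threshold
    truth["detect_leak"] = leak[:, -1] > config.detect_threshold
    truth["detect_total"] = (light[:, -1] + leak[:, -1]) > config.detect_threshold
    if config.stain_mode == "P2B":
        stain = config.stain_slope * truth.mcherry_final.to_numpy() + rng.normal(
            0, config.stain_noise_sd, n
        )
    elif config.stain_mode == "P2A":
        stain = config.stain_offset + rng.normal(0, config.stain_noise_sd, n)
    else:
        raise ValueError("stain_mode must be 'P2B' or 'P2A'")
    truth["stain_level"] = np.maximum(stain, 0.0)

    ny, nx = field_spec.frame_shape(config.pixel_size_um)
    px = config.pixel_size_um
    x_px = cells.x_um.to_numpy() / px
    y_px = cells.y_um.to_numpy() / px
    sigma_px = config.psf_sigma_um / px
    z_centers = np.arange(config.n_z) * config.z_step_um
    zw = np.exp(
        -((cells.z_um.to_numpy()[None, :] - z_centers[:, None]) ** 2)
        / (2 * config.z_sigma_um**2)
    )  # (n_z, n_cells)

    static_amp = {
        "nuclei": np.full(n, config.nuclear_amp) * rng.uniform(0.7, 1.0, n),
        "iRFP": config.irfp_amp * cells.has_p1.to_numpy() * rng.uniform(0.7, 1.0, n),
        "EGFP": config.egfp_amp * cells.has_p2.to_numpy() * rng.uniform(0.7, 1.0, n),
    }
    end_amp = {
        "stain": truth.stain_level.to_numpy(),
        "edu": config.edu_amp * cells.edu_positive.to_numpy(),
    }
    disk_r_px = cells.radius_um.to_numpy() / px
    edge_sigma_px = config.edge_sigma_um / px
    nucleus_filling = {"mCherry", "stain", "edu"}
    data = np.empty((nt, config.n_z, len(channels), ny, nx), dtype=np.float32)
    for it in range(nt):
        for ic, ch in enumerate(channels):
            for iz in range(config.n_z):
                frame = np.full((ny, nx), config.background, dtype=float)
                amp = None
                if ch == "mCherry":
                    amp = m[:, it] * zw[iz]
                elif ch in static_amp and it == 0:
                    amp = static_amp[ch] * zw[iz]
                elif ch in end_amp and it == nt - 1:
                    amp = end_amp[ch] * zw[iz]
                if amp is not None and np.any(amp > 0):
                    if ch in nucleus_filling:
                        _splat(frame, x_px, y_px, amp, edge_sigma_px, disk_r_px)
                    else:
                        _splat(frame, x_px, y_px, amp, sigma_px)
                data[it, iz, ic] = _camera(rng, frame, config)
    stack = ImageStack(data, px, tuple(ts), tuple(channels))
    return stack, truth


def render_stack(
    cells: pd.DataFrame,
    config: GeneratorConfig,
    timestamps: Sequence[float],
    condition: IrradiationCondition,
    rng: np.random.Generator | None = None,
    channels: Sequence[str] = CHANNELS,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a single-region frame (one region unit under one condition)."""
    fs = single_region_field(GeneratorConfig(seed=0) if config is None else config,
                             condition.label, not condition.is_control)
    cells = cells.copy()
    cells["field"] = fs.name
    cells["region"] = fs.regions[0].name
    cells["irradiated"] = fs.regions[0].irradiated
    cells["condition_label"] = fs.regions[0].condition_label
    return render_field(cells, fs, config, timestamps, {condition.label: condition},
                        rng, channels)


# ---------------------------------------------------------------------------
# whole experiments


@dataclass
class SimulatedExperiment:
    """Stacks plus ground truth for a multi-field simulated experiment."""

    stacks: dict[str, ImageStack]
    fields: list[FieldSpec]
    conditions: dict[str, IrradiationCondition]
    truth: GroundTruth
    config: GeneratorConfig


def _region_summary(truth_cells: pd.DataFrame) -> pd.DataFrame:
    rows = []
    assigned = truth_cells[truth_cells.region != ""]
    for region, df in assigned.groupby("region", sort=False):
        n = len(df)
        co = df.co_transfected
        n_co = int(co.sum())
        n_either = int((df.has_p1 | df.has_p2).sum())
        rows.append(
            {
                "region": region,
                "field": df.field.iloc[0],
                "irradiated": bool(df.irradiated.iloc[0]),
                "condition_label": df.condition_label.iloc[0],
                "n_cell": n,
                "n_p1": int(df.has_p1.sum()),
                "n_p2": int(df.has_p2.sum()),
                "n_co": n_co,
                "n_either": n_either,
                "f_co_absolute": n_co / n if n else np.nan,
                "f_co_relative": n_co / n_either if n_either else np.nan,
                "f_leak": df.loc[co, "detect_leak"].mean() if n_co else np.nan,
                "f_induce": df.loc[co, "detect_light"].mean() if n_co else np.nan,
                "f_positive": df.loc[co, "detect_total"].mean() if n_co else np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: GeneratorConfig,
    fields: Sequence[FieldSpec],
    conditions: Mapping[str, IrradiationCondition],
    timestamps: Sequence[float],
    channels: Sequence[str] = CHANNELS,
) -> SimulatedExperiment:
    """Simulate every field of an experiment, one rendered stack per field.

    ``conditions`` maps condition labels to conditions; every irradiated
    region's ``condition_label`` must resolve.  All stacks and random draws
    derive deterministically from ``config.seed``.  For experiments too
    large to hold every stack in memory, use
    :func:`optolight.pipeline.run_experiment`, which streams.
    """
    for fs in fields:
        for reg in fs.regions:
            if reg.irradiated and reg.condition_label not in conditions:
                raise KeyError(
                    f"region {reg.name!r}: unknown condition {reg.condition_label!r}"
                )
    ss = np.random.SeedSequence(config.seed)
    stacks: dict[str, ImageStack] = {}
    truths = []
    for fs, fseed in zip(fields, ss.spawn(len(fields))):
        rng = np.random.default_rng(fseed)
        cells = sample_cells(config, fs, rng)
        stack, truth = render_field(cells, fs, config, timestamps, conditions, rng, channels)
        stacks[fs.name] = stack
        truths.append(truth)
    cells_truth = pd.concat(truths, ignore_index=True)
    gt = GroundTruth(cells_truth, _region_summary(cells_truth))
    return SimulatedExperiment(stacks, list(fields), dict(conditions), gt, config)
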