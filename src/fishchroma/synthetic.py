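"""Synthetic study generator: images with known ground truth plus simulated cohorts.

Everything the measurement and inference stages consume can be generated here
with known truth: a striped dorsal-skin scene imaged through a distorting
camera/flash model, a 24-patch calibration chart, per-trial b* trajectories
under crowding, a physiology cohort linking plasma lactate to skin colour,
post-mortem colour series, and binomial mortality counts.

The mackerel dorsal surface is modelled as alternating dark and light
stripes; only the light ("coloured section") pixels carry the colour signal
analysed downstream, exactly as in the photographic protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour import (
    LabTriple,
    lab_to_linear_rgb,
    srgb_encode,
)

__all__ = [
    "SceneSpec",
    "CameraModel",
    "TrialScenario",
    "CohortSpec",
    "default_scenarios",
    "chart_reference_patches",
    "render_fish_image",
    "render_chart_image",
    "random_camera",
    "simulate_trajectories",
    "simulate_cohort",
    "simulate_postmortem",
    "simulate_mortality",
    "CONTROL_LAB",
]

#: Mean CIELAB of unstressed control skin used as the generator baseline.
CONTROL_LAB = LabTriple(47.67, -9.27, 17.17)

#: Default exposure-gain range for the flash-inconsistency model.  The upper
#: end keeps the L*=95 white background below sensor clipping in an 8-bit
#: container (expose-to-protect-highlights); gains above ~1.13 would saturate
#: the background and make exposure correction physically unrecoverable.
GAIN_RANGE = (0.7, 1.1)


@dataclass
class SceneSpec:
    """Geometry and ground-truth colours of one synthetic dorsal photograph."""

    image_size: tuple[int, int] = (360, 640)  # (H, W)
    fish_region: tuple[int, int, int, int] = (55, 150, 540, 60)  # x, y, w, h
    stripe_period: int = 24
    stripe_duty: float = 0.4  # fraction of the period that is dark stripe
    light_lab: LabTriple = CONTROL_LAB
    dark_lab: LabTriple = LabTriple(20.0, -2.0, 0.0)
    background_lab: LabTriple = LabTriple(95.0, 0.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        x, y, rw, rh = self.fish_region
        if rw <= 0 or rh <= 0:
            raise ValueError("degenerate fish_region rectangle")
        if not (x > 0 and y > 0 and x + rw < w and y + rh < h):
            raise ValueError("fish_region must lie strictly inside the image")
        if not 0.0 < self.stripe_duty < 1.0:
            raise ValueError("stripe_duty must be in (0, 1)")
        if self.stripe_period < 2:
            raise ValueError("stripe_period must be at least 2 px")
        if not (self.background_lab[0] > self.light_lab[0] > self.dark_lab[0]):
            raise ValueError("require background L* > light L* > dark L*")

    @property
    def white_region(self) -> tuple[int, int, int, int]:
        """A background rectangle above the fish, used for exposure correction."""
        x, y, rw, rh = self.fish_region
        return (x, max(2, y - 40), rw, min(30, y - 4))


@dataclass
class CameraModel:
    """Linear-RGB camera distortion: 3x3 matrix, exposure gain, quantisation."""

    cam_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    exposure_gain: float = 1.0
    quantization: int = 8
    seed: int = 0

    def __post_init__(self):
        self.cam_matrix = np.asarray(self.cam_matrix, dtype=float)
        if self.cam_matrix.shape != (3, 3):
            raise ValueError("cam_matrix must be 3x3")
        if abs(np.linalg.det(self.cam_matrix)) < 1e-12:
            raise ValueError("cam_matrix must be invertible")
        if self.exposure_gain <= 0:
            raise ValueError("exposure_gain must be positive")
        if self.quantization < 1:
            raise ValueError("quantization must be >= 1 bit")

    def expose(self, rgb_linear):
        """Scene linear RGB -> quantised sRGB-encoded image array."""
        shot = (np.asarray(rgb_linear, dtype=float) * self.exposure_gain) @ self.cam_matrix.T
        encoded = srgb_encode(np.clip(shot, 0.0, 1.0))
        levels = 2 ** self.quantization - 1
        return np.round(encoded * levels).astype(np.uint8 if self.quantization <= 8 else np.uint16)


def random_camera(rng: np.random.Generator, distortion: float = 0.04,
                  gain_range: tuple[float, float] = GAIN_RANGE) -> CameraModel:
    """Draw a near-identity camera: I + U(-distortion, distortion) per entry,
    exposure gain uniform over ``gain_range``."""
    m = np.eye(3) + rng.uniform(-distortion, distortion, size=(3, 3))
    g = float(rng.uniform(*gain_range))
    return CameraModel(cam_matrix=m, exposure_gain=g)


def render_fish_image(scene: SceneSpec, camera: CameraModel):
    """Render a striped dorsal scene through a camera model.

    Returns ``(image, mask)``: an 8-bit RGB image and the exact boolean mask
    of the light inter-stripe pixels (the "coloured section") for oracle
    comparison with downstream segmentation.  Stripes are vertical bands of
    width ``stripe_duty * stripe_period`` repeating along the fish axis.
    """
    h, w = scene.image_size
    x, y, rw, rh = scene.fish_region
    lab = np.empty((h, w, 3), dtype=float)
    lab[:, :] = np.asarray(scene.background_lab, dtype=float)

    cols = np.arange(rw)
    dark_width = int(round(scene.stripe_duty * scene.stripe_period))
    dark_cols = (cols % scene.stripe_period) < dark_width
    fish_lab = np.where(
        dark_cols[:, None],
        np.asarray(scene.dark_lab, dtype=float),
        np.asarray(scene.light_lab, dtype=float),
    )
    lab[y : y + rh, x : x + rw] = fish_lab[None, :, :]

    mask = np.zeros((h, w), dtype=bool)
    mask[y : y + rh, x : x + rw] = ~dark_cols[None, :]

    rgb = np.clip(lab_to_linear_rgb(lab), 0.0, 1.0)
    return camera.expose(rgb), mask


# ---------------------------------------------------------------------------
# Calibration chart
# ---------------------------------------------------------------------------

def chart_reference_patches() -> np.ndarray:
    """Deterministic 24-patch reference lattice in linear RGB, (24, 3).

    A synthetic stand-in for a commercial colour chart: the 8 corners of a
    sub-gamut RGB cube, a 6-step neutral grey ramp, and 10 fixed mid-tones.
    Values span [0.05, 0.85]; the cap leaves flash-gain headroom below
    sensor clipping.
    """
    lo, hi = 0.05, 0.85
    corners = np.array(
        [[r, g, b] for r in (lo, hi) for g in (lo, hi) for b in (lo, hi)]
    )
    greys = np.linspace(lo, hi, 6)[:, None] * np.ones((1, 3))
    mid = np.array(
        [
            [0.60, 0.20, 0.20],
            [0.20, 0.60, 0.20],
            [0.20, 0.20, 0.60],
            [0.60, 0.60, 0.20],
            [0.20, 0.60, 0.60],
            [0.60, 0.20, 0.60],
            [0.45, 0.30, 0.15],
            [0.15, 0.45, 0.30],
            [0.30, 0.15, 0.45],
            [0.70, 0.45, 0.25],
        ]
    )
    patches = np.vstack([corners, greys, mid])
    assert patches.shape == (24, 3)
    return patches


#: Index of the brightest neutral patch (the grey-ramp end at 0.85).
CHART_WHITE_INDEX = 13


def chart_patch_boxes(patch_px: int = 40, gap: int = 10, margin: int = 12):
    """Pixel rectangles (x, y, w, h) of the 6x4 chart layout, row-major."""
    boxes = []
    for row in range(4):
        for col in range(6):
            x = margin + col * (patch_px + gap)
            y = margin + row * (patch_px + gap)
            boxes.append((x, y, patch_px, patch_px))
    return boxes


def render_chart_image(camera: CameraModel, patch_px: int = 40, gap: int = 10,
                       margin: int = 12):
    """Render the synthetic 24-patch chart through ``camera``.

    Returns ``(image, boxes, reference)``: the 8-bit RGB chart image, the
    per-patch pixel rectangles and the (24, 3) linear-RGB reference values.
    """
    boxes = chart_patch_boxes(patch_px, gap, margin)
    reference = chart_reference_patches()
    width = margin * 2 + 6 * patch_px + 5 * gap
    height = margin * 2 + 4 * patch_px + 3 * gap
    rgb = np.zeros((height, width, 3), dtype=float)
    for (x, y, w, h), ref in zip(boxes, reference):
        rgb[y : y + h, x : x + w] = ref
    return camera.expose(rgb), boxes, reference


# ---------------------------------------------------------------------------
# Trial scenarios and simulated tables
# ---------------------------------------------------------------------------

@dataclass
class TrialScenario:
    """One treatment condition: crowding density, duration and b* dynamics.

    ``rate`` is the signed change in b* per minute of exposure (negative =
    blueing); ``sigma`` the residual SD of individual measurements.
    """

    name: str
    density: float  # kg/m^3
    duration: float  # minutes
    b0: float = CONTROL_LAB.b
    rate: float = 0.0
    sigma: float = 2.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.name == "Control" and self.rate != 0.0:
            raise ValueError("Control scenario must have rate = 0")


def default_scenarios() -> dict[str, TrialScenario]:
    """The study conditions: densities/durations from the trial table, b*
    rates per minute from the fitted crowding model (-0.25 Low, -0.82 High,
    -0.20 High & Prolonged, +0.30 Moderate; controls flat)."""
    return {
        "Control": TrialScenario("Control", density=0.76, duration=112.0, rate=0.0),
        "Low": TrialScenario("Low", density=92.00, duration=15.0, rate=-0.25),
        "Moderate": TrialScenario("Moderate", density=146.21, duration=13.0, rate=0.30),
        "High": TrialScenario("High", density=179.87, duration=15.0, rate=-0.82),
        "HighProlonged": TrialScenario(
            "HighProlonged", density=182.75, duration=68.0, rate=-0.20
        ),
    }


def simulate_trajectories(scenarios, n_per_scenario: int, sampling_window: float,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate during-crowding b* measurements for each scenario.

    For fish i in a scenario: ``b* = b0 + rate * t + eps``, with sampling
    times t uniform over [0, min(duration, sampling_window)] and iid Gaussian
    residuals of scenario-specific SD (heteroscedastic across trials by
    design, matching a per-trial variance structure).
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("empty scenario list")
    if n_per_scenario < 2:
        raise ValueError("need at least 2 fish per scenario")
    rng = np.random.default_rng(seed)
    rows = []
    fid = 0
    for sc in scenarios:
        tmax = min(sc.duration, sampling_window)
        t = rng.uniform(0.0, tmax, size=n_per_scenario)
        eps = rng.normal(0.0, sc.sigma, size=n_per_scenario)
        b = sc.b0 + sc.rate * t + eps
        for ti, bi in zip(t, b):
            rows.append((f"F{fid:05d}", sc.name, float(ti), float(bi)))
            fid += 1
    return pd.DataFrame(rows, columns=["fish_id", "trial", "exposure_min", "b"])


@dataclass
class CohortSpec:
    """Physiology cohort: a monotone-decreasing lactate -> b* link plus
    nested random intercepts (monitoring period within trial).

    The link is logistic: ``f(lac) = lower + (upper - lower) /
    (1 + exp(steepness * (lac - midpoint)))`` with steepness > 0, so higher
    lactate gives lower (bluer) b*.  Glucose and cortisol are generated
    independent of b* (they were not predictive of skin colour).
    """

    n_per_cell: int = 8
    trials: tuple[str, ...] = ("Control", "Low", "Moderate", "High", "HighProlonged")
    periods: tuple[str, ...] = ("Pre-treatment", "Treatment", "2h post-treatment")
    link_lower: float = 6.0
    link_upper: float = CONTROL_LAB.b
    link_midpoint: float = 6.0  # mmol/L
    link_steepness: float = 0.8
    trial_intercept_sd: float = 1.0
    period_intercept_sd: float = 1.0
    residual_sd: float = 2.0
    lactate_range: tuple[float, float] = (0.5, 12.0)
    seed: int = 0

    def __post_init__(self):
        if self.link_steepness <= 0 or self.link_upper <= self.link_lower:
            raise ValueError("lactate link must be strictly decreasing")
        if min(self.trial_intercept_sd, self.period_intercept_sd, self.residual_sd) < 0:
            raise ValueError("all SDs must be >= 0")

    def link(self, lactate):
        lac = np.asarray(lactate, dtype=float)
        span = self.link_upper - self.link_lower
        return self.link_lower + span / (
            1.0 + np.exp(self.link_steepness * (lac - self.link_midpoint))
        )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate sampled fish with plasma chemistry and skin colour.

    b* = f(lactate) + u_trial + u_period(trial) + eps, with all random terms
    Gaussian at the spec's SDs.
    """
    rng = np.random.default_rng(spec.seed)
    u_trial = {t: rng.normal(0.0, spec.trial_intercept_sd) for t in spec.trials}
    u_period = {
        (t, p): rng.normal(0.0, spec.period_intercept_sd)
        for t in spec.trials
        for p in spec.periods
    }
    rows = []
    fid = 0
    for t in spec.trials:
        for p in spec.periods:
            n = spec.n_per_cell
            lac = rng.uniform(*spec.lactate_range, size=n)
            glucose = np.clip(rng.normal(5.0, 1.0, size=n), 0.1, None)
            cortisol = rng.lognormal(mean=4.0, sigma=0.6, size=n)
            eps = rng.normal(0.0, spec.residual_sd, size=n)
            b = spec.link(lac) + u_trial[t] + u_period[(t, p)] + eps
            weight = rng.normal(720.0, 60.0, size=n)
            length = rng.normal(38.3, 1.1, size=n)
            vit = rng.random(size=n) < 0.5
            for i in range(n):
                rows.append(
                    (
                        f"C{fid:05d}", t, p, bool(vit[i]), float(lac[i]),
                        float(glucose[i]), float(cortisol[i]), float(b[i]),
                        float(weight[i]), float(length[i]),
                    )
                )
                fid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id", "trial", "monitoring_period", "vitality_assessed",
            "lactate", "glucose", "cortisol", "b", "weight_g", "length_cm",
        ],
    )


def simulate_postmortem(n_fish: int, timepoints=(0.0, 1.0, 4.0, 24.0),
                        drop: float = 5.0, storage_effect: float = 0.0,
                        b0: float = CONTROL_LAB.b, fish_sd: float = 1.0,
                        residual_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Simulate repeated post-mortem b* measurements per fish.

    At death (t = 0) a fish sits at its own baseline b0_i ~ N(b0, fish_sd^2);
    from 1 h onward the colour has dropped by ``drop`` b* units (the rapid
    post-mortem blueing) and then stays level through 24 h.  Half the fish
    are stored in light, half in dark; storage adds ``storage_effect``
    (default 0: storage made no difference).
    """
    if n_fish < 2:
        raise ValueError("need at least 2 fish")
    if drop < 0:
        raise ValueError("drop must be >= 0")
    timepoints = tuple(float(t) for t in timepoints)
    if len(timepoints) < 2 or min(timepoints) != 0.0 or len(set(timepoints)) != len(timepoints):
        raise ValueError("timepoints must be distinct and include 0 h")
    rng = np.random.default_rng(seed)
    baselines = rng.normal(b0, fish_sd, size=n_fish)
    rows = []
    for i in range(n_fish):
        storage = "light" if i % 2 == 0 else "dark"
        for t in timepoints:
            mu = baselines[i] - (drop if t >= 1.0 else 0.0)
            if storage == "light":
                mu += storage_effect
            rows.append(
                (f"P{i:03d}", float(t), storage, float(mu + rng.normal(0.0, residual_sd)))
            )
    return pd.DataFrame(rows, columns=["fish_id", "time_h", "storage", "b"])


def simulate_mortality(n_monitored: int, true_p: float, seed: int = 0) -> int:
    """Binomial death count among monitored fish."""
    if not 0.0 <= true_p <= 1.0:
        raise ValueError("true_p must be in [0, 1]")
    if n_monitored < 0:
        raise ValueError("n_monitored must be >= 0")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_monitored, true_p))
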