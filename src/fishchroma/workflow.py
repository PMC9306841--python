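"""End-to-end orchestration: calibrate, measure, simulate and analyse studies.

The processing chain for every photograph is: sRGB decode -> exposure
normalisation against the white background -> chart-fitted matrix
correction -> XYZ -> CIELAB, then masked averaging over the coloured
section of the dorsal strip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import roi as roi_mod
from . import stats as st
from .colour import (
    CorrectionModel,
    exposure_normalize,
    fit_correction,
    lab_to_linear_rgb,
    srgb_decode,
)
from .roi import ColourMeasurement, ROISpec, extract_thumbnail, measure_colour, stripe_mask
from .synthetic import (
    CHART_WHITE_INDEX,
    CONTROL_LAB,
    CameraModel,
    CohortSpec,
    SceneSpec,
    default_scenarios,
    random_camera,
    render_chart_image,
    render_fish_image,
    simulate_cohort,
    simulate_postmortem,
    simulate_trajectories,
)

__all__ = [
    "load_image",
    "save_image",
    "measure_chart_patches",
    "calibrate_from_chart",
    "background_reference_green",
    "measure_fish_image",
    "simulate_study",
    "measure_study",
    "analyse_study",
]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path, array: np.ndarray):
    Image.fromarray(np.asarray(array)).save(path)


def measure_chart_patches(chart_image: np.ndarray, boxes) -> np.ndarray:
    """Mean linear-RGB value of each chart patch (inner 60% of each box)."""
    out = np.empty((len(boxes), 3))
    for i, (x, y, w, h) in enumerate(boxes):
        mx, my = int(w * 0.2), int(h * 0.2)
        patch = chart_image[y + my : y + h - my, x + mx : x + w - mx].astype(float)
        if chart_image.dtype == np.uint8:
            patch = patch / 255.0
        elif chart_image.dtype == np.uint16:
            patch = patch / 65535.0
        out[i] = srgb_decode(patch).reshape(-1, 3).mean(axis=0)
    return out


def calibrate_from_chart(chart_image: np.ndarray, boxes, reference: np.ndarray,
                         white_index: int = CHART_WHITE_INDEX) -> CorrectionModel:
    """Fit the colour correction from a photographed chart.

    Patch means are exposure-normalised against the brightest neutral patch
    before the 3x3 matrix fit, so the matrix is independent of the chart
    image's own flash gain; per-subject-image gains are handled at
    measurement time from the white background.
    """
    measured = measure_chart_patches(chart_image, boxes)
    ref = np.asarray(reference, dtype=float)
    gain = float(ref[white_index, 1] / measured[white_index, 1])
    model = fit_correction(measured * gain, ref)
    model.meta["chart_gain"] = gain
    return model


def background_reference_green(background_lab=(95.0, 0.0, 2.0)) -> float:
    """Linear green value of the white background at its ground-truth Lab."""
    return float(lab_to_linear_rgb(np.asarray(background_lab, dtype=float))[1])


def measure_fish_image(image: np.ndarray, roi: ROISpec,
                       correction: CorrectionModel | None,
                       white_region, reference_white: float) -> ColourMeasurement:
    """Measure mean coloured-section CIELAB of one dorsal photograph."""
    img = image.astype(float)
    if image.dtype == np.uint8:
        img = img / 255.0
    linear = srgb_decode(img)
    _, gain, saturated = exposure_normalize(linear, white_region, reference_white)
    thumb = extract_thumbnail(image, roi)
    mask, thr = stripe_mask(thumb)
    meas = measure_colour(thumb, mask, correction, exposure_gain=gain,
                          threshold_value=thr)
    if saturated:
        meas.reliable = False
    return meas


# ---------------------------------------------------------------------------
# Study-level orchestration (used by the CLI)
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def simulate_study(out_dir, seed: int = 0, n_fish_per_trial: int = 6,
                   sampling_window: float = 15.0, scenarios=None) -> dict:
    """Write a complete synthetic study: chart, per-fish images, metadata
    CSV, cohort and post-mortem tables, and a ground-truth YAML.

    Each sampled fish gets its own exposure gain (flash inconsistency) but
    the camera colour matrix is shared, as with a single physical camera.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scenarios = scenarios or default_scenarios()

    cam_matrix = random_camera(rng).cam_matrix  # shared optics/profile
    chart_cam = CameraModel(cam_matrix=cam_matrix,
                            exposure_gain=float(rng.uniform(0.7, 1.1)))
    chart_img, boxes, reference = render_chart_image(chart_cam)
    save_image(out / "chart.png", chart_img)

    traj = simulate_trajectories(scenarios.values(), n_fish_per_trial,
                                 sampling_window, seed=int(rng.integers(2**31)))
    scene0 = SceneSpec()
    rx, ry, rw, rh = scene0.fish_region
    roi = ROISpec(x=rx + 5, y=ry + 3)

    records = []
    gains = {}
    for _, row in traj.iterrows():
        lab = (CONTROL_LAB.L, CONTROL_LAB.a, float(row["b"]))
        scene = SceneSpec(light_lab=lab)
        cam = CameraModel(cam_matrix=cam_matrix,
                          exposure_gain=float(rng.uniform(0.7, 1.1)))
        img, mask = render_fish_image(scene, cam)
        img_path = out / f"{row['fish_id']}.png"
        save_image(img_path, img)
        gains[row["fish_id"]] = cam.exposure_gain
        records.append(
            {
                "fish_id": row["fish_id"],
                "trial": row["trial"],
                "monitoring_period": "Treatment",
                "exposure_min": row["exposure_min"],
                "vitality_assessed": bool(rng.random() < 0.5),
                "lactate": float("nan"),
                "glucose": float("nan"),
                "cortisol": float("nan"),
                "weight_g": float(rng.normal(720.0, 60.0)),
                "length_cm": float(rng.normal(38.3, 1.1)),
                "image_path": img_path.name,
                "roi_x": roi.x,
                "roi_y": roi.y,
                "true_b": float(row["b"]),
            }
        )
    meta = pd.DataFrame(records)
    meta.to_csv(out / "metadata.csv", index=False)

    cohort = simulate_cohort(CohortSpec(seed=int(rng.integers(2**31))))
    cohort.to_csv(out / "cohort.csv", index=False)
    pm = simulate_postmortem(n_fish=15, seed=int(rng.integers(2**31)))
    pm.to_csv(out / "postmortem.csv", index=False)

    truth = {
        "seed": int(seed),
        "cam_matrix": [[float(v) for v in r] for r in cam_matrix],
        "chart_gain": float(chart_cam.exposure_gain),
        "image_gains": {k: float(v) for k, v in gains.items()},
        "light_lab_L": CONTROL_LAB.L,
        "light_lab_a": CONTROL_LAB.a,
        "scenarios": {
            name: {"density": sc.density, "duration": sc.duration,
                   "b0": sc.b0, "rate": sc.rate, "sigma": sc.sigma}
            for name, sc in scenarios.items()
        },
        "roi": {"x": roi.x, "y": roi.y, "width": roi.width, "height": roi.height},
        "white_region": list(scene0.white_region),
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
    return truth


def measure_study(data_dir, out_csv=None) -> pd.DataFrame:
    """Calibrate from the study chart and measure every fish image."""
    data = Path(data_dir)
    meta = pd.read_csv(data / "metadata.csv")
    with open(data / "ground_truth.yaml") as fh:
        truth = yaml.safe_load(fh)

    chart_img = load_image(data / "chart.png")
    from .synthetic import chart_patch_boxes, chart_reference_patches

    correction = calibrate_from_chart(chart_img, chart_patch_boxes(),
                                      chart_reference_patches())
    ref_white = background_reference_green()
    white_region = tuple(truth["white_region"])

    rows = []
    for _, row in meta.iterrows():
        path = data / row["image_path"]
        try:
            img = load_image(path)
            roi = ROISpec(x=int(row["roi_x"]), y=int(row["roi_y"]))
            meas = measure_fish_image(img, roi, correction, white_region, ref_white)
            rows.append(
                {
                    "fish_id": row["fish_id"],
                    "trial": row["trial"],
                    "monitoring_period": row["monitoring_period"],
                    "exposure_min": row["exposure_min"],
                    "L": meas.mean_lab.L,
                    "a": meas.mean_lab.a,
                    "b": meas.mean_lab.b,
                    "n_pixels_used": meas.n_pixels_used,
                    "mask_fraction": meas.mask_fraction,
                    "threshold_value": meas.threshold_value,
                    "gain": meas.gain,
                    "reliable": meas.reliable,
                    "error": "",
                }
            )
        except Exception as exc:  # keep the batch going, record the failure
            rows.append({"fish_id": row["fish_id"], "trial": row.get("trial", ""),
                         "error": str(exc)})
    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def analyse_study(data_dir, measurements: pd.DataFrame | None = None,
                  out_json=None, plots_dir=None, seed: int = 0) -> dict:
    """Fit the full inferential suite on a simulated (or measured) study.

    Runs the trial-by-exposure GLS on the colour measurements, the
    lactate-b* spline mixed model on the cohort, the post-mortem LME, and
    Wilson mortality intervals; returns one JSON-serialisable report.
    """
    data = Path(data_dir)
    if measurements is None:
        measurements = pd.read_csv(data / "measurements.csv")
    if "error" in measurements.columns:
        err = measurements["error"].fillna("").astype(str)
        measurements = measurements[err == ""].copy()

    report: dict = {"seed": seed}

    # Crowding GLS: b ~ trial * exposure with per-trial variance ratios
    spec = st.DesignSpec(
        data=measurements,
        response="b",
        fixed=("trial", "exposure_min", "trial:exposure_min"),
        variance_groups="trial",
    )
    fit = st.fit_gls(spec)
    slopes = st.trial_slopes(fit)
    inter = st.wald_f(fit, "trial:exposure_min")
    report["crowding_gls"] = {
        "slopes": slopes.to_dict(orient="records"),
        "interaction_F": inter.statistic,
        "interaction_df": inter.df,
        "interaction_p": inter.p_value,
        "var_ratios": fit.var_ratios,
        "sigma": fit.sigma,
        "converged": fit.converged,
    }

    # Physiology spline model on the cohort
    cohort_path = data / "cohort.csv"
    if cohort_path.exists():
        cohort = pd.read_csv(cohort_path)
        sspec = st.DesignSpec(
            data=cohort, response="b", smooth="lactate",
            random_groups=("trial", "monitoring_period"), variance_power=True,
        )
        sfit = st.fit_spline_mixed(sspec)
        grid = np.quantile(cohort["lactate"], np.linspace(0.05, 0.95, 25))
        curve = st.predict_smooth(sfit, grid)
        report["lactate_spline"] = {
            "basis_dim": sfit.extra["basis_dim"],
            "smooth_edf": sfit.extra["smooth_edf"],
            "var_power": sfit.var_power,
            "monotone_decreasing": bool(np.all(np.diff(curve) <= 1e-6)),
            "curve_x": [float(v) for v in grid],
            "curve_b": [float(v) for v in curve],
            "converged": sfit.converged,
        }

    # Post-mortem LME: b ~ time + storage, random intercept per fish
    pm_path = data / "postmortem.csv"
    if pm_path.exists():
        pm = pd.read_csv(pm_path)
        pm["time_h"] = pm["time_h"].astype(str)
        full = st.DesignSpec(data=pm, response="b", fixed=("time_h", "storage"),
                             random_groups=("fish_id",))
        fit_full = st.fit_lme(full)
        fit_nostorage = st.fit_lme(full.drop_term("storage"))
        storage_test = st.lrt(fit_full, fit_nostorage)
        fit_notime = st.fit_lme(
            st.DesignSpec(data=pm, response="b", fixed=(), random_groups=("fish_id",))
        )
        time_test = st.lrt(fit_nostorage, fit_notime)
        contrast = [c for c in fit_nostorage.params.index if c.startswith("time_h[T.1")]
        report["postmortem_lme"] = {
            "storage_lrt": storage_test.statistic,
            "storage_p": storage_test.p_value,
            "time_lrt": time_test.statistic,
            "time_df": time_test.df,
            "time_p": time_test.p_value,
            "contrast_1h_vs_0h": float(fit_nostorage.params[contrast[0]]) if contrast else None,
            "fish_sd": fit_nostorage.random_sd.get("fish_id"),
        }

    # Mortality Wilson intervals (the observed study counts)
    mortality = {
        "Low": (0, 231), "Control 3": (0, 175), "Control 2": (0, 116),
        "Moderate": (4, 131), "High": (46, 150),
    }
    report["mortality_wilson"] = {
        name: {"deaths": d, "n": n, "proportion": d / n,
               "ci": list(st.wilson_interval(d, n))}
        for name, (d, n) in mortality.items()
    }

    if plots_dir is not None:
        _write_plots(measurements, report, plots_dir)
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def _write_plots(measurements: pd.DataFrame, report: dict, plots_dir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = Path(plots_dir)
    plots.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for trial, grp in measurements.groupby("trial"):
        ax.scatter(grp["exposure_min"], grp["b"], s=12, label=trial, alpha=0.7)
    for rec in report["crowding_gls"]["slopes"]:
        sub = measurements[measurements["trial"] == rec["trial"]]
        if len(sub):
            t = np.linspace(0, sub["exposure_min"].max(), 10)
            b0 = sub["b"].mean() - rec["slope"] * sub["exposure_min"].mean()
            ax.plot(t, b0 + rec["slope"] * t, lw=1)
    ax.set_xlabel("exposure (min)")
    ax.set_ylabel("b* (blue - / yellow +)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(plots / "crowding_b_vs_exposure.png", dpi=120)
    plt.close(fig)

    if "lactate_spline" in report:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(report["lactate_spline"]["curve_x"],
                report["lactate_spline"]["curve_b"], lw=2)
        ax.set_xlabel("plasma lactate (mmol/L)")
        ax.set_ylabel("fitted b*")
        fig.tight_layout()
        fig.savefig(plots / "lactate_smooth.png", dpi=120)
        plt.close(fig)
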