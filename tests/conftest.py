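import numpy as np
import pytest

from fishchroma import stats as st
from fishchroma.roi import ROISpec
from fishchroma.synthetic import (
    CameraModel,
    CohortSpec,
    SceneSpec,
    random_camera,
    render_chart_image,
    render_fish_image,
    simulate_cohort,
)
from fishchroma.workflow import (
    background_reference_green,
    calibrate_from_chart,
    measure_fish_image,
)


@pytest.fixture(scope="session")
def control_scene():
    return SceneSpec()


@pytest.fixture(scope="session")
def default_roi(control_scene):
    x, y, _, _ = control_scene.fish_region
    return ROISpec(x=x + 5, y=y + 3)


@pytest.fixture(scope="session")
def calibrated_control_measurement(control_scene, default_roi):
    """Full pipeline on the control scene through a seeded random camera:
    chart render -> correction fit -> fish render -> masked Lab mean."""
    rng = np.random.default_rng(12345)
    cam = random_camera(rng)
    chart_img, boxes, ref = render_chart_image(cam)
    correction = calibrate_from_chart(chart_img, boxes, ref)
    fish_cam = CameraModel(cam_matrix=cam.cam_matrix,
                           exposure_gain=float(rng.uniform(0.7, 1.1)))
    image, mask = render_fish_image(control_scene, fish_cam)
    meas = measure_fish_image(image, default_roi, correction,
                              control_scene.white_region,
                              background_reference_green())
    return {
        "measurement": meas,
        "image": image,
        "truth_mask": mask,
        "correction": correction,
        "fish_gain": fish_cam.exposure_gain,
    }


@pytest.fixture(scope="session")
def cohort_spline_fit():
    """Lactate cohort and its fitted spline mixed model (shared: slow fit)."""
    cohort = simulate_cohort(CohortSpec(seed=3))
    spec = st.DesignSpec(
        data=cohort, response="b", smooth="lactate",
        random_groups=("trial", "monitoring_period"), variance_power=True,
    )
    return cohort, st.fit_spline_mixed(spec)
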