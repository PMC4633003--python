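import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fvri.engine import FvriConfig, classify_frame, compute_fvri, score_frames
from fvri.normal_model import FALCAO2015_DEFAULT
from fvri.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Published 4×3 lesion contingency counts (FVRI rows: negative, incomplete,
#: complete, ectatic; classical columns: negative, intermediate, positive).
TABLE3_COUNTS = np.array(
    [
        [51, 49, 38],
        [57, 79, 119],
        [28, 84, 105],
        [0, 2, 6],
    ]
)


@pytest.fixture(scope="session")
def table3_counts():
    return TABLE3_COUNTS.copy()


@pytest.fixture(scope="session")
def small_sim():
    """A 10-patient default-condition cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=424242, n_patients=10))


@pytest.fixture(scope="session")
def small_scored(small_sim):
    return score_frames(small_sim.cohort, FALCAO2015_DEFAULT, FvriConfig())


def build_scored_artery(
    burdens,
    lumens=None,
    eem_pred=10.0,
    patient_id="P001",
    artery_id="P001-LAD",
    spacing=0.3,
    config=FvriConfig(),
):
    """Construct a scored artery table from a burden profile.

    When ``lumens`` is omitted the EEM area is fixed at 12 mm² and the lumen
    derived from the burden; otherwise EEM is set so lumen and burden are
    consistent.  FVRI and class columns are filled with the engine.
    """
    burdens = np.asarray(burdens, dtype=float)
    n = len(burdens)
    if lumens is None:
        eem = np.full(n, 12.0)
        lumen = eem * (1 - burdens / 100.0)
    else:
        lumen = np.asarray(lumens, dtype=float)
        eem = lumen / (1 - burdens / 100.0)
    plaque = eem - lumen
    fvri = np.array(
        [
            compute_fvri(e, eem_pred, p, config) if p > 0 else np.nan
            for e, p in zip(eem, plaque)
        ]
    )
    classes = [
        classify_frame(f if p > 0 else None, b, e, eem_pred, config)
        for f, p, b, e in zip(fvri, plaque, burdens, eem)
    ]
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "artery_id": artery_id,
            "vessel": "LAD",
            "frame_index": np.arange(n),
            "distance_mm": spacing * (np.arange(n) + 1),
            "lumen_area_mm2": lumen,
            "eem_area_mm2": eem,
            "plaque_media_area_mm2": plaque,
            "plaque_burden_pct": burdens,
            "eem_pred_mm2": eem_pred,
            "fvri": fvri,
            "remodeling_class": classes,
        }
    )
    for col in ("fibrous_mm2", "fibrofatty_mm2", "necrotic_mm2", "dense_calcium_mm2"):
        df[col] = np.nan
    return df


@pytest.fixture
def scored_artery_builder():
    return build_scored_artery
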