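import numpy as np
import pandas as pd
import pytest

from furrowscan import field_simulator as fsim
from furrowscan.plot_pipeline import process_session
from furrowscan.sweep_geometry import SensorGeometry


@pytest.fixture(scope="session")
def geom():
    return SensorGeometry()


@pytest.fixture(scope="session")
def full_session(tmp_path_factory):
    """One full-layout (1728-plot) simulated session, processed end to end.

    Expensive; shared by every test that needs the complete pipeline.
    """
    out = tmp_path_factory.mktemp("full_session")
    scene = fsim.generate_field(seed=11)
    track = fsim.PlatformTrack()
    result = fsim.simulate_session(scene, track, seed=11, out_dir=out)
    summary, counts = process_session(result.dat00, result.dat01, scene.layout)
    truth = pd.read_csv(result.truth_csv)
    return {
        "scene": scene, "track": track, "result": result,
        "summary": summary, "counts": counts, "truth": truth,
    }


def make_gradient_scene(n_cols=6, n_ranges=12, ch_range=(0.1, 1.6),
                        porosity=0.25, soil_roughness_mm=5.0):
    """Small scene whose plot heights sweep a prescribed range.

    Used for recovery studies: heights are assigned deterministically from
    ``ch_range`` (plot-id order) and covers follow the generator's
    logit-in-height default.
    """
    n_plots = n_cols * n_ranges
    scene = fsim.generate_field(
        seed=5, n_accessions=n_plots - 2, n_checks=1, check_reps=2,
        blocks=1, n_cols=n_cols, n_ranges=n_ranges,
        soil_roughness_mm=soil_roughness_mm,
    )
    ch = np.linspace(ch_range[0], ch_range[1], n_plots)
    cover = 1.0 / (1.0 + np.exp(-(-3.214 + 2.695 * ch)))
    scene.plants["canopy_height_m"] = ch
    scene.plants["cover_fraction"] = cover
    scene.plants["porosity"] = porosity
    scene.plants["row_halfwidth_m"] = fsim._cover_to_halfwidth(
        cover, np.full(n_plots, porosity), 0.76
    )
    return scene


@pytest.fixture(scope="session")
def gradient_session(tmp_path_factory):
    """Processed session over the height-gradient scene (72 plots)."""
    out = tmp_path_factory.mktemp("gradient_session")
    scene = make_gradient_scene()
    track = fsim.PlatformTrack()
    result = fsim.simulate_session(scene, track, seed=21, out_dir=out)
    summary, counts = process_session(result.dat00, result.dat01, scene.layout)
    truth = pd.read_csv(result.truth_csv)
    merged = summary.merge(truth, on="plot_id", suffixes=("", "_truth"))
    return {
        "scene": scene, "track": track, "result": result,
        "summary": summary, "counts": counts, "truth": truth,
        "merged": merged,
    }
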