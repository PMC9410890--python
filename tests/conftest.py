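import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from punctasurv.config import GeneratorConfig, GroupSpec
from punctasurv.imaging import process_movie
from punctasurv.synthetic import render_movie, sample_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A compact single-group cohort with aggregates and elevated hazard."""
    return GeneratorConfig(
        seed=424242,
        n_neurons_per_group=60,
        neurons_per_well=20,
        frame_shape=(384, 384),
        groups=(
            GroupSpec(
                "mix",
                aggregate_probability=0.5,
                baseline_hazard_per_interval=0.04,
                aggregate_hazard_multiplier=2.0,
            ),
        ),
    )


def match_tracks_to_truth(tracks, truth_well: pd.DataFrame, tol: float = 3.0):
    """Pair each track with the ground-truth neuron whose timepoint-1
    centroid is nearest (within ``tol`` pixels)."""
    pairs = []
    for tr in tracks:
        cy, cx = tr.rois[0].centroid
        d = np.hypot(truth_well["y_tp1"] - cy, truth_well["x_tp1"] - cx)
        j = d.idxmin()
        if d[j] < tol:
            pairs.append((tr, truth_well.loc[j]))
    return pairs


@pytest.fixture(scope="session")
def tracked_cohort(small_config):
    """Ground truth + death-annotated tracks for the small cohort, with
    track-to-truth matching."""
    truth = sample_cohort(small_config)
    all_pairs = []
    n_tracks = 0
    for well in truth["well"].unique():
        movie = render_movie(truth, small_config, well=well)
        tracks = process_movie(movie)
        n_tracks += len(tracks)
        all_pairs.extend(match_tracks_to_truth(tracks, truth[truth["well"] == well]))
    return {"truth": truth, "pairs": all_pairs, "n_tracks": n_tracks}
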