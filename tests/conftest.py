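import numpy as np
import pytest

import nuctrack as nt


@pytest.fixture(scope="session")
def nuc_cohort():
    """Standard nucleokinetic cohort: 100 tracks x 200 frames, seed 42."""
    return nt.simulate(
        nt.SimParams(mode=nt.Mode.NUC, n_tracks=100, n_frames=200, seed=42)
    )


@pytest.fixture(scope="session")
def mes_cohort():
    """Matched mesenchymal cohort at the 15-min preset."""
    return nt.simulate(
        nt.SimParams.for_mode("mes", n_tracks=100, n_frames=200, seed=43)
    )


@pytest.fixture(scope="session")
def sessile_cohort():
    """Sessile cohort calibrated so the median NC step is 0.12 um."""
    sigma = nt.jitter_for_noise_median(0.12)
    return nt.simulate(
        nt.SimParams.for_mode(
            "sessile", n_tracks=100, n_frames=200, jitter_sd_um=sigma, seed=7
        )
    )


@pytest.fixture(scope="session")
def nuc_summaries(nuc_cohort):
    return nt.summarize_tracks(nuc_cohort.tracks)


@pytest.fixture(scope="session")
def mes_summaries(mes_cohort):
    return nt.summarize_tracks(mes_cohort.tracks)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_track(cc, nc, track_id="t", interval=5.0, frame_index=None, phase=None):
    cc = np.asarray(cc, dtype=float)
    if frame_index is None:
        frame_index = np.arange(len(cc))
    return nt.CentroidTrack(
        track_id=track_id,
        frame_index=frame_index,
        cc=cc,
        nc=np.asarray(nc, dtype=float),
        frame_interval_min=interval,
        phase=phase,
    )
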