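import numpy as np
import pytest
from hypothesis import settings

import rppgstress as r
from rppgstress.hr_postprocess import clean_hr, moving_average5

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_video():
    """10 s pulsatile test video (3 windows) with a known ROI."""
    video = r.make_synthetic_video(duration_s=10, fps=30, pulse_bpm=72,
                                   frame_height=80, frame_width=100, seed=1)
    roi = r.extract_cheek_rois(video.face_box, (80, 100))
    return video, roi


@pytest.fixture(scope="session")
def cohort_datasets():
    """Default synthetic cohort run through the full feature pipeline."""
    records, series = r.make_synthetic_cohort(seed=1)
    raw = {s: moving_average5(v) for s, v in series.items()}
    clean = {s: clean_hr(raw[s]) for s in raw}
    return r.build_all_variants(records, raw, clean)
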