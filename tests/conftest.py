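import numpy as np
import pandas as pd
import pytest

from cuerate.cue_rates import SightingRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20150105)


def make_sighting(
    hour=10.0,
    bearing=200.0,
    range_m=1500.0,
    group=1,
    direction="south",
    beaufort=2,
    visibility=2,
    pod_id=None,
):
    return SightingRecord(
        time=pd.Timestamp("2015-01-05") + pd.Timedelta(hours=hour),
        bearing_deg=bearing,
        range_m=range_m,
        group_size=group,
        direction=direction,
        beaufort=beaufort,
        visibility_code=visibility,
        pod_id=pod_id,
    )


@pytest.fixture
def five_pod_sightings():
    """Five pods with hand-computable mean ranges and final group sizes.

    Qualifying southbound pods: 1 (mean 1500 m, size 2), 2 (mean 800 m,
    size 3), 5 (mean 2500 m, size 1).  Pod 3 is northbound, pod 4 sits
    at Beaufort 5 (excluded by the strict < 5 cutoff).
    """
    return [
        make_sighting(hour=9.0, range_m=1000, group=1, pod_id=1),
        make_sighting(hour=9.2, range_m=2000, group=2, pod_id=1),
        make_sighting(hour=10.0, range_m=700, group=3, pod_id=2),
        make_sighting(hour=10.1, range_m=900, group=3, pod_id=2),
        make_sighting(hour=11.0, range_m=1200, group=2, direction="north", pod_id=3),
        make_sighting(hour=12.0, range_m=3000, group=4, beaufort=5, pod_id=4),
        make_sighting(hour=13.0, range_m=2500, group=1, pod_id=5),
    ]
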