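import numpy as np
import pytest

from sorghead.region_analysis import CandidateRegion, extract_regions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def region_from_pixels(pixels) -> CandidateRegion:
    """Build a CandidateRegion directly from a pixel set (test helper)."""
    arr = np.asarray(sorted(pixels), dtype=np.int64)
    top, left = arr.min(axis=0)
    bottom, right = arr.max(axis=0)
    return CandidateRegion(
        region_id=0,
        pixels=arr,
        bbox=(int(top), int(left), int(bottom - top + 1), int(right - left + 1)),
        centroid=(float(arr[:, 0].mean()), float(arr[:, 1].mean())),
    )


def random_mask_region(rng, size=20, p=0.45):
    """One random connected region extracted from a random mask (or None)."""
    mask = rng.random((size, size)) < p
    regions = extract_regions(mask, min_area=1)
    if not regions:
        return None
    return regions[rng.integers(len(regions))]
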