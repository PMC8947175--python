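import numpy as np
import pytest

from mitopuncta import estimate_factors, preset, render


@pytest.fixture(scope="session")
def control_stacks():
    """Three rendered control fields of one synthetic batch."""
    return [render(preset("control", 101 + k))[0] for k in range(3)]


@pytest.fixture(scope="session")
def factors(control_stacks):
    """Batch calibration factors estimated from the control fields."""
    return estimate_factors(control_stacks)


def match_puncta(result, truth, max_dist_px=5.0):
    """Greedily match detected ectopic puncta to ground-truth centroids.

    Returns (n_matched, n_false_positive).
    """
    detections = [p for p in result.puncta if p.classification == "ectopic_mito"]
    gt = truth.of_type("ectopic_punctum")
    used = set()
    matched = 0
    for _, row in gt.iterrows():
        best, best_i = np.inf, None
        for i, p in enumerate(detections):
            if i in used:
                continue
            d = np.hypot(p.centroid[0] - row.row, p.centroid[1] - row.col)
            if d < best:
                best, best_i = d, i
        if best_i is not None and best <= max_dist_px:
            matched += 1
            used.add(best_i)
    return matched, len(detections) - matched
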