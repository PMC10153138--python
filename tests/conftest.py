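import numpy as np
import pytest
from scipy.spatial import cKDTree

from syncap import CapFieldSpec, SegmentationParams, label_map_table, segment_caps


@pytest.fixture
def cap_params() -> SegmentationParams:
    """Segmentation configuration used for the synthetic cap fields.

    Frangi scales 4 and 6 px match the synthetic furrow ridges (~2 px
    paint + PSF), giving a ridge response broad enough to survive the
    11-px median filter with a usable crest; everything else is the
    default recipe.
    """
    return SegmentationParams(frangi_scales_px=(4.0, 6.0))


def match_caps(gt_table, rec_table, pixel_size_um, tol_px=2.0):
    """One-to-one centroid matching of ground-truth caps to recovered regions.

    A truth cap is matched when its nearest recovered centroid lies
    within ``tol_px`` pixels and no other truth cap claims the same
    region. Returns (matched fraction, per-cap relative area errors of
    the matched pairs).
    """
    gtc = gt_table[["centroid_x_um", "centroid_y_um"]].to_numpy()
    rc = rec_table[["centroid_x_um", "centroid_y_um"]].to_numpy()
    d, j = cKDTree(rc).query(gtc)
    matched = d < tol_px * pixel_size_um
    claims = np.bincount(j[matched], minlength=len(rc))
    ok = matched & (claims[j] == 1)
    ga = gt_table["area_um2"].to_numpy()[ok]
    ra = rec_table["area_um2"].to_numpy()[j[ok]]
    return float(ok.mean()), np.abs(ra - ga) / ga


def segment_and_match(spec: CapFieldSpec, params: SegmentationParams):
    """Generate a field, segment it, and match regions to ground truth."""
    from syncap import generate_cap_field

    img, gt = generate_cap_field(spec)
    label_map = segment_caps(img, params)
    table = label_map_table(label_map, img)
    frac, errs = match_caps(gt.table, table, spec.pixel_size_um)
    return frac, errs, label_map, gt
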