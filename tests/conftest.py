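import numpy as np
import pytest

from cprnfl.geometry import RasterScan
from cprnfl.phantom import PhantomParams, make_truth

NOISELESS = dict(
    sigma_subject_um=0.0,
    sigma_scan_um=0.0,
    sigma_assessor_um=0.0,
    sigma_pixel_um=0.0,
    missing_quadrant_prob=0.0,
)


@pytest.fixture
def noiseless_params():
    """Default geometry/field, all error sources off."""
    return PhantomParams(**NOISELESS)


@pytest.fixture
def control_truth(noiseless_params):
    return make_truth(noiseless_params)


def constant_params(level: float = 100.0, **overrides) -> PhantomParams:
    """Params whose ground-truth field is the constant `level` outside the disc."""
    base = dict(
        base_temporal_um=level,
        base_nasal_um=level,
        peak_superior_um=level,
        peak_inferior_um=level,
        radial_decay_per_deg=0.0,
        **NOISELESS,
    )
    base.update(overrides)
    return PhantomParams(**base)


def field_scan(fn, n_ascans=400, n_bscans=400, extent=(8.0, 8.0), center=None, **kw) -> RasterScan:
    """A fully valid RasterScan whose thickness is fn(x_mm, y_mm) at pixel centres."""
    w, h = extent
    x = (np.arange(n_ascans) + 0.5) * (w / n_ascans)
    y = (np.arange(n_bscans) + 0.5) * (h / n_bscans)
    xx, yy = np.meshgrid(x, y)
    t = np.asarray(fn(xx, yy), dtype=float)
    t = np.broadcast_to(t, xx.shape).copy()
    return RasterScan(
        thickness=t,
        valid_mask=np.ones_like(t, dtype=bool),
        extent_x_mm=w,
        extent_y_mm=h,
        onh_center_mm=center or (w / 2, h / 2),
        **kw,
    )
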