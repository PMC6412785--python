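import numpy as np
import pytest

from multinuc import (
    CellFieldSpec,
    generate_cell_field,
)


@pytest.fixture(scope="session")
def field_88():
    """100-cell field with 88 multinucleated cells (the 48-h treatment level)."""
    spec = CellFieldSpec(n_cells=100, frac_multinucleated=0.88, seed=1)
    img, cmask, nmask, truth = generate_cell_field(spec)
    return spec, img, cmask, nmask, truth


@pytest.fixture(scope="session")
def big_nuclei_field():
    """Field whose nuclei are large (radius >= 8 px) and well separated,
    inside the segmentation-recovery guarantee."""
    spec = CellFieldSpec(
        n_cells=50, frac_multinucleated=0.5,
        cell_area_um2=(3000.0, 300.0), cell_area_bounds_um2=(2200.0, 3800.0),
        mono_ratio_pct=(12.0, 2.0), per_nucleus_ratio_pct=(9.0, 1.5),
        seed=2,
    )
    img, cmask, nmask, truth = generate_cell_field(spec)
    return spec, img, cmask, nmask, truth


@pytest.fixture
def disk_mask():
    """Rasterized filled disk of radius 50 px."""
    rr, cc = np.mgrid[0:120, 0:120]
    return (rr - 60.0) ** 2 + (cc - 60.0) ** 2 <= 50.0**2
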