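import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import shape

from erqc.detect import NucleusObject
from erqc.simulate import RenderSpec, render_duct
from erqc.stains import default_hdab_matrix, deconvolve, rgb_to_od

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_nucleus(mean_dab_od, label=1, area_um2=40.0, circularity=0.9,
                 mean_h_od=0.6, centroid=(10.0, 10.0), exclusion_code="none"):
    """Synthetic nucleus object for quantification tests (square boundary)."""
    side = np.sqrt(area_um2) / 0.5  # px at 0.5 um/px
    boundary = np.array([[0, 0], [side, 0], [side, side], [0, side], [0, 0]],
                        dtype=float)
    return NucleusObject(
        label=label, centroid=centroid, area_um2=area_um2,
        circularity=circularity, mean_hematoxylin_od=mean_h_od,
        mean_dab_od=mean_dab_od, boundary=boundary,
        exclusion_code=exclusion_code,
    )


@pytest.fixture(scope="session")
def hdab():
    return default_hdab_matrix()


@pytest.fixture(scope="session")
def rendered_duct(hdab):
    """One rendered duct (12 nuclei, noise sd 0.02) with its unmixed maps."""
    dab_values = tuple(np.linspace(0.12, 0.9, 12))
    spec = RenderSpec(n_nuclei=12, dab_od_values=dab_values)
    image, truth, annotation = render_duct(spec, seed=5)
    maps = deconvolve(rgb_to_od(image), hdab)
    polygon = shape(annotation["features"][0]["geometry"])
    return {"spec": spec, "image": image, "truth": truth,
            "annotation": annotation, "maps": maps, "polygon": polygon}
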