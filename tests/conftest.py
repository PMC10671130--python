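import numpy as np
import pytest

from dyescan.classify import PixelClassMap
from dyescan.synthetic import ScanRecipe, generate_scan


@pytest.fixture(scope="session")
def two_shade_scan():
    """A 300x300 synthetic scan with both shade populations and its labels."""
    recipe = ScanRecipe(width=300, height=300, shade1_frac=(0.3,),
                        shade2_frac=(0.2,), seed=11)
    scan, labels = generate_scan(recipe, 1)
    return recipe, scan, labels


def make_classmap(labels, layer_index=1, n_layers=1):
    """Wrap a raw label grid in a PixelClassMap."""
    return PixelClassMap(labels=np.asarray(labels, dtype=np.uint8),
                         layer_index=layer_index, n_layers=n_layers)
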