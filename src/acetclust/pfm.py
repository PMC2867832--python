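"""Access to the packaged default TATA position-frequency matrix."""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io import read_pfm


def default_tata_pfm() -> np.ndarray:
    """The JASPAR TBP (TATA-box) count matrix shipped with the package."""
    ref = resources.files("acetclust").joinpath("data/tata_jaspar.pfm")
    with resources.as_file(ref) as path:
        return read_pfm(path)
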