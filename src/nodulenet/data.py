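"""Training-unit container shared by the pipeline modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Sample:
    """One training case: a nodule cube, one reader's mask cube, and the
    labels attached to that reader's annotation.

    ``labels`` holds ``individual`` (0/1), ``panel`` (0/1 or the EXCLUDED
    sentinel) and ``semantic`` (feature name -> 0/1).
    """
    nodule_cube: np.ndarray
    mask_cube: np.ndarray
    labels: dict
    nodule_id: str
    reader_id: str

    def stacked(self) -> np.ndarray:
        return np.stack([self.nodule_cube, self.mask_cube]).astype(np.float32)
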