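"""Clonal vs subclonal labeling from multi-region presence patterns.

In multi-region sequencing of one tumor, a somatic variant present in every
sampled region must predate the most recent common ancestor of the sampled
lineages and is labeled *clonal*; a variant present in only a proper subset
of regions (including a single region) arose later and is *subclonal*.
The rule is purely combinatorial given a presence matrix; probabilistic
presence calling (as done by phylogeny tools that model sequencing error)
is out of scope here — presence comes from the read-count rule in
:mod:`enhmut.variant_filtering`.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Sequence

import numpy as np

__all__ = ["PresenceMatrix", "label_clonality"]


@dataclasses.dataclass
class PresenceMatrix:
    """Boolean variant-by-sample presence matrix for one patient."""

    variants: Sequence[Hashable]
    samples: Sequence[str]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"presence matrix shape {self.present.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(self.samples) < 2:
            raise ValueError(
                "clonality is undefined with fewer than 2 samples per patient"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in presence matrix")


def label_clonality(pm: PresenceMatrix) -> dict[Hashable, str]:
    """Label every variant ``clonal`` (present in all samples) or
    ``subclonal`` (present in a proper subset).

    Raises if any variant is present in zero samples — such a variant
    should never have survived filtering.
    """
    n_present = pm.present.sum(axis=1)
    if (n_present == 0).any():
        bad = [v for v, n in zip(pm.variants, n_present) if n == 0]
        raise ValueError(f"variant(s) present in zero samples: {bad[:5]}")
    n_samples = len(pm.samples)
    return {
        v: ("clonal" if n == n_samples else "subclonal")
        for v, n in zip(pm.variants, n_present)
    }
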