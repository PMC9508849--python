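"""Reference synthetic fixtures used by the validation suite and examples.

Two regimes matter for validating the empirical-p-value statistic:

* the **dense** default cell (200 emitters in the default 96 px stack) —
  used for null calibration, where no enrichment exists and only the
  test's type-I behaviour is at stake;
* the **sparse-loci** cell (50 emitters in an 11 x 288 x 288 stack with a
  7.6 um lateral semi-axis) — used for planted-signal recovery, the
  rotation negative control, and the PCC contrast.  The rotation null and
  the "every planted spot flagged" idealization hold only when
  marker-enriched loci occupy a negligible fraction of the nuclear volume;
  in the dense cell the enrichment bumps would cover most of the nucleus
  and contaminate the reference intensity distribution.  Real nuclei are
  in the sparse regime: a nucleus is orders of magnitude larger than a
  reader-binding locus.
"""

from __future__ import annotations

import numpy as np

from .core import ImageStack, Spot
from .simulate import (DEFAULT_GEOMETRY, EmitterSpec, GroundTruth, MarkerSpec,
                       NucleusSpec, generate_cell)

__all__ = [
    "dense_cell",
    "sparse_cell",
    "spots_from_truth",
    "SPARSE_SHAPE_ZYX",
    "SPARSE_NUCLEUS",
]

SPARSE_SHAPE_ZYX = (11, 288, 288)
SPARSE_NUCLEUS = NucleusSpec(semi_axes_um=(0.9, 7.6, 7.6))


def dense_cell(seed: int, coloc_fraction: float = 0.0, enrichment: float = 3.0,
               n_spots: int = 200) -> tuple[ImageStack, GroundTruth]:
    """Default-scale cell: ~200 emitters, 96 px stack."""
    return generate_cell(
        NucleusSpec(),
        EmitterSpec(n_spots=n_spots),
        MarkerSpec(coloc_fraction=coloc_fraction, enrichment=enrichment),
        geometry=DEFAULT_GEOMETRY,
        seed=seed,
    )


def sparse_cell(seed: int, coloc_fraction: float, enrichment: float = 10.0,
                n_spots: int = 50) -> tuple[ImageStack, GroundTruth]:
    """Sparse-loci cell: 50 emitters in a large nucleus, enrichment bumps
    covering <1% of the nuclear support."""
    return generate_cell(
        SPARSE_NUCLEUS,
        EmitterSpec(n_spots=n_spots),
        MarkerSpec(coloc_fraction=coloc_fraction, enrichment=enrichment),
        geometry=DEFAULT_GEOMETRY,
        seed=seed,
        shape_zyx=SPARSE_SHAPE_ZYX,
    )


def spots_from_truth(truth: GroundTruth, cell_id: int = 0) -> list[Spot]:
    """Wrap ground-truth emitter positions as Spot records, to exercise the
    co-localization statistic independently of the detector."""
    return [
        Spot(
            cell_id=cell_id,
            position_px=tuple(float(c) for c in pos),
            amplitude=1.0,
            background=0.0,
            sigma_px=1.0,
            fit_quality=0.0,
            z_slice_of_max=int(round(pos[0])),
            spot_id=i,
        )
        for i, pos in enumerate(truth.emitter_zyx)
    ]
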