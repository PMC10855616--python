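"""Stochastic dilution-series model of the PCR limit of detection.

At low template input the relevant physics is sampling statistics: the number
of amplifiable genome copies pipetted into a reaction is Poisson-distributed
around the copy number implied by the DNA mass, and a reaction succeeds only
if at least ``min_detectable_copies`` land in the tube. For a threshold of
one copy the detection probability has the closed form 1 - exp(-lambda),
which the simulator converges to — this is the analytic anchor for the
model. Real assays fall short of single-copy efficiency for reasons the
publication record rarely quantifies (polymerase efficiency, inhibition,
fragmentation in processed food), so the wet-lab limit of detection is not a
prediction of this simulator; instead, ``min_detectable_copies`` (and an
effective genome size folding in chloroplast copy number) let a user ask
which efficiency is consistent with an observed limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_model import PanelValidationError

__all__ = [
    "DilutionPoint",
    "mass_to_copies",
    "detection_probability",
    "simulate_dilution_series",
    "DEFAULT_MASS_GRID_PG",
]

AVOGADRO = 6.02214076e23
MEAN_BP_WEIGHT_G_PER_MOL = 650.0  # average double-stranded base-pair weight

#: Ten-fold series from 10 ng down to 0.01 pg, the span probed in the assay.
DEFAULT_MASS_GRID_PG = (1e4, 1e3, 1e2, 1e1, 1.0, 0.1, 0.01)


@dataclass(frozen=True)
class DilutionPoint:
    """One mass on the dilution ladder with its simulated detection tally."""

    mass_pg: float
    expected_copies: float
    replicates: int
    detected_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.detected_count <= self.replicates):
            raise PanelValidationError("detected_count outside [0, replicates]")

    @property
    def detection_fraction(self) -> float:
        return self.detected_count / self.replicates


def mass_to_copies(mass_pg: float, genome_size_bp: float) -> float:
    """Genome copies contained in a DNA mass.

    copies = (mass_pg * 1e-12 g * N_A) / (genome_size_bp * 650 g/mol).
    Use an *effective* genome size (nuclear genome divided by per-cell
    chloroplast copy number) when modeling a plastid-encoded target.
    """
    if mass_pg <= 0 or genome_size_bp <= 0:
        raise PanelValidationError("mass and genome size must be positive")
    return (mass_pg * 1e-12 * AVOGADRO) / (genome_size_bp * MEAN_BP_WEIGHT_G_PER_MOL)


def detection_probability(expected_copies: float, min_detectable_copies: int) -> float:
    """P(Poisson(lambda) >= k): the analytic detection probability."""
    from scipy import stats

    return float(stats.poisson.sf(min_detectable_copies - 1, expected_copies))


def simulate_dilution_series(
    masses_pg: Sequence[float],
    genome_size_bp: float,
    replicates: int,
    min_detectable_copies: int = 1,
    seed: int | None = None,
) -> list[DilutionPoint]:
    """Monte-Carlo dilution series.

    For each mass, draws ``replicates`` Poisson copy numbers around the
    expected copy count and tallies reactions reaching the detection
    threshold. Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise PanelValidationError("replicates must be >= 1")
    if min_detectable_copies < 1:
        raise PanelValidationError("min_detectable_copies must be >= 1")
    rng = np.random.default_rng(seed)
    points = []
    for mass in masses_pg:
        lam = mass_to_copies(mass, genome_size_bp)
        copies = rng.poisson(lam, size=replicates)
        detected = int(np.count_nonzero(copies >= min_detectable_copies))
        points.append(
            DilutionPoint(
                mass_pg=float(mass),
                expected_copies=float(lam),
                replicates=int(replicates),
                detected_count=detected,
            )
        )
    return points


def dilution_table(points: Sequence[DilutionPoint]) -> pd.DataFrame:
    """Tabulate a simulated series (one row per mass) for export."""
    return pd.DataFrame(
        [
            {
                "mass_pg": p.mass_pg,
                "expected_copies": p.expected_copies,
                "replicates": p.replicates,
                "detected_count": p.detected_count,
                "detection_fraction": p.detection_fraction,
            }
            for p in points
        ]
    )
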