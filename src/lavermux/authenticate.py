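"""Species calling and label verification from electrophoresis peaks.

Bridges the instrument readout to the authentication verdict: called peaks
are binned onto the panel's expected amplicon sizes to give a per-species
presence/absence pattern (plus internal-control status), and each product's
pattern is compared against its declared label. The assay is qualitative, so
a *specific* label is judged by strict set equality: a product labelled as
one species but containing that species **and** others is mismatched —
undeclared admixture is exactly the fraud the assay exists to catch. Generic
trade-name labels ("Laver") declare no species and cannot mismatch, but they
stay in the survey denominator when the mislabeling rate is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ce_sim import Peak
from .panel_model import (
    SPECIES_CODES,
    DetectionPattern,
    Panel,
    PanelValidationError,
    ProductRecord,
)

__all__ = [
    "AuthResult",
    "DEFAULT_NAME_MAP",
    "classify_pattern",
    "authenticate_product",
    "pattern_from_record",
    "summarize_products",
    "AmbiguousPeakError",
    "UnknownLabelError",
]

#: Label spellings seen on commercial packaging, mapped to species codes.
DEFAULT_NAME_MAP: dict[str, str] = {
    "n. yezoensis": "NY",
    "neopyropia yezoensis": "NY",
    "porphyra yezoensis": "NY",
    "pyropia yezoensis": "NY",
    "n. tenera": "NT",
    "neopyropia tenera": "NT",
    "porphyra tenera": "NT",
    "pyropia tenera": "NT",
    "n. haitanensis": "NH",
    "neoporphyra haitanensis": "NH",
    "porphyra haitanensis": "NH",
    "pyropia haitanensis": "NH",
    "n. dentata": "ND",
    "neoporphyra dentata": "ND",
    "porphyra dentata": "ND",
    "pyropia dentata": "ND",
    "p. suborbiculata": "PS",
    "pyropia suborbiculata": "PS",
    "porphyra suborbiculata": "PS",
    "n. seriata": "NS",
    "neoporphyra seriata": "NS",
    "porphyra seriata": "NS",
    "pyropia seriata": "NS",
}


class AmbiguousPeakError(ValueError):
    """A peak lies within tolerance of two different expected sizes."""


class UnknownLabelError(KeyError):
    """A specific (non-generic) label has no species-code mapping."""


def classify_pattern(peaks: Sequence[Peak], panel: Panel) -> DetectionPattern:
    """Bin called peaks onto the panel's expected sizes.

    Each peak is assigned to the nearest expected amplicon size if it lies
    within ``panel.size_tolerance_bp``; a species is detected when its bin
    receives at least one peak, and the run is valid (``control_ok``) when the
    internal-control bin does. Peaks matching no bin are recorded as
    anomalies, not errors. Requires the panel's sizes to be separated by more
    than twice the tolerance so binning is unambiguous.
    """
    expected = panel.expected_sizes  # species_code -> size, CTRL included once
    tol = panel.size_tolerance_bp
    sizes = sorted(expected.values())
    for a, b in zip(sizes, sizes[1:]):
        if b - a <= 2 * tol:
            raise AmbiguousPeakError(
                f"expected sizes {a} and {b} bp are within 2 x tolerance ({tol} bp); "
                "peak assignment would be ambiguous"
            )
    detected = {code: False for code in SPECIES_CODES}
    control_ok = False
    anomalies: list[float] = []
    for peak in peaks:
        hits = [
            code for code, size in expected.items() if abs(peak.size_bp - size) <= tol
        ]
        if not hits:
            anomalies.append(round(float(peak.size_bp), 2))
            continue
        code = hits[0]  # unique by the gap precondition
        if code == "CTRL":
            control_ok = True
        else:
            detected[code] = True
    return DetectionPattern(detected=detected, control_ok=control_ok,
                            anomalies=tuple(anomalies))


@dataclass(frozen=True)
class AuthResult:
    """Verdict for one product: declared vs detected species sets.

    ``mismatch`` is None (not applicable) for generic labels and for
    invalid runs (internal control absent); otherwise it is the strict
    set-inequality flag. ``undeclared_detected`` lists species found but not
    declared; ``declared_not_detected`` the converse.
    """

    product_id: str
    label_specific: bool
    declared: frozenset[str]
    detected: frozenset[str]
    mismatch: bool | None
    undeclared_detected: frozenset[str]
    declared_not_detected: frozenset[str]
    valid_run: bool = True

    def __post_init__(self) -> None:
        if not self.label_specific and self.mismatch is not None:
            raise PanelValidationError(
                f"{self.product_id}: mismatch must be not-applicable for generic labels"
            )


def authenticate_product(
    record: ProductRecord,
    name_map: Mapping[str, str] | None = None,
) -> AuthResult:
    """Compare one product's detection pattern against its declared label."""
    name_map = DEFAULT_NAME_MAP if name_map is None else name_map
    detected = frozenset(record.pattern.detected_set)
    if not record.pattern.control_ok:
        return AuthResult(
            product_id=record.product_id,
            label_specific=not record.label_is_generic,
            declared=frozenset(),
            detected=detected,
            mismatch=None,
            undeclared_detected=frozenset(),
            declared_not_detected=frozenset(),
            valid_run=False,
        )
    if record.label_is_generic:
        return AuthResult(
            product_id=record.product_id,
            label_specific=False,
            declared=frozenset(),
            detected=detected,
            mismatch=None,
            undeclared_detected=detected,
            declared_not_detected=frozenset(),
        )
    key = record.declared_label.strip().lower()
    if key not in name_map:
        raise UnknownLabelError(
            f"{record.product_id}: no species mapping for label "
            f"{record.declared_label!r}"
        )
    declared = frozenset({name_map[key]})
    return AuthResult(
        product_id=record.product_id,
        label_specific=True,
        declared=declared,
        detected=detected,
        mismatch=declared != detected,
        undeclared_detected=detected - declared,
        declared_not_detected=declared - detected,
    )


def pattern_from_record(
    record: ProductRecord, panel: Panel
) -> list[tuple[float, float]]:
    """Amplicon (length, amount) list that would reproduce a record's pattern,
    internal control included — input for :func:`lavermux.ce_sim.simulate_trace`."""
    sizes = panel.expected_sizes
    amps = [(float(sizes["CTRL"]), 1.0)] if record.pattern.control_ok else []
    amps += [
        (float(sizes[code]), 1.0)
        for code in SPECIES_CODES
        if record.pattern.detected[code]
    ]
    return amps


def summarize_products(
    results: Iterable[AuthResult],
    records: Iterable[ProductRecord],
) -> dict:
    """Survey-level summary: product counts by type and label class,
    per-species detection frequency, and the mislabeling rate (mismatched
    products as a percentage of *all* surveyed products)."""
    results = list(results)
    records = list(records)
    n = len(records)
    food_counts = (
        pd.Series([r.food_type for r in records]).value_counts().to_dict()
    )
    specific = [r for r in records if not r.label_is_generic]
    detection_freq = {
        code: sum(rec.pattern.detected[code] for rec in records)
        for code in SPECIES_CODES
    }
    mismatched = sorted(
        (res.product_id for res in results if res.mismatch),
        key=lambda s: (len(s), s),
    )
    return {
        "n_products": n,
        "by_food_type": food_counts,
        "n_specific_labels": len(specific),
        "n_generic_labels": n - len(specific),
        "detection_frequency": detection_freq,
        "mismatched_ids": mismatched,
        "n_mismatched": len(mismatched),
        "percent_mismatched": 100.0 * len(mismatched) / n if n else 0.0,
        "invalid_runs": sorted(
            res.product_id for res in results if not res.valid_run
        ),
    }
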