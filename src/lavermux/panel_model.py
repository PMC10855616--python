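"""Assay panel data model: primers, species pairs, multiplex sets, product records.

The panel describes a capillary-electrophoresis multiplex PCR assay for six
commercially important laver species (genera *Neoporphyra*, *Neopyropia* and
*Pyropia*), each identified by a species-specific primer pair targeting the
chloroplast rbcL or rbcS gene and producing a diagnostic amplicon size, plus a
universal eukaryote 18S rRNA pair (89 bp) that serves as an internal
amplification control in every reaction.

Species codes used throughout::

    NY  Neopyropia yezoensis      211 bp (rbcL)
    NT  Neopyropia tenera         169 bp (rbcL)
    NH  Neoporphyra haitanensis   127 bp (rbcS)
    ND  Neoporphyra dentata       274 bp (rbcS)
    PS  Pyropia suborbiculata     117 bp (rbcL)
    NS  Neoporphyra seriata       195 bp (rbcL)
    CTRL  18S rRNA internal control  89 bp
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "IUPAC_DNA",
    "SPECIES_CODES",
    "Primer",
    "AssayPair",
    "Panel",
    "DetectionPattern",
    "ProductRecord",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "load_products",
    "bundled_panel",
    "bundled_products",
    "bundled_accessions",
]

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: The six target species, in the column order used by product tables.
SPECIES_CODES = ("NY", "NT", "NH", "ND", "PS", "NS")

_VALID_CODES = frozenset(SPECIES_CODES) | {"CTRL"}
_FOOD_TYPES = frozenset({"dried", "roasted", "seasoned"})

_PANEL_COLUMNS = [
    "set_id",
    "species_code",
    "species_name",
    "gene",
    "primer_name",
    "role",
    "sequence",
    "expected_size_bp",
    "concentration_uM",
]

_PRODUCT_COLUMNS = [
    "product_id",
    "country",
    "market",
    "food_type",
    "declared_label",
    *SPECIES_CODES,
]


class PanelFormatError(ValueError):
    """A panel or product table is structurally malformed (missing columns, ...)."""


class PanelValidationError(ValueError):
    """A table parsed but violates a panel invariant (bad base, duplicate, ...)."""


def _clean_sequence(seq: str, *, context: str = "") -> str:
    """Strip whitespace from a printed primer sequence and validate IUPAC codes."""
    cleaned = "".join(str(seq).split()).upper()
    if not cleaned:
        raise PanelValidationError(f"empty primer sequence {context}".strip())
    bad = sorted(set(cleaned) - IUPAC_DNA)
    if bad:
        raise PanelValidationError(
            f"non-IUPAC character(s) {bad} in sequence {context}".strip()
        )
    return cleaned


@dataclass(frozen=True)
class Primer:
    """A single oligo, written 5'->3'."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"
    concentration_uM: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _clean_sequence(self.sequence, context=f"of primer {self.name}")
        )
        if self.role not in ("forward", "reverse"):
            raise PanelValidationError(
                f"primer {self.name}: role must be forward/reverse, got {self.role!r}"
            )
        if self.concentration_uM < 0:
            raise PanelValidationError(
                f"primer {self.name}: negative concentration {self.concentration_uM}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssayPair:
    """A forward/reverse primer pair diagnosing one species (or the control)."""

    species_code: str
    species_name: str
    gene: str
    forward: Primer
    reverse: Primer
    expected_size_bp: int
    set_id: int

    def __post_init__(self) -> None:
        if self.species_code not in _VALID_CODES:
            raise PanelValidationError(f"unknown species code {self.species_code!r}")
        if self.expected_size_bp < len(self.forward) + len(self.reverse):
            raise PanelValidationError(
                f"{self.species_code}: expected size {self.expected_size_bp} bp is "
                f"shorter than the combined primer footprints "
                f"({len(self.forward)} + {len(self.reverse)} nt)"
            )
        if self.forward.role != "forward" or self.reverse.role != "reverse":
            raise PanelValidationError(f"{self.species_code}: primer roles are swapped")

    @property
    def is_control(self) -> bool:
        return self.species_code == "CTRL"


@dataclass(frozen=True)
class Panel:
    """An ordered multiplex panel split into reaction sets.

    ``size_tolerance_bp`` is the +/- window used when binning called
    electrophoresis peaks onto expected sizes; ``min_separation_bp`` is the
    design target for the size gap between amplicons co-amplified in one set.
    The gap target is audited by :mod:`lavermux.panel_qc`, not enforced here:
    the shipped panel itself places the 89 bp control within 40 bp of its
    nearest neighbour in both sets.
    """

    pairs: tuple[AssayPair, ...]
    size_tolerance_bp: int = 3
    min_separation_bp: int = 40

    def __post_init__(self) -> None:
        seen: dict[tuple[int, str], AssayPair] = {}
        for pair in self.pairs:
            key = (pair.set_id, pair.species_code)
            if key in seen:
                raise PanelValidationError(
                    f"species {pair.species_code} duplicated within set {pair.set_id}"
                )
            seen[key] = pair
        # Size must identify the species unambiguously panel-wide; the shared
        # CTRL pair legitimately carries the same 89 bp size in both sets.
        by_code: dict[str, int] = {}
        for pair in self.pairs:
            prev = by_code.setdefault(pair.species_code, pair.expected_size_bp)
            if prev != pair.expected_size_bp:
                raise PanelValidationError(
                    f"{pair.species_code}: inconsistent expected sizes {prev} and "
                    f"{pair.expected_size_bp}"
                )
        sizes = sorted(by_code.values())
        for a, b in zip(sizes, sizes[1:]):
            if a == b:
                raise PanelValidationError(f"expected size {a} bp assigned to two species")
        for set_id, members in self.sets.items():
            if "CTRL" not in members:
                raise PanelValidationError(f"set {set_id} lacks the 18S internal control")

    @property
    def sets(self) -> dict[int, tuple[str, ...]]:
        """Mapping set_id -> member species codes, in panel order."""
        out: dict[int, list[str]] = {}
        for pair in self.pairs:
            out.setdefault(pair.set_id, []).append(pair.species_code)
        return {k: tuple(v) for k, v in out.items()}

    @property
    def species_pairs(self) -> tuple[AssayPair, ...]:
        return tuple(p for p in self.pairs if not p.is_control)

    @property
    def control_pair(self) -> AssayPair:
        for pair in self.pairs:
            if pair.is_control:
                return pair
        raise PanelValidationError("panel has no internal-control pair")

    def pair_for(self, species_code: str, set_id: int | None = None) -> AssayPair:
        for pair in self.pairs:
            if pair.species_code == species_code and (set_id is None or pair.set_id == set_id):
                return pair
        raise KeyError(species_code)

    @property
    def expected_sizes(self) -> dict[str, int]:
        """Species code -> diagnostic amplicon size (bp), control included once."""
        return {
            pair.species_code: pair.expected_size_bp
            for pair in self.pairs
        }


@dataclass(frozen=True)
class DetectionPattern:
    """Presence/absence of the six species plus internal-control status.

    ``control_ok`` False marks a failed reaction (the 89 bp universal product
    is expected from any eukaryote DNA), not a negative sample. ``anomalies``
    lists peak sizes that fell in no expected-size bin.
    """

    detected: Mapping[str, bool]
    control_ok: bool
    anomalies: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in SPECIES_CODES if c not in self.detected]
        if missing:
            raise PanelValidationError(f"pattern lacks species keys: {missing}")
        object.__setattr__(
            self, "detected", {c: bool(self.detected[c]) for c in SPECIES_CODES}
        )

    @property
    def detected_set(self) -> frozenset[str]:
        return frozenset(c for c, hit in self.detected.items() if hit)


@dataclass(frozen=True)
class ProductRecord:
    """One surveyed commercial product: provenance, label, and PCR pattern."""

    product_id: str
    country: str
    market: str
    food_type: str
    declared_label: str
    pattern: DetectionPattern

    def __post_init__(self) -> None:
        if self.food_type not in _FOOD_TYPES:
            raise PanelValidationError(
                f"{self.product_id}: food type {self.food_type!r} not in {sorted(_FOOD_TYPES)}"
            )

    @property
    def label_is_generic(self) -> bool:
        """True for trade-name labels ('Laver') that declare no species."""
        return self.declared_label.strip().lower() in {"laver", "kim", "nori", "zicai"}


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"{path}: empty table") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing column(s) {missing}")
    return df


def load_panel(path: str | Path, *, size_tolerance_bp: int = 3,
               min_separation_bp: int = 40) -> Panel:
    """Read a panel TSV (one row per primer, two rows per pair) into a Panel.

    Sequences may contain internal whitespace as printed in primer tables;
    it is stripped. Raises :class:`PanelFormatError` for missing columns and
    :class:`PanelValidationError` for bad bases or duplicated species.
    """
    df = _read_table(path, _PANEL_COLUMNS)
    if df.empty:
        raise PanelFormatError(f"{path}: table has a header but no rows")
    pairs: list[AssayPair] = []
    for (set_id, code), grp in df.groupby(["set_id", "species_code"], sort=False):
        roles = dict(zip(grp["role"], grp.index))
        if set(roles) != {"forward", "reverse"} or len(grp) != 2:
            raise PanelValidationError(
                f"set {set_id} species {code}: need exactly one forward and one "
                f"reverse primer, got roles {sorted(grp['role'])}"
            )
        prim = {}
        for _, row in grp.iterrows():
            prim[row["role"]] = Primer(
                name=row["primer_name"],
                sequence=_clean_sequence(
                    row["sequence"], context=f"(primer {row['primer_name']})"
                ),
                role=row["role"],
                concentration_uM=float(row["concentration_uM"]),
            )
        sizes = set(grp["expected_size_bp"].astype(int))
        if len(sizes) != 1:
            raise PanelValidationError(
                f"set {set_id} species {code}: forward/reverse rows disagree on size"
            )
        pairs.append(
            AssayPair(
                species_code=str(code),
                species_name=str(grp["species_name"].iloc[0]),
                gene=str(grp["gene"].iloc[0]),
                forward=prim["forward"],
                reverse=prim["reverse"],
                expected_size_bp=sizes.pop(),
                set_id=int(set_id),
            )
        )
    return Panel(tuple(pairs), size_tolerance_bp=size_tolerance_bp,
                 min_separation_bp=min_separation_bp)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a Panel back to the TSV layout accepted by :func:`load_panel`."""
    rows = []
    for pair in panel.pairs:
        for primer in (pair.forward, pair.reverse):
            rows.append(
                {
                    "set_id": pair.set_id,
                    "species_code": pair.species_code,
                    "species_name": pair.species_name,
                    "gene": pair.gene,
                    "primer_name": primer.name,
                    "role": primer.role,
                    "sequence": primer.sequence,
                    "expected_size_bp": pair.expected_size_bp,
                    "concentration_uM": primer.concentration_uM,
                }
            )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_products(path: str | Path) -> tuple[ProductRecord, ...]:
    """Read a product-survey TSV into ProductRecords.

    Pattern cells must be "+" or "-" (the typographic minus is accepted).
    The internal control is taken as passed for every surveyed row.
    """
    df = _read_table(path, _PRODUCT_COLUMNS)
    ids = list(df["product_id"])
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise PanelValidationError(f"duplicated product id(s): {dupes}")
    records = []
    for _, row in df.iterrows():
        detected = {}
        for code in SPECIES_CODES:
            cell = str(row[code]).strip()
            if cell == "+":
                detected[code] = True
            elif cell in {"-", "−", "–"}:
                detected[code] = False
            else:
                raise PanelValidationError(
                    f"product {row['product_id']}, column {code}: expected +/-, "
                    f"got {cell!r}"
                )
        records.append(
            ProductRecord(
                product_id=str(row["product_id"]),
                country=str(row["country"]),
                market=str(row["market"]),
                food_type=str(row["food_type"]),
                declared_label=str(row["declared_label"]),
                pattern=DetectionPattern(detected=detected, control_ok=True),
            )
        )
    return tuple(records)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("lavermux.data") / name)


def bundled_panel(**kwargs) -> Panel:
    """The shipped six-species panel (plus 18S control) with printed sizes
    {274, 211, 195, 169, 127, 117, 89} bp and per-set primer concentrations."""
    return load_panel(_data_path("primer_panel.tsv"), **kwargs)


def bundled_products() -> tuple[ProductRecord, ...]:
    """The shipped 40-product market survey table."""
    return load_products(_data_path("commercial_products.tsv"))


def bundled_accessions() -> pd.DataFrame:
    """GenBank accessions of the rbcL/rbcS reference records, as a DataFrame."""
    return _read_table(_data_path("reference_accessions.tsv"),
                       ["species", "algae_class", "gene", "accession"])
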