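"""Mismatch-tolerant primer binding search and amplicon prediction.

This is the computational stand-in for running the assay on a DNA template:
find every position where a primer can anneal (allowing a configurable number
of mismatches, but never within the 3'-terminal anchor — polymerase extension
is intolerant of 3' mispairing), pair forward and reverse sites into candidate
amplicons, and tabulate cross-amplification of a whole panel against a set of
templates as a specificity matrix.

Conventions: coordinates are 0-based, half-open, on the plus strand. A
"plus"-strand binding site means the primer sequence itself matches the plus
strand left to right (the primer extends rightward); a "minus"-strand site
means the primer anneals to the plus strand, i.e. its reverse complement
matches the plus strand (the primer extends leftward). Amplicon length counts
both primer footprints, matching how electrophoresis sizes the product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .panel_model import IUPAC_DNA, AssayPair, Panel, PanelValidationError, Primer

__all__ = [
    "TemplateSeq",
    "BindingSite",
    "Amplicon",
    "reverse_complement",
    "find_binding_sites",
    "predict_amplicons",
    "specificity_matrix",
    "read_templates",
]

DEFAULT_MAX_MISMATCH = 0
DEFAULT_ANCHOR_LEN = 3
DEFAULT_MAX_AMPLICON_BP = 3000

_TEMPLATE_ALPHABET = frozenset("ACGTN")

# 4-bit encoding: one bit per canonical base; an IUPAC code is the union of
# its bases. Template N encodes to 0 so it matches nothing (low-quality
# sequence should not create binding sites).
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_PRIMER_CODE = np.zeros(128, dtype=np.uint8)
for code, bases in _IUPAC_SETS.items():
    _PRIMER_CODE[ord(code)] = sum(_BITS[b] for b in bases)
_TEMPLATE_CODE = np.zeros(128, dtype=np.uint8)
for base, bit in _BITS.items():
    _TEMPLATE_CODE[ord(base)] = bit


@dataclass(frozen=True)
class TemplateSeq:
    """A template DNA sequence (FASTA record or synthetic construct)."""

    id: str
    sequence: str
    description: str = ""
    species_label: str | None = None

    def __post_init__(self) -> None:
        seq = str(self.sequence).upper()
        if not seq:
            raise PanelValidationError(f"template {self.id}: empty sequence")
        bad = sorted(set(seq) - _TEMPLATE_ALPHABET)
        if bad:
            raise PanelValidationError(
                f"template {self.id}: characters {bad} outside A/C/G/T/N"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """One primer hybridization locus, in plus-strand coordinates."""

    template_id: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product spanning both primer footprints."""

    species_code: str
    template_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC ambiguity support (R<->Y, N<->N, ...)."""
    seq = str(seq).upper()
    bad = sorted(set(seq) - IUPAC_DNA)
    if bad:
        raise PanelValidationError(f"invalid DNA character(s) {bad}")
    return str(Seq(seq).reverse_complement())


def _encode_template(seq: str) -> np.ndarray:
    return _TEMPLATE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan(primer_bits: np.ndarray, template_bits: np.ndarray,
          max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
    """All start offsets where the encoded primer matches with <= max_mismatch
    mismatches, plus the per-window mismatch mask (windows x primer length)."""
    m, n = len(primer_bits), len(template_bits)
    if m > n:
        return np.empty(0, dtype=int), np.empty((0, m), dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, m)
    mismatch = (windows & primer_bits) == 0
    counts = mismatch.sum(axis=1)
    starts = np.nonzero(counts <= max_mismatch)[0]
    return starts, mismatch[starts]


def find_binding_sites(
    primer: Primer | str,
    template: TemplateSeq,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> list[BindingSite]:
    """Locate every hybridization site of ``primer`` on both template strands.

    A site qualifies when it has at most ``max_mismatch`` mismatches overall
    and zero mismatches within the ``anchor_len`` 3'-terminal bases of the
    primer. IUPAC-degenerate primer bases match any base in their set;
    template ``N`` mismatches everything. Results are sorted by
    (strand, start) with plus before minus.
    """
    if max_mismatch < 0 or anchor_len < 0:
        raise PanelValidationError("max_mismatch and anchor_len must be >= 0")
    seq = primer.sequence if isinstance(primer, Primer) else str(primer).upper()
    bad = sorted(set(seq) - IUPAC_DNA)
    if bad:
        raise PanelValidationError(f"invalid primer character(s) {bad}")
    if not seq:
        raise PanelValidationError("empty primer")
    m = len(seq)
    anchor = min(anchor_len, m)
    tmpl_bits = _encode_template(template.sequence)
    sites: list[BindingSite] = []

    # Plus strand: primer as written matches the plus strand; its 3' end is
    # the rightmost position of the window.
    bits = _PRIMER_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    starts, mismatch = _scan(bits, tmpl_bits, max_mismatch)
    for start, row in zip(starts, mismatch):
        tpm = int(row[m - anchor:].sum()) if anchor else 0
        if tpm == 0:
            sites.append(BindingSite(template.id, "plus", int(start),
                                     int(start) + m, int(row.sum()), 0))

    # Minus strand: the primer anneals to the plus strand, so its reverse
    # complement matches the plus strand and the primer's 3' end maps to the
    # leftmost position of the window.
    rc_bits = _PRIMER_CODE[
        np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)
    ]
    starts, mismatch = _scan(rc_bits, tmpl_bits, max_mismatch)
    for start, row in zip(starts, mismatch):
        tpm = int(row[:anchor].sum()) if anchor else 0
        if tpm == 0:
            sites.append(BindingSite(template.id, "minus", int(start),
                                     int(start) + m, int(row.sum()), 0))

    sites.sort(key=lambda s: (s.strand != "plus", s.start))
    return sites


def predict_amplicons(
    pair: AssayPair,
    template: TemplateSeq,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_amplicon_bp: int = DEFAULT_MAX_AMPLICON_BP,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Every convergent forward/reverse site combination within the length cap
    yields an amplicon: forward on plus paired with reverse on minus
    downstream of it, and the mirror orientation (forward on minus with
    reverse on plus upstream). Zero amplicons is a valid outcome.
    """
    fwd = find_binding_sites(pair.forward, template, max_mismatch, anchor_len)
    rev = find_binding_sites(pair.reverse, template, max_mismatch, anchor_len)
    out: list[Amplicon] = []
    for f in fwd:
        for r in rev:
            if f.strand == "plus" and r.strand == "minus":
                start, end = f.start, r.end
            elif f.strand == "minus" and r.strand == "plus":
                start, end = r.start, f.end
            else:
                continue
            length = end - start
            if 0 < length <= max_amplicon_bp:
                out.append(Amplicon(pair.species_code, template.id, start, end, f, r))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def specificity_matrix(
    panel: Panel,
    templates: Iterable[TemplateSeq],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_amplicon_bp: int = DEFAULT_MAX_AMPLICON_BP,
) -> pd.DataFrame:
    """Cross-amplification table: predicted amplicon counts, species x template.

    Rows are the panel's species codes plus CTRL (the shared 18S pair is
    evaluated once); columns follow the template order given. The in-silico
    analogue of running every singleplex reaction against every specimen.
    """
    templates = list(templates)
    row_codes: list[str] = []
    row_pairs: list[AssayPair] = []
    for pair in panel.pairs:
        if pair.species_code in row_codes:
            continue  # CTRL is shared between sets
        row_codes.append(pair.species_code)
        row_pairs.append(pair)
    data = {
        t.id: [
            len(predict_amplicons(p, t, max_mismatch, max_amplicon_bp))
            for p in row_pairs
        ]
        for t in templates
    }
    return pd.DataFrame(data, index=row_codes, dtype=int)


def read_templates(path: str | Path) -> list[TemplateSeq]:
    """Load templates from a (multi-record) FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            TemplateSeq(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    if not records:
        raise PanelValidationError(f"{path}: no FASTA records found")
    return records
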