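"""Panel quality audit: Tm, GC, primer-dimer risk, amplicon size separation.

A multiplex set only works if (i) all primers anneal at the common cycling
temperature, (ii) no two primers are complementary enough to form dimers that
steal polymerase and dNTPs, and (iii) the product sizes within a set are far
enough apart to be resolved by electrophoresis. The audit quantifies each of
these; it flags rather than raises, since a designed panel can knowingly
violate a soft target (the shipped panel places the 89 bp control 38 bp and
28 bp from its nearest neighbours while the species amplicons keep gaps of
at least 42 bp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

from Bio.SeqUtils import MeltingTemp, gc_fraction

from .panel_model import Panel, PanelValidationError, Primer

__all__ = [
    "PrimerQC",
    "PrimerPairQC",
    "SetQC",
    "QCReport",
    "melting_temperature",
    "dimer_score",
    "audit_panel",
]

DEFAULT_NA_MM = 50.0
DEFAULT_PRIMER_NM = 400.0  # 0.4 uM, the singleplex per-primer concentration
THREE_PRIME_WINDOW = 5

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PrimerQC:
    name: str
    length_nt: int
    gc_fraction: float
    tm_celsius: float


@dataclass(frozen=True)
class PrimerPairQC:
    primer_a: str
    primer_b: str
    max_dimer_score: int
    three_prime_dimer_score: int


@dataclass(frozen=True)
class SetQC:
    set_id: int
    sizes_bp: tuple[int, ...]  # sorted ascending, control included
    species_sizes_bp: tuple[int, ...]
    min_pairwise_separation_bp: int | None  # None when <2 members
    species_min_separation_bp: int | None
    separation_ok: bool
    species_separation_ok: bool


@dataclass(frozen=True)
class QCReport:
    primers: tuple[PrimerQC, ...]
    primer_pairs: tuple[PrimerPairQC, ...]
    sets: tuple[SetQC, ...]

    def to_dict(self) -> dict:
        return {
            "primers": [asdict(p) for p in self.primers],
            "primer_pairs": [asdict(p) for p in self.primer_pairs],
            "sets": [asdict(s) for s in self.sets],
        }


def melting_temperature(
    primer: Primer | str,
    na_mM: float = DEFAULT_NA_MM,
    primer_nM: float = DEFAULT_PRIMER_NM,
) -> float:
    """Nearest-neighbor melting temperature (Celsius).

    Uses the unified Allawi & SantaLucia (1997) duplex parameters with the
    SantaLucia (1998) entropy-based monovalent-salt correction, assuming the
    primer is not self-complementary and is in excess over template
    (Tm = dH / (dS + R ln(Ct/4)) with Ct the total strand concentration).
    Degenerate bases have no single dH/dS and are rejected.
    """
    seq = primer.sequence if isinstance(primer, Primer) else str(primer).upper()
    if any(c not in "ACGT" for c in seq):
        raise PanelValidationError(
            f"Tm undefined for degenerate/invalid sequence {seq!r}"
        )
    if len(seq) < 8:
        raise PanelValidationError(f"sequence too short for a NN Tm estimate: {seq!r}")
    if na_mM <= 0 or primer_nM <= 0:
        raise PanelValidationError("salt and primer concentrations must be positive")
    return float(
        MeltingTemp.Tm_NN(
            seq,
            nn_table=MeltingTemp.DNA_NN3,  # Allawi & SantaLucia 1997
            Na=na_mM,
            dnac1=primer_nM / 2,
            dnac2=primer_nM / 2,
            saltcorr=5,  # SantaLucia 1998: dS += 0.368 (N-1) ln[Na+]
            selfcomp=False,
        )
    )


def dimer_score(a: Primer | str, b: Primer | str) -> tuple[int, int]:
    """Ungapped antiparallel primer-dimer score.

    Slides the two oligos against each other in the annealing (antiparallel)
    orientation and, at each offset, counts Watson-Crick complementary
    positions. Returns ``(max_dimer_score, three_prime_dimer_score)``:
    the best count over all offsets, and the best count restricted to
    positions lying within either primer's five 3'-terminal bases (the
    extension-prone end; complementarity there seeds amplifiable dimers).
    """
    sa = (a.sequence if isinstance(a, Primer) else str(a).upper())
    sb = (b.sequence if isinstance(b, Primer) else str(b).upper())
    na, nb = len(sa), len(sb)
    best = best3 = 0
    # Antiparallel alignment: position i of a pairs with position j of b where
    # i + j = k for a constant k per offset (a 5'->3' against b 3'->5').
    for k in range(na + nb - 1):
        total = total3 = 0
        for i in range(max(0, k - nb + 1), min(na, k + 1)):
            j = k - i
            if _WC.get(sa[i]) == sb[j]:
                total += 1
                if i >= na - THREE_PRIME_WINDOW or j >= nb - THREE_PRIME_WINDOW:
                    total3 += 1
        best = max(best, total)
        best3 = max(best3, total3)
    return best, best3


def _separation(sizes: tuple[int, ...]) -> int | None:
    if len(sizes) < 2:
        return None
    return min(b - a for a, b in itertools.pairwise(sorted(sizes)))


def audit_panel(
    panel: Panel,
    na_mM: float = DEFAULT_NA_MM,
    primer_nM: float = DEFAULT_PRIMER_NM,
) -> QCReport:
    """Compute the full QC report for a panel. Never raises on a soft failure;
    size-separation shortfalls are reported via the ok flags."""
    primers: dict[str, Primer] = {}
    for pair in panel.pairs:
        for primer in (pair.forward, pair.reverse):
            primers.setdefault(primer.name, primer)

    primer_qc = tuple(
        PrimerQC(
            name=p.name,
            length_nt=len(p),
            gc_fraction=float(gc_fraction(p.sequence)),
            tm_celsius=melting_temperature(p, na_mM, primer_nM),
        )
        for p in primers.values()
    )

    pair_qc = []
    names = list(primers)
    for i, name_a in enumerate(names):
        for name_b in names[i:]:  # self-dimers included
            mx, tp = dimer_score(primers[name_a], primers[name_b])
            pair_qc.append(PrimerPairQC(name_a, name_b, mx, tp))

    set_qc = []
    for set_id, members in panel.sets.items():
        sizes = tuple(sorted(
            panel.pair_for(code, set_id).expected_size_bp for code in members
        ))
        species_sizes = tuple(sorted(
            panel.pair_for(code, set_id).expected_size_bp
            for code in members if code != "CTRL"
        ))
        min_sep = _separation(sizes)
        sp_sep = _separation(species_sizes)
        set_qc.append(
            SetQC(
                set_id=set_id,
                sizes_bp=sizes,
                species_sizes_bp=species_sizes,
                min_pairwise_separation_bp=min_sep,
                species_min_separation_bp=sp_sep,
                separation_ok=(min_sep is None or min_sep >= panel.min_separation_bp),
                species_separation_ok=(sp_sep is None or sp_sep >= panel.min_separation_bp),
            )
        )
    return QCReport(primer_qc, tuple(pair_qc), tuple(set_qc))
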