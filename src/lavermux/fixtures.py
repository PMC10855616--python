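"""Synthetic template construction with planted primer binding sites.

Real chloroplast reference records live in GenBank and cannot be assumed
present, so the test substrate is synthetic: random background DNA of a
chosen GC fraction with a primer pair's binding sites planted at exact
positions, rejection-checked so that no *additional* site for the relevant
primers arises by chance. A full reference set mimics a specificity
experiment's sample layout: one stand-in template per target species (its own
diagnostic sites plus a universal 18S site) and one decoy per non-target
seaweed (18S site only), so the cross-amplification matrix over the set is
exactly the planted pattern.

Backgrounds are i.i.d. draws and share nothing with real chloroplast
sequence beyond GC content; they validate the machinery, not the primers'
biological specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .insilico_pcr import (
    TemplateSeq,
    find_binding_sites,
    predict_amplicons,
    reverse_complement,
)
from .panel_model import AssayPair, Panel, PanelValidationError

__all__ = [
    "SyntheticSpec",
    "make_synthetic_template",
    "random_background",
    "build_reference_set",
    "bundled_synthetic_refs",
    "write_fasta",
    "NON_TARGET_SPECIES",
]

#: Seed used to generate the shipped data/synthetic_refs.fasta.
BUNDLED_REFS_SEED = 0

DEFAULT_GC_BACKGROUND = 0.40
_MAX_REJECTION_ROUNDS = 200

#: Non-target seaweeds used as specificity decoys, in sample-layout order
#: (four close red-algal relatives, then brown algae and an outgroup).
NON_TARGET_SPECIES = (
    "Porphyra koreana",
    "Neopyropia katadae",
    "Pyropia kuniedae",
    "Pyropia ishigecola",
    "Undaria pinnatifida",
    "Costaria costata",
    "Undaria crenata",
    "Saccharina japonica",
    "Saccharina sculpera",
    "Sargassum fusiforme",
    "Gracilaria vermiculophylla",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic template carrying one plantable amplicon."""

    pair: AssayPair
    amplicon_length_bp: int
    flank_left_bp: int = 100
    flank_right_bp: int = 100
    seed: int = 0
    gc_background: float = DEFAULT_GC_BACKGROUND

    def __post_init__(self) -> None:
        floor = len(self.pair.forward) + len(self.pair.reverse)
        if self.amplicon_length_bp < floor:
            raise PanelValidationError(
                f"amplicon length {self.amplicon_length_bp} bp cannot hold both "
                f"primer footprints ({floor} nt)"
            )
        if not (0.0 < self.gc_background < 1.0):
            raise PanelValidationError("gc_background must be in (0, 1)")
        if self.flank_left_bp < 0 or self.flank_right_bp < 0:
            raise PanelValidationError("flanks must be >= 0")


def random_background(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with i.i.d. bases at the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _assemble(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    fwd = spec.pair.forward.sequence
    rev_rc = reverse_complement(spec.pair.reverse.sequence)
    insert_len = spec.amplicon_length_bp - len(fwd) - len(rev_rc)
    return "".join(
        [
            random_background(spec.flank_left_bp, spec.gc_background, rng),
            fwd,
            random_background(insert_len, spec.gc_background, rng),
            rev_rc,
            random_background(spec.flank_right_bp, spec.gc_background, rng),
        ]
    )


def _clean_for(pairs: list[AssayPair], template: TemplateSeq,
               expected: dict[str, int]) -> bool:
    """True iff each pair yields exactly the expected number of amplicons and
    no primer has more binding sites than the construction planted."""
    for pair in pairs:
        want = expected.get(pair.species_code, 0)
        if len(predict_amplicons(pair, template, max_mismatch=0)) != want:
            return False
        for primer in (pair.forward, pair.reverse):
            if len(find_binding_sites(primer, template, max_mismatch=0)) != want:
                return False
    return True


def make_synthetic_template(spec: SyntheticSpec) -> TemplateSeq:
    """Build one template on which ``spec.pair`` amplifies exactly once.

    The forward primer is planted verbatim and the reverse primer's reverse
    complement downstream of it so the product has exactly
    ``amplicon_length_bp``; the random background is rejection-sampled until
    neither primer has any spurious zero-mismatch site.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_REJECTION_ROUNDS):
        seq = _assemble(spec, rng)
        template = TemplateSeq(
            id=f"{spec.pair.species_code}_synthetic",
            sequence=seq,
            description=(
                f"synthetic template, planted {spec.pair.species_code} amplicon "
                f"{spec.amplicon_length_bp} bp, seed={spec.seed}"
            ),
            species_label=spec.pair.species_name,
        )
        if _clean_for([spec.pair], template, {spec.pair.species_code: 1}):
            return template
    raise RuntimeError("rejection sampling failed to produce a clean background")


def build_reference_set(panel: Panel, seed: int = 0) -> list[TemplateSeq]:
    """Synthetic stand-ins for a full specificity experiment.

    Returns one template per target species (diagnostic sites plus an 18S
    internal-control site) followed by one decoy per non-target seaweed (18S
    site only). Every template is rejection-checked against the *whole*
    panel, so the specificity matrix over the set is exactly diagonal for the
    species rows with an all-ones control row.
    """
    ctrl = panel.control_pair
    all_pairs = list(dict.fromkeys(panel.pairs))  # CTRL de-duplicated by identity
    templates: list[TemplateSeq] = []
    rng = np.random.default_rng(seed)

    def plant(pair_specs: list[tuple[AssayPair, int]], tid: str, label: str) -> TemplateSeq:
        expected = {pair.species_code: 1 for pair, _ in pair_specs}
        for _ in range(_MAX_REJECTION_ROUNDS):
            parts = [random_background(60, DEFAULT_GC_BACKGROUND, rng)]
            for pair, length in pair_specs:
                fwd = pair.forward.sequence
                rev_rc = reverse_complement(pair.reverse.sequence)
                insert = length - len(fwd) - len(rev_rc)
                parts += [fwd, random_background(insert, DEFAULT_GC_BACKGROUND, rng),
                          rev_rc, random_background(60, DEFAULT_GC_BACKGROUND, rng)]
            template = TemplateSeq(
                id=tid, sequence="".join(parts),
                description=f"synthetic specificity stand-in for {label}, seed={seed}",
                species_label=label,
            )
            if _clean_for(all_pairs, template, expected):
                return template
        raise RuntimeError(f"could not build a clean template for {tid}")

    for pair in panel.species_pairs:
        if any(t.id == f"{pair.species_code}_synthetic" for t in templates):
            continue  # panel order may repeat species across sets
        templates.append(
            plant(
                [(pair, pair.expected_size_bp), (ctrl, ctrl.expected_size_bp)],
                f"{pair.species_code}_synthetic",
                pair.species_name,
            )
        )
    for species in NON_TARGET_SPECIES:
        tid = species.replace(" ", "_").replace(".", "") + "_synthetic"
        templates.append(plant([(ctrl, ctrl.expected_size_bp)], tid, species))
    return templates


def bundled_synthetic_refs() -> list[TemplateSeq]:
    """The shipped synthetic specificity reference set (seed 0); identical to
    ``build_reference_set(bundled_panel(), seed=BUNDLED_REFS_SEED)``."""
    import importlib.resources

    from .insilico_pcr import read_templates

    return read_templates(
        Path(importlib.resources.files("lavermux.data") / "synthetic_refs.fasta")
    )


def write_fasta(templates: list[TemplateSeq], path: str | Path) -> None:
    """Write templates as uncompressed FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for t in templates:
            header = t.id if not t.description else f"{t.id} {t.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(t.sequence), 60):
                fh.write(t.sequence[i:i + 60] + "\n")
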