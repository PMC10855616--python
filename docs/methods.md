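# Methods

`lavermux` models a capillary-electrophoresis multiplex PCR assay that
distinguishes six commercially traded laver species by diagnostic amplicon
size. This note records the models behind each component, the defaults and
why they were chosen, and what the synthetic test substrate does and does not
establish.

## The assay being modelled

Six species-specific primer pairs target the chloroplast rbcL or rbcS genes —
regions conserved within a species but polymorphic between species — and a
universal eukaryote 18S rRNA pair (89 bp product) runs in every reaction as
an internal amplification control: its absence marks a failed reaction, not a
negative sample. The pairs are split into two multiplex sets so that products
co-amplified in one tube differ enough in size to be resolved
electrophoretically:

| set | species (code) | gene | amplicon (bp) | primer conc. (µM) |
|----|----|----|----|----|
| 1 | *Neoporphyra haitanensis* (NH) | rbcS | 127 | 1.6 |
| 1 | *Neopyropia tenera* (NT) | rbcL | 169 | 1.8 |
| 1 | *Neopyropia yezoensis* (NY) | rbcL | 211 | 0.8 |
| 1 | 18S control (CTRL) | 18S rRNA | 89 | 0.2 |
| 2 | *Neoporphyra dentata* (ND) | rbcS | 274 | 0.6 |
| 2 | *Pyropia suborbiculata* (PS) | rbcL | 117 | 2.6 |
| 2 | *Neoporphyra seriata* (NS) | rbcL | 195 | 0.32 |
| 2 | 18S control (CTRL) | 18S rRNA | 89 | 0.4 |

Set membership follows the layout the concentrations are bound to. A
market-class grouping (stone laver {ND, NS, PS} vs traditional laver
{NY, NT, NH}) is sometimes quoted for the same assay; it is noted as a
comment in the bundled panel file but not used, because the optimized
concentrations only exist for the layout above. Thermal-cycling parameters
(94 °C denaturation, 60 °C annealing, 40 cycles) are treated as metadata:
nothing in the package simulates reaction thermodynamics.

## In-silico PCR

Primer binding is a sequence-matching model, deliberately free of
hybridization thermodynamics. A primer binds at a position if it aligns with
at most `max_mismatch` mismatches overall **and** zero mismatches in the
`anchor_len` 3'-terminal bases. Defaults are `max_mismatch = 0` and
`anchor_len = 3`: polymerase extension is highly sensitive to 3'-terminal
mispairing, and with no published mismatch-tolerance data for these primers a
conservative default is the defensible one; both are configurable.
IUPAC-degenerate primer bases match any base in their set; a template `N`
matches nothing, so low-quality sequence cannot create sites. Degenerate
template bases other than N are rejected at load (the panel's primers are
fully specified, and templates are expected to be plain sequence).

Coordinates are 0-based half-open on the plus strand. A convergent
forward/reverse site combination yields an amplicon whose length spans both
primer footprints (the quantity electrophoresis actually sizes); products
longer than `max_amplicon_bp` (default 3000 bp, generous against the assay's
89–274 bp design range) are discarded. Both template orientations are
handled symmetrically. The search is a vectorised bitmask comparison over
sliding windows; its correctness is pinned, in tests, to an independent
character-by-character sliding-window oracle across random instances and
mismatch budgets 0–2.

The specificity matrix counts predicted amplicons for every (pair, template)
cell, the in-silico analogue of running each singleplex reaction against
every specimen; the control row appears once even though the 18S pair sits
in both sets.

## Panel QC

* **Melting temperature** — nearest-neighbor model with the unified Allawi &
  SantaLucia (1997) duplex parameters and the SantaLucia (1998) entropy salt
  correction, at 50 mM monovalent cation and 400 nM total primer (the
  singleplex per-primer concentration); Tm = ΔH/(ΔS + R ln(Cₜ/4)). Computed
  via Biopython's `Tm_NN` and cross-checked in tests against a hand-summed
  implementation of the same published table.
* **Dimer risk** — ungapped antiparallel alignment scan: the maximum count
  of Watson–Crick complementary positions over all offsets, plus the same
  maximum restricted to either primer's five 3'-terminal bases (3'-anchored
  complementarity is what seeds extensible primer dimers). No hairpin or
  full secondary-structure folding; that is out of scope.
* **Size separation** — within each set, the minimum pairwise gap between
  expected sizes, evaluated twice: over all members, and over species
  amplicons only. The design target of ≥ 40 bp is a report-only flag, not an
  invariant, because the panel itself places the 89 bp control 38 bp (set 1)
  and 28 bp (set 2) from its nearest neighbour while the species amplicons
  keep gaps of 42/42 and 78/79 bp. The audit documents this: the ≥ 40 bp
  rule evidently refers to the species amplicons, with the control peak
  relying on CE resolution far finer than 28 bp.

## Electropherogram simulation and peak calling

Chip-based CE instruments report size-calibrated traces, so simulation works
directly on a bp axis (default 50–400 bp, 0.25 bp grid) rather than modelling
migration time. Each amplicon adds a Gaussian of width
σ = max(0.5 bp, 0.4 % × size) — a stated, configurable stand-in for the
resolution of a DNA 1000-class kit, for which no printed resolution data
exist — with height proportional to its relative amount. Baseline noise is
additive Gaussian (seeded) and the trace is clipped at zero.

The caller thresholds local maxima at `min_height_fraction` (default 0.05) of
the trace maximum and an absolute floor of 5 × noise_sd, requires prominence
of half the threshold (so shoulders on a saturated baseline are not called),
and refines each apex by three-point parabolic interpolation; area is the
trapezoidal integral between the peak's base points. Property tests show
planted peaks ≥ 5 bp apart at ≤ 2 % noise are recovered within ±1 bp across
100 seeds, and that the panel's tightest spacing (117/127 bp) is always
resolved — at σ ≈ 0.5 bp those peaks are ~10σ apart, so this is expected by
construction, not a discovery about the instrument.

## Pattern classification and authentication

Called peaks are binned to the nearest expected size within
`size_tolerance_bp` (default ±3 bp; the panel's minimum inter-size gap of
10 bp exceeds twice the tolerance, which classification enforces as a
precondition). A species is detected if its bin receives a peak; the run is
valid only if the control bin does; unassigned peaks are recorded as
anomalies rather than errors.

A specific label is judged by **strict set equality** between declared and
detected species. This is the semantics the assay needs: a product labelled
as one species but containing it *plus* undeclared cheaper species is
mislabelled even though the declared species is present. Generic trade-name
labels ("Laver") declare no species, so no mismatch verdict applies — but
such products stay in the denominator of the survey-level mislabeling
percentage, which is mismatched products over *all* products surveyed. On
the bundled 40-product survey this yields 6 mismatched products
(P26, P30, P31, P32, P34, P37) = 15.0 %.

## Dilution-series sensitivity model

At low input the controlling statistics are Poissonian: a reaction receives
`Poisson(λ)` genome copies, with λ from mass via
copies = mass · N_A / (genome_size · 650 g/mol), and detects if at least
`min_detectable_copies` arrive. For a single-copy threshold the detection
probability is 1 − e^(−λ), the closed form the simulator is tested against.
The default mass ladder is the standard ten-fold series 10 ng → 0.01 pg.
Deliberately **not** modelled: amplification efficiency, inhibition, and
template fragmentation — so the simulator does not predict a wet-lab limit
of detection. Instead `min_detectable_copies` and an *effective* genome size
(nuclear size divided by per-cell plastid copy number, folding in the
multi-copy advantage of chloroplast targets) let a user ask what efficiency
is consistent with an observed limit.

## Synthetic templates

Because chloroplast reference records cannot be assumed locally available,
the test substrate is synthetic: i.i.d. random background at 40 % GC (typical
of the AT-rich rbcL/rbcS regions these primers target) with primer sites
planted at exact positions, rejection-sampled until no spurious
zero-mismatch site for any panel primer remains. The shipped
`synthetic_refs.fasta` (seed 0) mirrors a specificity experiment's layout:
six target stand-ins (own sites + 18S site) and eleven decoys for the
non-target seaweeds (18S site only), so the specificity matrix over the set
is exactly diagonal with an all-ones control row. A chance match of a
≥ 17-mer primer in random background is ~4⁻¹⁷ per position, so rejection
rarely triggers.

What passing on this substrate shows: the search, pairing, sizing, calling
and classification machinery is correct end to end. What it does not show:
that the primers are biologically specific — synthetic flanks share nothing
with real chloroplast sequence beyond GC content, and cross-reaction against
real near-neighbour genomes can only be assessed on real records (the
bundled accession table lists them for users with GenBank access).

## Numerical and degenerate-input choices

Tolerances in tests mirror the models: Tm agreement with the independent
oracle to 0.1 °C; peak sizing to ±1 bp (±0.5 bp noise-free); Monte-Carlo
checks to 3 standard errors with fixed seeds. Degenerate inputs are handled
explicitly: empty tables and missing columns are format errors naming the
problem; a single-member set has no pairwise separation and reports
not-applicable with a passing flag; an empty peak list classifies as an
invalid run (control absent); zero predicted amplicons is a valid result,
not an error. All randomness flows through seeded `numpy` generators; equal
seeds give bit-identical traces, templates and dilution tallies.

## Problem sizes

Default verification runs are desk-scale: 200+ random oracle instances for
the search, 100 seeds for peak-recovery properties, 10⁴ replicates for the
Poisson check — all chosen as the smallest sizes at which the statistical
assertions (3 SE) are meaningful.
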