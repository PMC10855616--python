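# lavermux

In-silico multiplex PCR and capillary electrophoresis (CE) toolkit for
authenticating the six commercially traded laver species — *Neoporphyra
dentata*, *N. haitanensis*, *N. seriata*, *Neopyropia yezoensis*,
*N. tenera* and *Pyropia suborbiculata*.

Processed laver (dried, roasted, seasoned sheets) retains no morphology, so
cheaper species can silently replace or dilute the species on the label. A
CE-based multiplex PCR assay resolves this with six species-specific primer
pairs on the chloroplast rbcL/rbcS genes, each producing a diagnostic
amplicon size (274, 211, 195, 169, 127, 117 bp), plus a universal 18S rRNA
pair (89 bp) as an internal amplification control. `lavermux` is the
computational side of that assay, for assay developers and food-fraud
analysts: it predicts what the panel amplifies on any template, audits the
panel's design, simulates the CE readout, converts called peaks into species
presence/absence patterns, and turns declared-vs-detected comparisons into
mislabeling verdicts.

## What's in the box

* `panel_model` — the bundled primer panel (sequences, sizes, per-set
  concentrations), product-survey tables, and their TSV readers/writers.
* `insilico_pcr` — mismatch-tolerant binding-site search (3'-anchor
  enforced), amplicon prediction, and a panel × template specificity matrix.
* `panel_qc` — nearest-neighbor Tm, GC, primer-dimer scores, and amplicon
  size-separation audit per multiplex set.
* `ce_sim` — electropherogram simulation on a bp axis and peak
  calling/sizing with parabolic apex refinement.
* `authenticate` — peak → detection-pattern classification, label-mismatch
  verdicts (strict set semantics), and survey summaries.
* `sensitivity` — Poisson copy-number dilution-series simulator for
  limit-of-detection reasoning.
* `fixtures` — synthetic templates with planted primer sites, including a
  shipped 17-template specificity reference set.

The model details and their assumptions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Specificity of the whole panel against the bundled synthetic reference set
(six target stand-ins, then eleven non-target decoys carrying only the 18S
control site):

```python
>>> import lavermux as lm
>>> from lavermux import fixtures, insilico_pcr
>>> panel = lm.bundled_panel()
>>> refs = fixtures.bundled_synthetic_refs()
>>> insilico_pcr.specificity_matrix(panel, refs).iloc[:, :6]
      NH_synthetic  NT_synthetic  NY_synthetic  ND_synthetic  PS_synthetic  NS_synthetic
NH               1             0             0             0             0             0
NT               0             1             0             0             0             0
NY               0             0             1             0             0             0
CTRL             1             1             1             1             1             1
ND               0             0             0             1             0             0
PS               0             0             0             0             1             0
NS               0             0             0             0             0             1
```

Each cell counts predicted amplicons: every pair amplifies exactly its own
target, and the control amplifies everywhere — the pattern a clean
specificity experiment shows.

Simulate the CE trace of a mixed sample (control + NY + PS) at 2% baseline
noise, call peaks, and classify:

```python
>>> from lavermux import ce_sim
>>> trace = ce_sim.simulate_trace([(89.0, 1.0), (211.0, 1.0), (117.0, 1.0)],
...                               noise_sd=0.02, seed=1)
>>> for p in ce_sim.call_peaks(trace):
...     print(f"{p.size_bp:7.2f} bp  height {p.height:.3f}")
  88.98 bp  height 0.977
 116.99 bp  height 1.018
 210.90 bp  height 0.991
>>> pat = lm.classify_pattern(ce_sim.call_peaks(trace), panel)
>>> sorted(pat.detected_set), pat.control_ok
(['NY', 'PS'], True)
```

The three peaks land within 0.1 bp of the planted sizes; binning them onto
the panel (±3 bp tolerance) detects *N. yezoensis* and *P. suborbiculata*
with a valid internal control.

Authenticate the bundled 40-product market survey:

```python
>>> prods = lm.bundled_products()
>>> res = [lm.authenticate_product(r) for r in prods]
>>> s = lm.summarize_products(res, prods)
>>> s["by_food_type"], s["n_specific_labels"], s["n_generic_labels"]
({'seasoned': 26, 'roasted': 11, 'dried': 3}, 9, 31)
>>> s["mismatched_ids"], s["percent_mismatched"]
(['P26', 'P30', 'P31', 'P32', 'P34', 'P37'], 15.0)
>>> r31 = next(r for r in res if r.product_id == "P31")
>>> sorted(r31.declared), sorted(r31.detected), r31.mismatch
(['NT'], ['NY', 'PS'], True)
```

Six of the forty products (15%) carry labels inconsistent with their
detected species. P31 is the canonical substitution case: labelled as the
expensive *N. tenera*, it actually contains *N. yezoensis* and
*P. suborbiculata* and none of the declared species.

The same operations are available from a shell:

```sh
lavermux ispcr --templates refs.fasta --out matrix.tsv
lavermux panel-qc --out qc.json
lavermux simulate-ce --species NY,PS --seed 1 --out trace.tsv
lavermux authenticate --products products.tsv --out results.json
lavermux lod-sim --genome-size 1.3e9 --replicates 1000 --seed 7 --out lod.tsv
```

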