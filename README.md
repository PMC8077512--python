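# tagtrace

Quantitation of single-mRNA translation imaging in early embryos.

In the syncytial blastoderm of *Drosophila*, translation of individual mRNAs
can be visualized by tagging a reporter coding sequence with a SunTag epitope
array: ribosomes elongating through the array expose epitopes that recruit a
fluorescent single-chain antibody (scFv-mNeonGreen), so each translated mRNA
appears as a bright nascent-protein punctum colocalized with its smFISH spot.
Turning such images into biology requires a chain of quantitative steps:
detecting diffraction-limited 3D puncta, masking nuclear signal, assigning
cytoplasmic mRNAs to nuclear territories, recovering the anterior–posterior
(AP) axis from the nuclear field, pairing mRNA and protein channels, counting
ribosomes per translation site against a single-protein intensity standard,
measuring mRNA 5′–3′ end separation, and tracking membrane-tethered
translation sites through time. `tagtrace` implements that chain as a tested,
reusable library for anyone analysing SunTag/MS2-style translation imaging —
plus a synthetic-embryo generator that provides ground-truth data for every
stage, so the whole pipeline is verifiable without microscope data.

## The measurements

* **Translation efficiency per territory.** Cytoplasmic spots (outside every
  nucleus sphere) are assigned to the nearest nucleus. An mRNA is *translated*
  if a nascent-protein centroid lies within 0.6 µm (strict, one-to-one greedy
  matching by ascending distance). Per-territory percent translated is binned
  in 20 µm AP bins; positions are expressed in %EL (percent egg length,
  anterior = 0, egg length 500 µm).
* **AP axis from nuclei.** Nuclei within 1.5 internuclear distances of the
  frame edge are removed; boundary nuclei of the remaining cloud (alpha-shape)
  are split into two lateral arcs; the midline is a total-least-squares line
  through the midpoints of all cross pairs; the end of the axis with fewer
  nuclei (the narrowing anterior cap) fixes the orientation.
* **Ribosomes per site.** n̂ = I_site / (I_single · c), where I_single is the
  median intensity of unmatched single proteins (per embryo, after excluding
  bright aggregates) and c = (0.5·L_sun + L_hb)/(L_sun + L_hb) corrects for
  ribosomes that have translated only part of the epitope array. Counts ≤ 5
  are flagged low-confidence. The inter-ribosomal spacing is L/n̂ (nt).
* **mRNA compaction.** 5′ and 3′ probe spots < 0.3 µm apart (3D) are one
  molecule; a molecule is *translating* if a protein centroid is < 0.3 µm
  from its 5′ spot. Per-embryo medians are compared by a paired t-test.
* **Live tracking.** Nearest-neighbour linking with gap closing (6 µm travel
  cap, 5-frame gap cap), per-frame background subtraction, nearest-nucleus
  linking, and alignment of series to a nuclear-cycle onset.

## Worked example

Run the fixed-embryo workflow on a synthetic nc13 embryo:

```python
from tagtrace.pipeline import RunConfig, run_fixed_pipeline
from tagtrace.config import EmbryoConfig

report = run_fixed_pipeline(RunConfig(embryo=EmbryoConfig(rng_seed=1, nuclear_cycle="nc13")))
print(report.profile[["bin", "pct_el_mid", "total_mrna", "pct_translated"]].round(2))
sites = report.ribosome_sites
print(sites.loc[sites.confident, "n_ribosomes"].mean())
```

prints the AP-binned profile

```
 bin  pct_el_mid  total_mrna  pct_translated
   0         2.0         223           45.74
   1         6.0         403           47.39
   2        10.0         624           49.20
   3        14.0         577           50.26
   4        18.0         628           48.89
   5        22.0         688           48.40
   6        26.0         730           45.21
   7        30.0         825           48.24
   8        34.0        1264           49.13
   9        38.0          68           52.94
```

and a mean of `19.7` ribosomes per confident translation site. Read: at this
simulated cycle roughly half of cytoplasmic mRNAs are engaged by ribosomes in
every 20 µm bin across the expression domain (the generator's nc13 truth is a
flat 50%), each carrying ~20 ribosomes (truth: Poisson with mean 20, with the
single-protein standard recalibrated from the image itself: I_single = 103.0,
c = 0.8125).

The same workflow runs from the shell:

```bash
tagtrace simulate --seed 5 --cycle nc13 --out out/sim
tagtrace quantify-fixed --seed 5 --cycle nc13 --out out/qf
tagtrace track --seed 5 --out out/live
tagtrace detect out/stack.tif --out out/spots.tsv
```

All tables are tab-separated text; every run directory carries the full
parameter set (`run_config.yaml`) and a machine-readable log of record counts
at each filtering stage (`run_log.json`), stamped with a config hash.

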