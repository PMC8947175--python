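# mitopuncta

Semi-quantitative counting of **ectopic mitochondrial DNA** — dsDNA that has
leaked from mitochondria into the cytoplasm — in triple-stained fluorescence
microscopy images of cultured cells.

Cytosolic DNA is inflammatory (it feeds the cGAS–STING pathway) and shows up
in models of Parkinson's disease, aging, heart failure and cancer.  In a
triple stain the dsDNA antibody lights up everything: nuclei, intra-
mitochondrial nucleoids, and the cytoplasmic puncta of interest.  The two
marker channels — histone H2B for DNA of nuclear origin, Hsp60 for the
mitochondrial matrix — let the confounding signal be subtracted away, so that
what remains can be counted objectively.  The package is for microscopists
and cell biologists who want that count to be reproducible and scriptable:
it is a library plus a CLI, with a synthetic-image generator that stands in
for microscope data in all tests.

## Method

For one experiment batch, with control images `C`:

1. **Calibration.** Find the smallest scalars `x`, `y` such that in controls

   `dsDNA − x·Hsp60 ≤ 0` inside mitochondria, `dsDNA − y·H2B ≤ 0` inside nuclei.

   Implemented as a quantile (default 0.999; quantile 1 is the literal rule)
   of the pixelwise ratios `dsDNA/Hsp60` and `dsDNA/H2B` on marker-defined
   masks.  One `(x, y)` pair per batch, applied to every condition.
2. **Subtraction.** `Subtract-1 = clip(dsDNA − x·Hsp60, 0)`;
   `Subtract-2 = clip(dsDNA − x·Hsp60 − y·H2B, 0)`.  An optional linear
   contrast window, shared across the batch, can be applied.
3. **Binarize and count.** Otsu threshold (per image or pooled per batch),
   connected components, and a filter chain that gives each punctum exactly
   one class — first failing rule wins:
   area outside **[2, 20] μm²** → `rejected_size`;
   circularity `4πA/P²` below **0.1** → `rejected_shape`;
   Euler number < 1 (the component contains a hole — ring-shaped dsDNA of
   nuclear origin) → `nuclear_origin_donut`;
   histone overlap > 0.3 → `nuclear_origin_overlap`;
   otherwise → **`ectopic_mito`**.
   With `Subtract-1` (H2B not subtracted) the histone-overlap rule is the
   mandatory discriminator; with `Subtract-2` it is a safeguard.
4. **Normalise and compare.** Nuclei counted from the H2B channel (Otsu,
   hole filling, area floor, watershed split of touching nuclei) give the
   field-level ratio *ectopic dots per cell*.  Conditions are summarised as
   mean ± SEM over fields and compared with a two-sided Student's t-test
   (pooled variance).

## Worked example

No microscope data is needed; the built-in generator renders control,
TFAM-knockdown-like and GBA-knockdown-like fields with ground truth
(true bleed factors x = 1.5, y = 0.6):

```sh
mitopuncta simulate --preset control --n-fields 5 --seed 11 --out-dir fields/control
mitopuncta simulate --preset tfam_kd --n-fields 5 --seed 21 --out-dir fields/tfam
mitopuncta simulate --preset gba_kd  --n-fields 5 --seed 31 --out-dir fields/gba

mitopuncta calibrate --controls 'fields/control/*.ome.tif' --out factors.json
# x = 1.69603, y = 0.645238 -> factors.json

mitopuncta detect --factors factors.json --out puncta.csv \
    fields/control/*.ome.tif fields/tfam/*.ome.tif fields/gba/*.ome.tif
mitopuncta report --results puncta_per_image.csv --conditions conditions.csv \
    --out summary.csv --plot bars.png
```

(`conditions.csv` maps each `image_id` to its condition.)  Output:

```
condition  n_images  n_excluded  mean_dots_per_cell  sem_dots_per_cell  pooled_dots_per_cell
  control         5           0                0.16           0.040000                  0.16
  tfam_kd         5           0                2.40           0.296648                  2.40
   gba_kd         5           0                0.92           0.185472                  0.92
control vs tfam_kd: t = -7.483, p = 7.038e-05, df = 8
control vs gba_kd: t = -4.006, p = 0.003919, df = 8
```

Reading: the estimated factors sit a few percent above the true bleed
(the quantile estimator is deliberately conservative so control residuals
stay non-positive); control fields contain almost no ectopic puncta
(0.16 dots/cell), the TFAM-knockdown phenotype has ~2.4 dots/cell, the mixed
GBA-knockdown phenotype ~0.9 — its histone-positive nuclear-origin dots were
detected but excluded from the count.  Both knockdowns differ from control
at p < 0.005 despite only five fields per group.

The same steps are available as library calls (`estimate_factors`,
`subtract`, `detect`, `summarize`, `compare_groups`) on `ChannelStack`
objects from `read_stack` or `render`.

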