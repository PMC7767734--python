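# epicyto — automated whole-tissue histocytometry of the epidermis

`epicyto` quantifies single cells in sections of human epidermis (or
organotypic skin equivalents) the way a flow cytometer would — except the
"events" stay in place. From just two label-free-compatible channels, a
nuclear stain and a transmitted-light brightfield image, it

1. detects nuclei and builds a connected **nuclei map**,
2. thresholds the optically dense **brightfield area**,
3. predicts the **epidermis** by growing the nuclei map over the
   brightfield area,
4. partitions the epidermis into **basal**, **low suprabasal**, **high
   suprabasal** and **stratum corneum** strata using nuclei density and
   distance from the basement membrane,
5. grows competitive **single-cell measurement masks** from the nuclear
   seeds (maximal radius 10 µm, confined to the nucleated strata), and
6. measures every cell in every channel: nuclear and cytoplasmic means of
   immunofluorescence markers (K10, K14, γH2AX, cell tracker) and the
   formazan **optical density** of G6PD enzyme-histochemistry staining,
   computed as the cytoplasmic mean of the inverted brightfield,
   OD = I_max − I, anchored at the modal background intensity I_max.

On top of the per-cell table sit marker gating (absolute / Otsu /
background + k·σ), per-stratum distributions and 95 % density contours,
reaction-time-course fits for the enzymatic assay (with DHEA
inhibitor-baseline subtraction), and the statistical layer used in UV- and
drug-response experiments: unpaired two-tailed Student's *t*, two-way
ANOVA with Bonferroni-corrected contrasts, and OLS regression of activity
on nuclear γH2AX with a 95 % confidence band.

Because donor tissue is not shippable, the package includes a
**synthetic-epidermis generator** (`epicyto.synthetic`) that draws
sections with full ground truth — a wavy basement membrane carrying a
tight row of basal nuclei, suprabasal rows of decreasing density, an
anucleate stratum corneum, a differentiation-dependent activity gradient
written into the brightfield channel as attenuation, per-stratum K10/K14
distributions, and optional UV, pre-labelling, parakeratosis and
treatment effects. Every stage of the pipeline is validated against it.

## Worked example

```python
from epicyto import (preset_params, generate_section, run_pipeline,
                     gate_cells, violin_summary, compare_groups)

params = preset_params("homeostatic", seed=42, width_px=1600)
image, truth = generate_section(params)          # 1600 µm of epidermis
result = run_pipeline(image)                     # nuclei -> strata -> cells
table = gate_cells(result.table, "k14", "otsu")  # flag K14+ cells

summary, _ = violin_summary(table, value="activity_od")
print(summary.round(2).to_string(index=False))

basal = table[table["stratum"] == "basal"]
print(f"K14-negative basal cells: {100 * (1 - basal['k14_pos'].mean()):.1f} %")

res = compare_groups(table[table["stratum"] != "high_suprabasal"], "stratum")
print(f"basal vs low suprabasal activity: t = {res.t:.1f}, "
      f"p = {res.p:.3g} {res.stars}")
```

prints

```
        stratum   mean   n  median     q1     q3
          basal  77.06 200   77.24  74.29  79.93
high_suprabasal 107.02 359  107.05 103.60 110.25
 low_suprabasal  91.12 168   91.01  88.23  94.02
K14-negative basal cells: 5.5 %
basal vs low suprabasal activity: t = -29.6, p = 2.58e-99 ****
```

The per-stratum mean optical densities recover the generated
differentiation gradient (activity rising toward the granular layer), the
suprabasal-vs-basal difference is highly significant, and the fraction of
basal cells without K14 — the melanocyte-like residents seeded at 6 % —
comes back within the 5–7 % range expected for human epidermis.

A command-line interface mirrors the library:
`epicyto simulate | segment-nuclei | strata | measure | kinetics | report`,
all accepting `--config` (YAML) for the analysis parameters.

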