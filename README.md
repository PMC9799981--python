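# ireskit

Quantitative analysis of IRES-dependent translation experiments in stressed
cells — the assay suite used to study how the lncRNA *Neat1* and the
paraspeckle (a stress-induced nuclear body scaffolded by *Neat1* with the
DBHS proteins p54^nrb^/NONO, SFPQ and PSPC1) regulate cap-independent
translation of (lymph)angiogenic and cardioprotective factor mRNAs in
hypoxic cardiomyocytes.

The package implements four analysis arms as a reusable, tested pipeline,
plus seeded synthetic-data generators with known ground truth so every stage
is verifiable without any external download:

| arm | input | core computation |
| --- | --- | --- |
| `ireskit.spots` | multi-channel FISH/smiFISH TIFFs | nucleus segmentation (Otsu + watershed), spot detection by local maxima of a negated Laplacian-of-Gaussian response, foci per cell, distance-based two-channel colocalization |
| `ireskit.enrichment` | label-free AP-MS intensity tables | unique-peptide summation → median normalization → per-run 5%-quantile imputation → log2 → technical averaging → pooled-variance Student t-test; enriched ⇔ \|log2FC\| > 1 and p < 0.05, plus PSM (> 4) and replicate (≥ 2 quantified pre-imputation) confidence filters; paraspeckle-component overlap |
| `ireskit.translatome` | Fluidigm-style qPCR Ct tables | 2^−ΔΔCT relative quantification against a reference gene (Gapdh) and a calibrator treatment; polysome recruitment as RQ_polysomal/RQ_total; signed fold change (−1/RQ when RQ < 1); per-class repression/induction summaries |
| `ireskit.reporter` | dual-luciferase plate readings | background subtraction from non-transduced wells, LucF/LucR per well (the bicistronic IRES-activity readout), technical → biological averaging, normalization to a reference group, exact Mann-Whitney comparisons |

## Worked example

Simulate a dual-luciferase plate whose true *FGF1* IRES activity doubles in
hypoxia (LucF/LucR 0.2 → 0.4, nine biological × three technical replicates,
10 % channel gain CV, additive background), then recover and test it:

```python
import ireskit as ik

readings, truth = ik.simulate_plate(ik.SimPlateConfig(seed=7))
acts = ik.ires_activity(ik.subtract_background(readings))
normed = ik.normalize_to_reference(acts[acts.construct == "FGF1"], "normoxia")
print(normed.groupby("condition")["normalized_ratio"].agg(["mean", "std"]).round(3))
cmp = ik.mann_whitney(
    normed.loc[normed.condition == "normoxia", "normalized_ratio"],
    normed.loc[normed.condition == "hypoxia", "normalized_ratio"],
    "normoxia", "hypoxia",
)
print(f"U = {cmp.u:.0f}, two-sided p = {cmp.p:.4g} ({cmp.method})")
```

```
            mean    std
condition
hypoxia    1.926  0.155
normoxia   1.000  0.075
U = 0, two-sided p = 4.114e-05 (exact)
```

The normalized normoxia mean is 1 by construction; the recovered hypoxia
activation (1.93×) estimates the configured 2× truth, and the exact
Mann-Whitney test at n = 9 per group rejects equality.

The packaged paraspeckle-component annotation gives the interactome overlap
directly:

```python
>>> ik.annotate_paraspeckle(ik.load_paraspeckle_table())
{'n_total': 40, 'n_present': 22, 'n_present_itaf': 6, 'mode': 'fixture'}
```

i.e. 22 of 40 listed paraspeckle components are present in the p54^nrb^
AP-MS interactome, 6 of them with a known ITAF function.

## Command line

```sh
ireskit simulate all --seed 7 --out sim/       # synthetic inputs + ground truth
ireskit spots detect sim/images/*.tif --channel Cy3 --sigma 1.5
ireskit spots coloc sim/images/*.tif --max-dist 0.3
ireskit enrich --proteins sim/lfq/proteins.csv --annotation sim/lfq/annotation.csv --psm sim/lfq/psm.csv
ireskit translatome --ct sim/ct/ct.csv --reference Gapdh --calibrator control
ireskit reporter --plate sim/plate/plate.csv --normalize-to normoxia
ireskit demo --seed 7 --out demo/              # everything end to end
```

Every run writes a `provenance.json` (package version, seed, parameters)
beside its outputs. Simulator parameters can also come from a flat YAML
config with one block per generator (`images`, `lfq`, `ct`, `plate`);
unknown keys are rejected.

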