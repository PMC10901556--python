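# p53evo

Evolutionary and biophysical analysis of the motif-mediated p53TAD/MDM2
interaction in ray-finned fishes — and a general toolkit for the two kinds
of inference that study design requires:

1. **Ancestral sequence reconstruction** of a short binding motif on a
   time-calibrated species tree that must be surgically edited first:
   non-target species pruned, missing species grafted at known divergence
   ages, and the teleost clade *duplicated* at the whole-genome-duplication
   age (303 My) so each species contributes one tip per p53 paralog
   (`_P1`/`_P2`).  Reconstruction uses Felsenstein pruning under
   JTT(+G+I+F) with discretised-gamma rate categories, marginal posteriors
   at every internal node, and ML / AltAll ancestral calls (AltAll swaps in
   the runner-up residue wherever the top posterior is < 0.90 and the
   runner-up is ≥ 0.10).  Substitution models are ranked by AICc with
   Akaike weights.
2. **Binding-affinity inference** from fluorescence-polarization (FP)
   titrations and ITC: exact 1:1 and ternary competition equilibria (no
   trace approximations), probe calibration from saturation curves,
   competitor K_D either via IC50 + exact free-species conversion or by
   direct fit of the ternary model, and single-site Wiseman isotherm fits
   for ITC (n, K_a, ΔH, ΔG = −RT ln K_a, ΔS).

The package also ships the measured affinity table for the human reference
interaction and 12 extant fish p53TAD/MDM2 pairs (canonical motif
peptide, cross-species, and full-length constructs, K_D in μM) together
with the analytics over it — fold changes, affinity-band counts, and
motif-vs-full-length correlation — plus seeded synthetic-data generators
(sequence evolution along a chronogram, FP curves, ITC isotherms) so every
stage is testable offline with recorded ground truth.

The scientific headline these analytics capture: extant fish motifs bind
their MDM2 relatively weakly (mostly K_D 0.6–4.5 μM), but in 11 of the 12
interactions the disordered flanking regions of full-length p53TAD tighten
binding 4- to 73-fold, back to the ~100 nM range of the human complex —
affinity is conserved even where sequence is not.

## Worked example

Affinity-table analytics from the packaged measurements:

```bash
p53evo report table1
```

```json
{
  "human_fold_change": 4.262295081967213,
  "max_fold_change": 73.46938775510203,
  "max_fold_change_label": "D. rerio p53TAD_P2",
  "min_fish_fold_change": 0.8260869565217391,
  "motif_vs_fulllength_r2_linear": 0.12907148298766175,
  "motif_vs_fulllength_r2_log": 0.0015498380611648954,
  "n_fish_improved_fulllength": 11,
  "n_fish_motif_kd_in_0.6_4.5": 10,
  "n_fish_rows": 12,
  "n_rows": 13,
  "not_improved": ["A. anguilla p53TAD_P1"]
}
```

Reading: the zebrafish interaction gains the most from its flanking
regions (K_D 3.6 μM for the motif vs 0.049 μM full-length, a 73-fold
increase; the human gain is only ~4-fold); the one exception to
flank-driven improvement is the European eel paralog-1 interaction, whose
motif already binds tightly; and motif affinity barely predicts
full-length affinity (R² ≈ 0.13 linear, ≈ 0.002 on log K_D).

Simulate a competition FP experiment at the study design (15 nM probe,
1 μM protein, 2 mP noise) and refit it:

```bash
p53evo simulate fp --seed 3 --kd-probe 0.1 --kd-competitor 1.2 --noise-sd 2
p53evo bind fit-competition fp_titrations.csv --probe-kd 0.1
```

```json
{
  "experiment": "competition_1",
  "conversion": {"kd_uM": 1.0698887369800274, "ic50_uM": 12.620741246621776},
  "direct": {"kd_uM": 1.0861776918161414}
}
```

Both routes — four-parameter-logistic IC50 followed by the exact
free-species conversion, and a direct fit of the ternary equilibrium —
recover the generating K_D of 1.2 μM to within the noise (≈10% here), and
agree with each other to ~1.5%.

Reconstruction on your own data:

```bash
p53evo tree duplicate species.nwk --clade 125 --age 303 --out duplicated.nwk
p53evo asr run --alignment p53tad.fasta --tree duplicated.nwk \
    --model JTT+G+I --categories 5 --out run1
p53evo asr modelselect --alignment p53tad.fasta --tree duplicated.nwk
```

`run1/` then contains `posteriors.tsv` (per node × site × 20 residues),
`ancestral_ml.fasta` / `ancestral_altall.fasta`, and a deterministic
`manifest.json` of the effective configuration.

## Library use

Everything the CLI does is a thin wrapper over the library:

```python
from p53evo import (jtt_model, parse_newick, duplicate_clade,
                    marginal_posteriors, table1_fixture)
```

See `docs/methods.md` for the models, conventions and their rationale.

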