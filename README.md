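# gcrobust

Error-robustness analysis of genetic codes: does the standard genetic
code (SGC) conserve amino acid properties under mismatch and frameshift
errors better than random codes — and is its frameshift-robustness
anything more than a statistical byproduct of its mismatch-robustness?

`gcrobust` is for molecular-evolution researchers studying genetic code
optimality. It measures, for any amino acid property P, the weighted
mean squared difference

    MS = Σᵢⱼ wᵢⱼ (Pᵢ − Pⱼ)² / Σᵢⱼ wᵢⱼ

over ordered pairs of sense codons, where Pᵢ is the property value of
the amino acid codon *i* encodes and wᵢⱼ is the relative frequency with
which an error converts codon *i* into codon *j*. Lower MS = more
robust. Three error models are built in:

* **MS1** — uniform mismatch: every single-nucleotide codon change has
  equal weight;
* **MS2** — mistranslation: single-nucleotide changes weighted by
  per-position error rates E₁..E₃ and per-position transition/transversion
  rate ratios κ₁..κ₃ (loaded from config; the all-ones default collapses
  MS2 onto MS1);
* **MS3** — +1 frameshift: codon n₁n₂n₃ followed by n₄ becomes n₂n₃n₄.
  There are 61×4 − 3×4 = 232 frameshift events between sense codons, of
  which 121 are *mismatch-like* (the amino-acid change is also achievable
  by a single mismatch between codons of the two amino acids) and 111
  *mismatch-unlike*. −1 frameshifts provably give identical MS.

Significance comes from the classic permutation null: random genetic
codes (RGCs) keep the stop codons and the synonymous codon blocks of the
SGC fixed and shuffle only the 20 amino-acid labels (20! ≈ 2.4×10¹⁸
codes). The empirical P value is the fraction of sampled RGCs with MS
below the SGC's; per-property significance across many properties is
controlled with Benjamini–Hochberg FDR. Control analyses (MS-matched,
N-count band, and joint multi-property controls) then ask whether the
SGC's frameshift-robustness exceeds what its mismatch-robustness already
predicts.

## Worked example

The package ships one classic demo property, the polar requirement
(Woese's chromatographic polarity scale). Run the full analysis against
100,000 random codes:

```
gcrobust --quiet run-all --n-codes 100000 --seed 1 --out demo_run
cat demo_run/per_property.tsv   # excerpt below
```

| quantity | value | meaning |
|---|---|---|
| P_MS1 | 0.00012 | only 12 of 10⁵ RGCs beat the SGC's mismatch MS — the SGC is exceptionally mismatch-robust in polar requirement |
| P_MS3 | 0.00018 | the SGC is also frameshift-robust in this property |
| r(MS1,MS3) | 0.698 | mismatch- and frameshift-MS are strongly correlated across RGCs |
| r(MS1,MS3-like) / r(MS1,MS3-unlike) | 0.756 / 0.177 | the correlation is carried by the mismatch-like frameshift events |

and `demo_run/controls.tsv` holds the byproduct test:

```
test        parameters                              control_size  n_beyond  fraction
ms_control  control=MS1,property=polar_requirement  12            1         0.083
```

Among the 12 control RGCs at least as mismatch-robust as the SGC, 8.3%
have a smaller frameshift MS than the SGC — the SGC's
frameshift-robustness is unremarkable once its mismatch-robustness is
held fixed, i.e. it is explainable as a byproduct.

Other entry points: `gcrobust classify-frameshifts` (prints the
232 = 121 + 111 event split), `gcrobust fake-props` (null property
tables from U(−1,1) or N(0,1)), `gcrobust simulate` / `pvalues` /
`controls` / `correlate` for stage-by-stage runs on a stored ensemble.
A user-supplied property table (TSV with one row per property, or an
AAindex flat file) plugs in via `--properties`; see
`docs/methods.md` for formats and model details.

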