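# msbalipid

Native mass spectrometry resolves the discrete lipid-bound states of intact
membrane-protein complexes: a titration of the ~130 kDa MsbA homodimer with a
lipid such as the LPS precursor Kdo2-lipid A (KDL) yields, at each total
lipid concentration, the mole fractions of the apo, singly-, doubly-, ...
lipid-bound dimer. `msbalipid` turns those spectra into per-event equilibrium
dissociation constants and asks whether successive binding events cooperate.

The package covers the whole path:

- **`msbalipid.spectra`** — forward synthesis of charge-state spectra for the
  adduct-laden dimer (copper, ADP, vanadate, lipids), template-based
  zero-charge deconvolution by non-negative least squares, exhaustive adduct
  stoichiometry assignment, and conversion of species intensities to
  mole fractions (pooling metal/nucleotide states that share a lipid count).
- **`msbalipid.binding`** — the sequential binding model and its global fit.
  With macroscopic association constants K_An for PL(n−1) + L ⇌ PLn, the
  mole fraction of the n-lipid species is the Adair form

      F_PLn = [L]f^n ∏_{j≤n} K_Aj / (1 + Σ_i [L]f^i ∏_{j≤i} K_Aj)

  with the free lipid obtained self-consistently from the depletion balance
  [L]f = [L]tot − [P]tot Σ_i i·F_PLi. Fitting minimises the unweighted sum of
  squared mole-fraction residuals ("pseudo-χ²") over all points and species,
  in log10 K_A with a deterministic multi-start. Replicates are fitted
  independently and summarised as mean ± s.d. of K_Dn = 1/K_An; a pooled-fit
  mode exists. Cooperativity is profiled as step ratios K_D(n+1)/K_Dn, both
  raw and corrected for the identical-independent-sites statistical factor
  n/(N−n+1).
- **`msbalipid.synth`** — ground-truthed synthetic titrations and raw
  spectra (triplicates of a 0.3 µM dimer, 8-point schedule, multiplicative
  intensity or additive mole-fraction noise), so every stage is testable
  against a known answer.
- **`msbalipid.conservation`** — maps reference residue numbering (e.g.
  R188) to alignment columns by skipping reference gaps, computes per-column
  amino-acid frequencies and information content in bits (the sequence-logo
  matrix), and scans sequence sets for the N-terminal Met-His copper-binding
  motif.
- **`msbalipid.io` / `msbalipid.cli`** — tidy TSV/CSV and two-column
  spectrum formats with units in headers, a strict YAML/JSON config schema,
  and a `msbalipid` command with `simulate`, `deconvolve`, `fit`,
  `conserve`, and composite `run` subcommands.

## Worked example

```python
from msbalipid import (TruthRecord, generate_titration, fit_series,
                       aggregate_replicates, cooperativity_profile)

truth = TruthRecord(seed=42)   # K_D = (0.6, 1.2) uM, 0.3 uM dimer, sigma = 0.02
replicates = generate_titration(truth, n_replicates=3)
fits = [fit_series(series, n_max=2) for series in replicates]
summary = aggregate_replicates(fits)
print("K_D1 = %.3f +/- %.3f uM" % (summary.kd_mean[0], summary.kd_sd[0]))
print("K_D2 = %.3f +/- %.3f uM" % (summary.kd_mean[1], summary.kd_sd[1]))
coop = cooperativity_profile(summary)
print("raw K_D2/K_D1 ratio = %.2f" % coop["raw_ratio"][0])
print("corrected ratio     = %.2f  (%s)" % (coop["corrected_ratio"][0],
                                            coop["label"][0]))
```

prints

```
K_D1 = 0.594 +/- 0.031 uM
K_D2 = 1.224 +/- 0.073 uM
raw K_D2/K_D1 ratio = 2.06
corrected ratio     = 0.51  (positive cooperativity)
```

The fitted constants recover the generator's truth (0.6 and 1.2 µM) within
the replicate scatter. The raw ratio says the second lipid binds four-fold
more weakly per macroscopic constant, but for two identical independent
sites that ratio would be 4 purely combinatorially; after dividing out the
statistical factor the corrected ratio of 0.5 shows the second event is
intrinsically *tighter* — positive cooperativity.

The same analysis runs from the shell:

```bash
msbalipid run --seed 42 --out-dir results --stages simulate,deconvolve,fit
```

which synthesises raw spectra, deconvolves them back to mole fractions, fits
each replicate, and writes `fit_summary.json` plus per-fit residual tables.

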