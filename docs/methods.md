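# Methods

## The binding model

A homodimeric transporter P binds a lipid L in up to `n_max` sequential
steps, PL(n−1) + L ⇌ PLn, each with a macroscopic association constant
K_An = [PLn]/([PL(n−1)][L]) in µM⁻¹ (K_Dn = 1/K_An in µM). The mole
fraction of the species with n bound lipids at free lipid concentration
[L]f is the Adair partition-function form

    F_PLn = [L]f^n ∏_{j=1..n} K_Aj / (1 + Σ_{i=1..n} [L]f^i ∏_{j=1..i} K_Aj),

where the inner product runs to the summation index i — the only reading
that is dimensionally consistent and sums to one. Evaluation is in the log
domain (a log-sum-exp over the cumulative log K_A), so products as large as
(K_A·[L]f)^6 ≈ 1e36 neither overflow nor lose normalization; the output sum
is within 1e-12 of one over the whole tested sweep K_A ∈ [1e-3, 1e3] µM⁻¹,
[L]f ∈ [0, 1e3] µM.

Because the protein sits at concentrations comparable to its K_Ds
(0.3–0.4 µM), bound lipid depletes the free pool. The free concentration
solves

    [L]f = [L]tot − [P]tot Σ_{i=0..n} i · F_PLi([L]f).

The left-minus-right residual is strictly increasing in [L]f and brackets a
sign change on [0, [L]tot], so Brent's method converges unconditionally;
the absolute tolerance is 1e-12 µM and the solution is verified to satisfy
the balance to 1e-10 relative. For a single site this reduces to the usual
quadratic, which the tests use as a closed-form oracle.

### Assumptions

- Stepwise equilibria with a single macroscopic constant per event; no
  distinction between binding sites beyond their order of filling.
- Peak intensity is proportional to solution abundance (equal ionisation
  and transmission across lipid-bound states) — the standard premise of
  native-MS titration quantification.
- Concentrations are final post-mix values; any dilution at the spray stage
  (e.g. a 1:1 mix with detergent buffer) is the caller's responsibility.

## Fitting

The objective is the unweighted "pseudo-χ²": the sum over titration points
and over all species, apo included, of (F_obs − F_calc)². Including the apo
species alongside the sum-to-one constraint merely reweights the objective
uniformly; it does not move the minimiser. Observed vectors shorter than
n_max+1 are padded with zeros (species never observed).

Optimisation is over log10 K_A, which enforces positivity, with box bounds
corresponding to K_D ∈ [1e-3, 1e4] µM — generously wider than any affinity
measurable at a 0.3 µM protein concentration. A deterministic coarse
enumeration (5 values per dimension spanning the bounds) ranks starting
points; the best three seed an L-BFGS-B polish, and ties between optima are
broken toward the smallest K_D1. No random numbers are used anywhere in
fitting, so identical inputs give bit-identical results. `n_max` defaults
to the largest bound-lipid count whose mole fraction exceeds 1% at any
point. Fits whose parameters finish within 1e-3 log units of a bound are
flagged `boundary`; data with no bound species at all short-circuit to a
flagged result with K_D at the upper bound rather than a silent failure.

Replicates are fitted independently and summarised as the arithmetic mean
and sample standard deviation (ddof = 1) of each K_Dn, matching how
triplicate native-MS titrations are conventionally reported; a pooled fit
over concatenated residuals is available but not the default, since the
replicate scatter of the K_Ds is itself the quantity of interest.

### Cooperativity

For N identical independent sites the macroscopic constants follow
K_Dn = K_intrinsic · n/(N−n+1), so even non-interacting sites show rising
macroscopic K_Ds. The profile therefore reports both the raw step ratio
K_D(n+1)/K_Dn and a corrected ratio computed after dividing each K_Dn by
its statistical factor; a corrected ratio below one is labelled positive
cooperativity. The corrected statistic is a derived extension (the raw
K_D sequence is the direct experimental readout) and is labelled as such in
the output.

## Spectral layer

Spectra are modelled with average (not isotope-resolved) masses and
Gaussian peaks — appropriate for a 130 kDa complex on instruments that do
not resolve isotopes at that mass. Each species of total mass M
contributes peaks at (M + z·1.00728)/z over integer charges, weighted by a
Gaussian charge envelope (default mean 29, width 2, placing the dimer near
4500 m/z). Default peak sigma is 1.5 Th and the default m/z grid step
0.4 Th. The copper adduct mass defaults to the observed shift of 65.0 Da
rather than elemental copper (63.546 Da, also provided): metal binding with
proton displacement makes the effective neutral shift ambiguous.
Vanadate defaults to the VO4 moiety mass, 114.94 Da; all adduct masses are
user-overridable.

Deconvolution is a template fit: each candidate composition is rendered
noiselessly on the observed grid and non-negative abundances are obtained
by NNLS. This is deliberately simple — it assumes the candidate species are
known, which holds for titrations of a characterised complex — and is not a
blind iterative charge deconvolution. A rank-deficient template matrix
(e.g. duplicate compositions) raises an error naming the colliding
candidates. Mole fractions by bound-lipid count are formed by summing
abundances over compositions sharing a lipid count (marginalising copper /
ADP / vanadate occupancy, which the intensity ratios cannot and need not
resolve for the binding question) and dividing by the grand total.

Stoichiometry assignment enumerates all adduct count combinations within
per-adduct maxima (one copper, ADP and vanadate per subunit by default) and
keeps the composition minimising the absolute mass error, if within
tolerance; the default tolerance is 0.4× the smallest inter-adduct mass
gap, which prevents a copper ladder from being mis-read as a lipid adduct.
Ties go to the fewest total adducts, then lexicographic order. Out-of-
tolerance masses stay unassigned rather than being forced.

## Synthetic data

The generator realises the binding model as the data-generating process,
which makes recovery tests self-checking but also means passing them shows
internal consistency, not correctness of the model for real spectra: real
data add detergent background, charge-state-dependent transmission, peak
shape drift, and possible deviations from the sequential model itself, none
of which are emulated.

Default design, chosen to mirror a realistic dimer titration: truth
K_D = (0.6, 1.2) µM; 0.3 µM dimer; triplicates; an 8-point schedule
consisting of a zero point plus geometric spacing from 0.05 µM to 4×K_D1
(geometric spacing keeps later binding events identifiable); noise sigma
0.02 added to mole fractions (tabular path) or multiplicative log-normal
sigma 0.05 plus a 0.2% additive baseline on intensities (spectral path).
The two noise entry points are deliberate: the tabular generator tests the
fitting stage alone, the spectral generator the deconvolution + fitting
chain. Noise that drives a fraction negative is clipped at zero and the
vector renormalised, with clip counts logged. Each replicate draws from an
independent child stream of one seeded root RNG, so datasets are exactly
reproducible and replicates independent.

Under these defaults the median relative error of the recovered K_D1 over
50 seeded triplicate datasets is about 2% (bounded at 15% in the acceptance
suite), the error falls monotonically as sigma drops through 0.05/0.02/
0.005, and the full raw-spectrum pathway recovers K_D1 within 20%.

## Conservation

Reference residue numbering is 1-based. A reference position p maps to the
alignment column holding the reference row's p-th non-gap character, the
inverse of degapping the alignment relative to the reference. Column
frequencies are normalised over the 20 standard residues; gaps and
ambiguous characters (X, B, Z, ...) are reported as separate fractions and
excluded from the entropy — the convention of common logo tools.
Information content is log2(20) − H in bits, with no small-sample
correction by default (a correction would shift the exact hand-checkable
values; it can be layered on by the caller). Matching is case-insensitive.
The lipid-contact position list is a parameter, not a constant, since the
relevant contact set depends on the structure used to define it. The motif
scan flags sequences beginning Met-His (extended motifs like MHK
supported): position 2 histidine is what allows the free alpha-amine plus
His side chain to chelate copper(II) at a mature N-terminus.

## Problem sizes and tolerances

Test and acceptance workloads use desk-scale sizes chosen for fast,
deterministic runs: 50-dataset recovery benchmarks, 10-instance optimizer
vs 50×50 grid comparisons, 20-case spectral round trips, and 100 fuzzed
alignments. Numerical tolerances are stated where they bind: 1e-12 on
normalization, 1e-10 on mass balance and the closed-form depletion check,
1e-6 relative on noiseless deconvolution round trips.

## Known limitations

- The sequential model fits macroscopic constants only; it cannot separate
  site identities or binding paths, and no competition between lipid
  classes is modelled.
- Template deconvolution requires the candidate species list; unknown
  adducts inflate the reported residual rather than being discovered.
- The apo-included χ² and the equal-weight treatment of all species assume
  comparable measurement error across species; no per-point variance
  weighting is implemented.
- K_D uncertainties come from replicate scatter, not from the fit
  covariance; with fewer than two usable replicates no s.d. is reported.
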