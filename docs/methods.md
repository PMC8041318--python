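# Methods

`folatekin` analyses the quantitative assays that characterize a
folate–peptide conjugate as a dual-mode inhibitor of human thymidylate
synthase (hTS) and as a folate-receptor-targeted payload: enzyme inhibition
kinetics, subcellular compartment quantification, biostability kinetics,
receptor binding competition and drug-combination synergy scoring.

## Inhibition mechanism model

hTS is a homodimer with an inactive conformation II and an active,
dUMP-bound conformation AA. A difunctional inhibitor i (peptide end +
folate end) participates in six fast dissociation equilibria (constants in
μM):

| # | equilibrium | constant | meaning |
|---|-------------|----------|---------|
| 1 | AA ⇌ II + d | K1 | dUMP-linked inactive/active coupling |
| 2 | II + i ⇌ IiI | K2 | peptide end at the monomer–monomer interface |
| 3 | AA + i ⇌ AAi | K3 | folate end in the dUMP-occupied monomer's pocket |
| 4 | AA + i ⇌ iAA | K4 | folate end in the other monomer's pocket |
| 5 | AA + s ⇌ AAs | K5 | productive mTHF binding (substrate half-saturation) |
| 6 | iAA + s ⇌ iAAs | K6 | non-productive ternary complex |

Only AAs turns over: v = Vmax·[AAs]/E_tot. Summing species gives

    v = Vmax·(s/K5) / (1 + K1/d + i·(K1/(d·K2) + 1/K3 + 1/K4)
                        + s/K5 + i·s/(K4·K6)),

a linear mixed-inhibition form with Km_app = K5·(1 + K1/d),
Ki′ = K4·K6/K5 and exact slope constant
1/Ki = [K1/(d·K2) + 1/K3 + 1/K4]/(1 + K1/d).

**Naming note.** The productive substrate half-saturation ("Ks") and
equilibrium-5 constant are the same quantity here; the code carries one
field `K5` with an `Ks` alias. K5 and K6 are separately unidentifiable from
initial-rate data — only the ratio K4·K6/K5 (= Ki′) is constrained — so
simulation helpers accept apparent constants and construct a consistent
microscopic set (`MechanismParams.from_apparent`), exactly.

**Approximation note.** `infer_micro_constants` uses the composite
relations in their conventional d ≫ K1 form, Ki_app = d·K2/K1 (peptide) and
1/Ki_app = 1/K3 + 1/K4 + K1/(d·K2) (conjugate), dropping the (1 + K1/d)
prefactor — a ~6.7% approximation at the assays' d/K1 = 15. The rate law
and the species-balance oracle keep the exact form. Defaults: d = 140 μM,
d/K1 = 15, both overridable.

**Species-balance oracle.** An independent numerical check of the closed
form: `species_balance_oracle` solves the full mass balance (free enzyme
and free ligands; one ligand sequestered per complex and per binding event)
with Levenberg–Marquardt on log-transformed unknowns, accepting solutions
only when all relative conservation residuals are below 1e-10. It does not
assume tracer enzyme, so it also quantifies ligand-depletion effects that
the closed form ignores; in the tracer limit the two agree to better than
0.1% relative (property-tested over random parameter draws).

## Double-reciprocal analysis

Primary fits are unweighted ordinary least squares of 1/v on 1/s per
inhibitor level (≥3 substrate levels required; a 1/v⁴-weighted option
exists but is off by default, matching the classical least-squares-lines
treatment). Secondary fits regress the primary slopes and intercepts on
inhibitor concentration; the apparent constants are the intercept/slope
ratios of those lines, with delta-method standard errors using the full
coefficient covariance.

Mode call: mixed iff the intercept-vs-i slope differs from zero by a
two-sided t-test at α = 0.05 (the visual criterion made reproducible). Two
guards: (a) a fitted relative intercept change < 1e-9 over the inhibitor
range is numerical zero → competitive (noise-free data otherwise produces
0/0 t-statistics); the same guard on the slope replot yields "no inhibition
detected" instead of an exception. (b) With exactly two inhibitor levels
the secondary line is exact (no residual degrees of freedom); a >5%
relative intercept change substitutes for the test and the call is flagged
low-confidence. Non-positive rates are excluded with a warning rather than
failing the fit.

## Compartment quantification

Masses (ng) per fraction convert to molar concentrations via
C = (m/M)/V with the compartment volume V from the geometry: n_cells ×
2 pL/cell × 60% (cytosol) or 2.5% (vesicles). The vesicle/cytosol
concentration ratio (m_ves/m_cyt)·(f_cyt/f_ves) cancels the molar mass and
cell count exactly and is therefore the robust headline quantity (13.7 at
37 °C for the reference masses 34.4/60.2 ng). The reference dataset's
printed absolute concentrations imply a molar mass near 1356 Da, which is
inconsistent with the 1432.63 Da obtained from the [M+3H]³⁺ ion at m/z
478.5515 (e.g. 60.2 ng in 2.4 μL → 17.5 μM computed vs 18.5 μM printed);
the package computes from the charge-state-derived mass and documents, not
reconciles, the discrepancy. The default 3.0 mL external volume is
back-implied from the extracellular mass/concentration pair and flagged as
inferred.

Charge-state arithmetic uses M = z·(m/z − 1.00728) and its inverse; the
proton mass is configurable for average-mass work. The fluorometric
back-calculation divides the treated-minus-control signal difference by a
calibration factor (kcounts per μM); that factor is instrument-specific and
never published — `PAPER_CONSISTENT_CALIBRATION` (= 87/20.2 kcounts/μM) is
shipped only as a documented, back-derived fixture. Negative signal
differences are clamped to zero with a warning (blank variability).
The single-cell formula is C = C_sample·V_dilution/(n_cells·v_cytosol) with
v_cytosol = 1.2 pL (60% of 2 pL), consistent with the geometry defaults.

## Decay kinetics

First-order fits are log-linear OLS of ln C on t (k = −slope,
t½ = ln 2/k exactly); a nonlinear refinement is available behind a flag.
Replicates are pooled by default (the per-replicate mode exists because the
original protocol is ambiguous on pooling). Fitted |k|·Δt < 1e-12 is
treated as no decay (k = 0, infinite half-life). Simulated noise is
multiplicative log-normal with a first-order mean correction, so synthetic
concentrations are always positive.

## Binding competition

Default inference is the tracer-limit odds ratio: displacement f at equal
competitor dose gives c/Kd = f/(1−f), so K_a/K_b = odds(f_a)/odds(f_b);
80%/40% displacement gives exactly 6. The full two-ligand/one-receptor mass
balance (free receptor by Brent bracketing; monotone residual) is used when
receptor and tracer concentrations are supplied, because receptor depletion
lowers apparent displacement — a plausible reason a full treatment can
yield a smaller ratio ("near 5") than the tracer-limit 6. Free-energy
differences use ΔΔG° = R·T·ln(ratio) at a default 298.15 K (the temperature
that reproduces the conventional ~4 kJ/mol for a ratio of 5; the binding
assays themselves ran at 4 °C).

## Synergy analysis

SQ = combined inhibition / (sum of single-agent inhibitions); >1.1
synergism, [0.9, 1.1] additivity, <0.9 antagonism. The clustering transform
subtracts 10 below 0.9 and adds 10 at ≥1.1, which separates classes by
≥8.9 units in transformed space so class membership dominates Euclidean
distances. The classification band and the transform rule disagree at
exactly SQ = 1.1 (closed band vs ≥); both are honored as stated, side by
side. Row clustering is complete-linkage on Euclidean distances of
transformed values (untransformed behind a flag); the linkage is exported
as a scipy linkage matrix and as Newick.

## Synthetic data

`ScenarioConfig` states one simulated world: the 4 × 5 initial-rate grid
([i] = 0, 25, 50, 100 μM at d = 140 μM; mTHF levels 5–80 μM bracketing the
default Km_app = 20 μM — the inhibitor grid and dUMP level follow the
standard assay design, the substrate levels are a realistic choice since
they are not published), apparent truth Ki = 40 μM, Ki′ = 44 μM with 40% of
1/Ki carried by interface binding; the five-timepoint (20–240 min) decay
series with C0 = 18.5 μM and k = 3.5e-3 min⁻¹; the two-temperature fraction
mass table; an 80%/40% displacement pair; and an 18-record combination
panel spanning all three interaction classes. Noise defaults — 5% CV on
rates, 10% CV on decay, 5 percentage points (truncated to [0, 100]) on
inhibitions, masses and displacements exact — are bench-plausible stated
choices, not measured values. Truth sidecars are written as a separate
`truth.json` so fixtures can double as blind tests.

What a green synthetic test does establish: the estimators are unbiased and
exact on data generated by their own model, at stated noise. What it does
not: robustness to model misspecification (substrate depletion during the
assay, non-Gaussian detector noise, partial lysis cross-contamination of
fractions, metabolite interference), which real data would contain.

## Numerical choices

- Species balance: LM on log-concentrations, residual tolerance 1e-10
  relative, zero-total ligands removed from the unknown set exactly.
- K2 = ∞ and K6 = ∞ are accepted to express absent binding paths (their
  reciprocals enter the rate law; the limit is exact).
- OLS everywhere via statsmodels; clustering via scipy complete linkage;
  ties in linkage follow scipy's deterministic ordering, so output is
  reproducible for a fixed row order and topology is permutation-invariant.
- Seeds: every stochastic routine takes an integer seed or a Generator;
  scenario generation spawns independent child streams per table from one
  SeedSequence.

## Known limitations

- No global nonlinear fit of all six microscopic constants (underdetermined
  by fixed-[dUMP] initial-rate designs); no progress-curve kinetics.
- Apparent-Ki inference inherits the d ≫ K1 approximation noted above.
- The absolute fraction concentrations depend on a conjugate molar mass the
  reference data are internally inconsistent about; ratios are reliable,
  absolute μM values carry that systematic.
- Tracer-limit binding inference assumes no nonspecific binding and no
  receptor depletion; the full-balance route needs inputs (receptor and
  tracer levels) that are often unreported.
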