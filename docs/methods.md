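# Methods

## Scope and model

`cnslim` implements the computational side of characterising calcineurin
(CN) substrates such as the Na⁺/H⁺-exchanger-1 tail (NHE1ct, residues
I680–Q815): finding the docking and substrate short linear motifs (SLiMs)
in disordered sequence, relating their spacing to the geometry of the CN
surface, and fitting the three quantitative models used to measure such
systems — pseudo-first-order dephosphorylation kinetics, single-site
binding isotherms, and Michaelis–Menten saturation kinetics.

## Motif scanning

Patterns use a restricted PROSITE dialect: literal residues, bracketed
residue sets, and `x` wildcards, with optional `-` separators; `[S/T]` and
`[ST]` are synonyms. Repetition counts and terminal anchors are deliberately
unsupported — the motif definitions in this domain do not use them, and the
small dialect admits an exact independent oracle (a lookahead regex) in the
tests. Built-in definitions:

* `LxVP_CN` = `[NQDESRTH]-[YTDFILV]Lx[VPL]X`, anchor at the literal L.
* `STxxP` = `[ST]xxP`, anchor at the phosphoacceptor S/T.
* `PxIxIT` = `P-x-I-x-I-T`, anchor at the P. No canonical regex exists for
  this motif and real instances (e.g. NHE1's PVITID) deviate from it, so
  this entry is a convenience default that callers should override when
  they have a better definition.

Scanning reports **all** overlapping windows, ordered by start, in the
protein's own residue numbering (carried in FASTA headers as
`>id|start=NNN`). An unknown residue `X` in the sequence matches only
wildcard positions: the conservative choice, since letting `X` satisfy a
set position would invent matches.

## Disorder filtering

SLiMs are functional in intrinsically disordered regions (IDRs), so hits
are filtered against per-residue disorder scores (IUPred long-format TSV;
the predictor itself is consumed as data, never reimplemented). The default
threshold is 0.4 with the `all_residues` rule — every residue of the match
must reach the threshold — which is the strictest reading of "the SLiM is
in an IDR"; an `anchor_only` rule is available because the per-residue
convention is not standardised. Raising the threshold can only shrink the
surviving set, and `all_residues` survivors are always a subset of
`anchor_only` survivors; both invariants are property-tested.

The packaged toy scorer (sliding-window fraction of the disorder-promoting
residues A, R, G, Q, S, P, E, K; window 11) exists so tests and synthetic
data need no external predictor. It is NOT IUPred and its scores should
never be used for inference on real proteins.

## Pairing geometry and cohort statistics

A phosphosite is considered CN-accessible when its [S/T]xxP anchor lies
C-terminal to an LxVP match with at least 9 intervening residues — the
minimum needed to bridge the LxVP pocket to the active site. Separation is
measured from the last residue of the LxVP match to the [S/T]xxP anchor;
the reference point is configurable (the literature states distances "from
the LxVP site" without fixing one), and measuring from the motif's
C-terminal end matches the physical bridging argument. The distinct
`linker_length` operation counts residues strictly between two motifs
(27 between the NHE1 LxVP ending at 687 and the PxIxIT starting at 715).

Cohort summaries report the fraction of pairings with separations in the
closed windows [10, 35] and [10, 100], sites per protein, and the Ser/Thr
split of the anchors, under two countings: every qualifying pair
(`all_pairs`) and one pair per substrate site via its nearest LxVP
(`nearest_lxvp`), since published per-site distance distributions do not
always state which convention they use. Published cohort figures from
curated substrate databases are *not* reproduced here — they depend on an
external protein list and specific predictor versions — so the screen is
validated only against synthetic cohorts with planted truth.

## Dephosphorylation kinetics

Each peak is modelled as `A·exp(−k·t) + C` (decay) or `A·(1−exp(−k·t)) + C`
(rise); all peaks reporting on one site share a single `k`
(Levenberg–Marquardt via lmfit). Choices where the procedure is open:

* **Initialisation**: `k₀` from the slope of `ln(I − min I)` on each peak,
  median across peaks; fallback 1/t_max. `A₀` = intensity range, `C₀` = the
  approached baseline.
* **Offsets** `C` are fitted per peak by default (residual baseline
  intensity is typical); fixable to 0 via `fit_offsets=False`.
* **Bounds**: `k ≥ 0`. Rates are reported ×10⁻³ h⁻¹ with standard errors
  from the Jacobian-based covariance at the optimum.
* **Degenerate data**: all-constant intensities return `k = 0` with an
  infinite SE (the rate is unidentifiable beyond "no decay"); optimizer
  failure returns a flagged (`converged=False`) result, never an exception.

At 2 % Gaussian noise the median recovered rate over 200 replicates stays
within 5 % of truth for rates spanning 11–642 ×10⁻³ h⁻¹ on matched time
grids, and the fit-reported SE tracks the empirical spread within a factor
of two (tested).

## ITC single-site model

The forward model uses the constant-volume perfusion convention: injection
`i` of volume `vᵢ` into cell volume `V₀` dilutes current contents by
`1 − vᵢ/V₀` and adds titrant `vᵢ·[syringe]/V₀`; the bound concentration
comes from the exact single-site quadratic with `n` identical sites; the
differential heat is `dH·V₀·(Bᵢ − Bᵢ₋₁(1 − vᵢ/V₀))`, the dilution term
accounting for complex displaced into the overflow. Instrument-specific
baseline treatment and first-injection artefacts are out of scope (a
`exclude_first` flag covers the common practice). Default synthetic
schedule: 25 × 10 µL injections into a 1.4 mL cell, 5 µM macromolecule,
50 µM titrant, 298.15 K.

Fitting is least squares over (n, ln K_D, dH) — K_D on a log scale for
conditioning — with dG = R·T·ln K_D (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹) and
T·dS = dH − dG derived at the experiment temperature; these identities hold
to machine precision by construction. The Wiseman c-value `n·[cell]/K_D` is
reported and a warning logged outside [1, 1000]. The forward model is
cross-checked in the tests against an independent numerical equilibrium
solver (Brent root-finding on the free-titrant concentration) to < 10⁻⁹
relative.

## pNPP assay

Absorbance at 405 nm converts to product concentration by Beer–Lambert with
ε = 18,000 M⁻¹ cm⁻¹ and a 0.3 cm path (96-well plate); negative
blank-subtracted values clip to zero with a warning. Rates against a
0–8000 µM substrate grid are fitted to v = V_max·[S]/(K_m + [S]) with
k_cat = V_max/[E]_total.

## Synthetic data

Every pipeline input can be generated with planted ground truth and an
explicit seed (bit-reproducible; identical seeds give identical files):

* **Screen datasets**: uniform-background sequences with one planted LxVP
  and [S/T]xxP sites at separations drawn from a stated window, inside an
  IDR scoring 0.5–0.9 against a 0.0–0.2 background, so the 0.4 threshold is
  decisive; optional decoy [S/T]xxP instances in the ordered tail exercise
  the filter. Planted LxVP instances avoid S/T at loose positions and P at
  wildcards so they can never contain or complete an unplanned [S/T]xxP;
  any accidental motif arising from the random background is scrubbed by
  mutating a non-wildcard, non-planted position to G (which belongs to no
  position class, so scrubbing can only destroy matches). The truth table
  is therefore exact: the screen must recover precisely the planted sites.
* **Time courses**: one decay peak plus a complementary "reporting
  neighbor" rise peak per site, unit amplitude, Gaussian noise as a
  fraction of the initial amplitude; resistant sites are planted at k = 0.
  Default grid 13 points over 0–48 h.
* **Isotherms / saturation curves**: forward-model evaluation plus Gaussian
  noise on the default schedule / substrate grid above.

What the generators do **not** emulate: non-uniform residue composition,
evolutionary conservation, raw NMR lineshapes, thermogram power traces,
baseline drift, or pipetting-correlated ITC errors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to every artefact of real measurements.

## Problem sizes

Default test and acceptance runs use 10–25-injection isotherms, 13-point
time courses, 100–200 replicate noise studies, and cohorts of ~10 synthetic
proteins — sizes chosen to make every stochastic check statistically
meaningful while the whole suite completes in seconds.

## Known limitations

* The PxIxIT default pattern is a stand-in (see above).
* Only the ≥ 0.4 single-predictor disorder criterion is implemented; no
  consensus over multiple predictors.
* The ITC model covers a single class of independent sites; competitive or
  two-site schemes are out of scope.
* The kinetics model is pseudo-first-order by design and does not treat
  enzyme saturation within the NMR reaction.
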