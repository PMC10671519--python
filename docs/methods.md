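# Methods

## Model

Residues along an alginate chain are modelled as independent draws with
P(M) = μ/(1+μ), P(G) = 1/(1+μ), where μ = M/G is the sample's monomer
ratio (1.56 for the bundled study material, handled internally as the
exact rational 39/25). A junction-zone cell is an ordered pair of
two-residue blocks, one per chain, the two chains independent. The cell
symmetry group has four elements: identity, chain swap, simultaneous
reversal of both blocks (reading the cell from its other end), and their
composition. Its orbits partition the 16 ordered configurations into seven
classes with multiplicities (1, 4, 2, 2, 2, 4, 1); this is why GM–GM
(parallel mixed blocks) folds with MG–MG but stays distinct from GM–MG
(antiparallel). Class probabilities are m·μ^d/(1+μ)⁴ with d the number of
M residues. A cation's theoretical occupancy X_T is the summed probability
of its preference set; the shipped registry encodes the literature-derived
sets (Ba/Zn: GG/MM-block cells; Sr: GG and GM cells, flagged tentative;
Ca and the in-cell Ni complexes: GG-containing cells; plus the GG–GG-only
set whose probability, ≈2.3% at μ = 1.56, measures the density of
dimer-nucleating "zipper" cells). The i.i.d. assumption is what makes the
closed forms exact; real alginates have blockier sequences, which the
Monte Carlo simulator can emulate (below) but the closed forms deliberately
do not.

Everything in `combinatorics` is computed in exact `fractions.Fraction`
arithmetic whenever μ is rational, so normalisation and the
oracle-equality test are exact identities, not float comparisons.

## Composition pipeline

EDX atomic percents are validated (IUPAC symbols, positive values, total
in [95, 105] to tolerate instrument-side trace dropping and rounding) and
filtered at a trace cutoff of 0.10 raw at% — the smallest cutoff that
separates sputtering/background traces (Al, Si, and post-wash residual Cl)
from meaningful residuals such as Na, whose 0.12 at% in the Mn sample must
survive even though its C12 coefficient rounds to 0.03. Values are never
renormalised after filtering: the rescaling consumes ratios only, for
which renormalisation is a no-op. Rescaling multiplies a row by 12/K_C
(K_C = carbon at%), pins C to exactly 12, and imputes H as 14 per block
(flagged, and suppressible). Oxygen is reported as measured, even below
the theoretical 12 — EDX reads light elements low and no correction model
is applied. Display rounding is half-up to 2 decimals; all internal
arithmetic is unrounded.

## Decomposition

Let Me be the metal coefficient, A the anion-unit coefficient (Cl count,
or S count for sulfates) and ν the anions per salt unit. The three
explicit policies are mass balances:

* **anion_driven** — associates = A/ν, structural X = Me − A/ν. Applies
  when every anion rides an adsorbed salt unit (Sr, Ca, Zn; degenerates to
  pure-structural when no anion survived washing: Ba, washed Sr).
* **full_occupancy** — X = 1, associates = Me − 1; the anion imbalance is
  reported as a residual, never absorbed (Mn: Cl exceeds 2×associates by
  0.33 per block). Associates above the geometric cap of 2 per block (one
  sheet face each side) are allowed but flagged, consistent with chain
  breaks enlarging the adsorbing surface.
* **complex_in_cell** — the integer excess of Me over 1 (snapped within
  tolerance, capped at 2) is adsorbed; the remaining anion sits in cells
  as cation–anion complexes; bare structural ions make up the difference
  (Ni: 2 adsorbed NiSO₄·4H₂O + 0.27 in-cell complexes + 0.72 plain ions
  from Me = 2.99; Cu: no adsorbed units, 0.96 in-cell complexes).

Metal conservation (structural + complexes + associates = Me) holds
exactly, pre-rounding, under every policy. The **auto** policy applies, in
order: no anion → anion_driven (pure structural); alginate oxygen below 8
per block with Me > 1 → full_occupancy (severe O deficit marks degraded,
oxygen-poor chains, and such samples also satisfy later rules for the
wrong reasons, so this test must come early); Me within 0.05 of an integer
≥ 1 → complex_in_cell; Me − A/ν in (0, 1] → anion_driven. This is the
smallest ordered rule set that classifies all eight bundled samples into
their published regimes, and the chosen rule is recorded in the result's
flags.

Oxygen is budgeted as alginate O = measured O − anion O − crystallisation
water, with the salt registry carrying the default hydration (NiSO₄ is
registered as the tetrahydrate; chlorides and ZnSO₄/CuSO₄ anhydrous). A
remaining surplus above 12 per block with in-cell complexes present is
converted to integer waters per complex against a reference alginate
oxygen of 11 (measured gels cluster near 11 because EDX under-reads O);
that is how the Cu gel's O = 23.05 yields CuSO₄·8H₂O in every cell.
Whether *in-cell* Ni complexes also carry hydration water is not
experimentally settled; `hydrated_in_cell=True` switches to that variant
(alginate O 10.6 instead of 11.67) without changing the metal split.

Tolerances: occupancy/snap tolerance 0.05 throughout (a measured X = 0.99
counts as a complete sheet); formula coefficients compare at ±0.01 because
the printed values are themselves rounded inconsistently at half-way cases
(1.545 appears as 1.54).

## Synthetic data

`SyntheticGelSpec` holds a complete ground truth (μ, salt, structural X,
associates, complex fraction, hydration, sodium residual, backbone oxygen)
from which `generate_edx_table` builds exact per-block element counts,
drops hydrogen (EDX blindness), converts to at% and applies per-element
multiplicative lognormal noise (mean-one parameterisation,
σ² = ln(1+CV²)) before renormalising to 100. Multiplicative noise is the
natural EDX error model — uncertainty scales with peak intensity. The
default CV of 0.02 is a placeholder for well-resolved peaks; the true
instrument error is not published. At CV = 0 the rescale→decompose
pipeline inverts the generator exactly (asserted to 1e-9); at CV = 0.02
the recovered occupancy is unbiased across replicates up to the O(CV²)
ratio-of-lognormals term (~10⁻³ here). What the generator does **not**
emulate: detector physics, ZAF matrix effects, element-dependent bias for
light elements, or spatial heterogeneity of real microspheres — passing
round-trip tests therefore validates the arithmetic of the pipeline, not
EDX accuracy.

`simulate_chain_cells` samples cells under the i.i.d. model or a
first-order "sticky" chain (each residue copies its predecessor with
probability `p_stay`, else draws fresh from the marginal). The sticky
parameterisation was chosen because it preserves the M/G marginal for
every `p_stay` and reduces to i.i.d. exactly at `p_stay = 0`, giving a
clean one-parameter handle on block correlation. Frequencies come with
binomial standard errors; at n = 10⁶ every class sits within 3 s.e. of the
closed form. Problem sizes in the shipped tests (10⁵–10⁶ cells, 200 noisy
replicates) were chosen as the smallest that make the 3-s.e. and
unbiasedness checks statistically meaningful. All randomness flows from
one integer seed through named substreams (`numpy` `SeedSequence` spawn
keys), so new operations never perturb existing seeded values.

## Known limitations

* The i.i.d. sequence model ignores the block statistics of real
  alginates; X_T values are exact for the model, approximate for material.
* Preference sets are literature summaries; Sr's (and the GM–MM member of
  Ba/Zn's) are marked tentative and should be treated as hypotheses.
* The decomposition is a stoichiometric balance, not a thermodynamic
  model: it says where atoms are, not why.
* Oxygen-based inferences (hydration, degradation flags) inherit EDX's
  poor light-element accuracy; they are reported with residuals rather
  than corrected.
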