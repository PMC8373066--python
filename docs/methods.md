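# Methods

## Ensemble model

A single-base bulge inside a mononucleotide tract of N identical bases is
modelled as an equilibrium ensemble of N degenerate conformations. Each
conformation is labelled by the bulged base and its two nearest neighbors
(`cTt`, `tTt`, …); conformations at either end of the tract see one flank
(terminal states), the N−2 interior positions all see the repeat base on
both sides (the triplet state). With per-state penalties gᵢ and
multiplicities mᵢ, the partition function is Z = Σ mᵢ·e^(−gᵢ/RT) and the
ensemble penalty ΔΔG° = −RT ln Z (R = 1.9872×10⁻³ kcal/(mol·K), T in
kelvin, all energies kcal/mol).

In practice the two terminal states are never resolved individually: the
measurable quantity is the two-slide composite ΔΔG°(f₅BBf₃) =
−RT ln(w_term1 + w_term2). The prediction for any N ≥ 3 is assembled from
that composite plus the triplet entry:

ΔΔG°(f₅Bᴺf₃) = −RT ln( e^(−g₂/RT) + (N−2)·e^(−g_t/RT) ).

`predict_ddg` evaluates this closed form; `predict_ddg_enumerated` evaluates
the explicit state sum and serves as the independent oracle (the two agree
to < 1e-9 kcal/mol over randomized parameters by construction of the
composite). Both use log-sum-exp so per-state energies anywhere in
±50 kcal/mol stay finite.

**Assumptions.** States interact only through shared normalization (no
cooperativity between bulge positions); one bulge per duplex; no competing
secondary structure (G-quadruplex and i-motif formation in long G/C tracts
are known deviations); parameters measured under the representative-NNN
convention transfer to other contexts with a context error of order
0.15 kcal/mol, which is reported as a caveat rather than modelled.

**Singularity length.** The smallest N with ΔΔG° ≤ 0 (ties count as
stable, making the criterion identical to Z ≥ 1). Closed form:
n\* = 2 if w₂ ≥ 1, else 2 + ⌈(1−w₂)/w_t⌉; an incremental scan over N is the
independent oracle and the two agree on 1000 random draws in the tests.
The temperature enters through both table entries; 37 °C is the default
wherever a temperature is not supplied.

**Family summaries.** For a given bulged base and length, the nine flank
combinations are summarised by the arithmetic mean of their nine ΔΔG°
predictions (mean of energies, not of Boltzmann factors — the summary is a
descriptive average, not an ensemble).

## Parameter tables

Three classes of table cover everything: 36 non-slide entries (`aTc`),
36 two-slide composites (`cTTc`), 4 triplet states (`tTt`). Files are CSV
(`motif,temperature_C,ddG_kcal_mol`, UTF-8, '.' decimal); temperatures are
Celsius in files and converted to kelvin internally. The canonical grid is
the 43 integer temperatures 25–67 °C. Queries interpolate linearly inside
the grid (exact at grid points; the measured grid is dense enough that the
choice of interpolant is immaterial) and extrapolate outside it with a
van't Hoff line ΔΔG°(T) = ΔΔH° − T·ΔΔS° least-squares-fitted to the
motif's grid values, always with an `ExtrapolationWarning` — extrapolation
beyond the measured range is a modelling statement, not a lookup.

## Synthetic tables

`synth_table` draws, per motif, ΔΔG°(37 °C) uniformly from a class range
and a temperature slope uniformly from −0.04 to +0.01 kcal/mol/°C, then
evaluates the exact van't Hoff line on the grid. Ranges: 1.0–3.5 kcal/mol
for non-/two-slide entries (the scale of measured single-bulge penalties)
and 1.0–6.0 for triplets (triplet penalties spread much wider across bases,
from strongly stabilizing-friendly G to large low-temperature A penalties).
Mostly-negative slopes mirror the observed relaxation of penalties with
temperature, strongest for purines. These fixtures reproduce scale and
qualitative structure only: they carry no sequence-specific correlations,
no purine/pyrimidine grouping, and no measurement noise, so passing tests
demonstrate the correctness of the machinery (parsing, assembly,
interpolation, ensemble algebra, inference), not agreement with any real
measured dataset. Measured tables load through the same CSV schema and
flow through identical code paths.

## TEEM forward and inverse problems

Forward: given K_CP and K_CX (association constants, 1/M) and totals
(defaults 20/30/40 nM for C/P/X(reference), 1 µM for X(bulge)), the coupled
equilibria C+P⇌CP, C+X⇌CX reduce to one monotone scalar equation in free C,
solved by Brent bracketing on [0, C₀] plus Newton polishing; all five
constraints hold to 1e-12 relative or the solver raises. The simulated
bulge probe gets K_ref·e^(−ΔΔG°/RT); K_ref defaults to 10¹² /M (a stable
~20 bp duplex) and is constant in temperature unless a callable is given —
the ΔΔG° inference is insensitive to this because the reference constant
cancels. Controls are simulated physically (positive: no protector;
negative: no probe); Gaussian noise is seeded and scales with the dynamic
range.

Inverse: f = (F_sample−F_neg)/(F_pos−F_neg) estimates [CX]/C₀; with free C
neglected the three mass balances close in closed form and K = [CX][P]/
([CP][X]) per assay, ΔΔG° = −RT ln(K_bulge/K_ref). Signals outside
(ε, 1−ε) with ε = 1e-3 are flagged as saturated/empty, never silently
clipped. Each temperature is inferred independently (no smoothing);
cooling and heating phases are reported separately plus their mean, and an
equilibration check flags temperatures where the phases disagree by more
than 0.02 in normalized signal. When the caller supplies K_CP, the
inference also reports a conservative (2× first-order) estimate of the
ΔΔG° error introduced by neglecting free C; in the round-trip tests the
actual residual is below 5×10⁻⁴ kcal/mol across −1…+4 kcal/mol and the
full 25–67 °C grid.

## Context analysis

Deviations are defined per (bulge, temperature) cell as the value minus the
across-context mean; per-context RMS over all cells is the primary
representativeness score and the maximum |deviation| the outlier guard.
Selection keeps the k_low lowest-RMS contexts and drops any that are also
among the k_high largest maximum deviations (defaults 3 and 3); ties break
lexicographically on the context label so the result is order-independent.
An all-excluded selection is returned empty for the caller to judge.

Triplet isolation uses the exact ensemble identity: per flank context,
w_t = e^(−g₃/RT) − e^(−g₂/RT) must be positive (otherwise the data are
inconsistent and the offending context is named); weights are averaged
across contexts at each temperature independently — mean of Boltzmann
weights, not of energies — and converted back with −RT ln(mean w_t).

Group contrasts use Welch's unequal-variance t with Welch–Satterthwaite
degrees of freedom, two-sided, no multiple-testing correction (single
comparisons per panel).

## Scanning and probe design

`find_runs` reports maximal homopolymer runs in BED-style 0-based
half-open coordinates; ambiguity codes break runs and never act as flanks,
and runs at sequence edges are reported but non-scorable. A +1 insertion at
a run of length L is the motif (f₅, B, f₃, L+1). Scanning is
strand-specific; `--revcomp` additionally emits the reverse-complement
motif (an A-run is a T-run on the other strand). Duplex ΔG° is assembled
from user-supplied nearest-neighbor stack and initiation terms plus the
bulge ΔΔG°; the hybridization yield solves the exact bimolecular quadratic
in its numerically stable form (2KA₀B₀ / (q + √(q²−4K²A₀B₀)),
q = K(A₀+B₀)+1).

## Problem sizes and numerical tolerances

Randomized cross-checks use 1000 draws (closed form vs enumeration,
n ≤ 50; singularity formula vs scan, n_max = 3000) and 40 seeded replicates
for noisy TEEM recovery; the sliding census covers n = 2–29 (1008 motifs).
Occupancies are validated to sum to 1 within 1e-12, oracle agreement to
1e-9 kcal/mol, equilibrium residuals to 1e-12 relative. The sliding census
convention starts at n = 2 (a bulge needs two degenerate states to slide);
either convention exceeds 1000 motifs below 30 repeats.

## Known limitations

- Predictions inherit the representative-context convention of the input
  tables; when the real NNN context differs, expect an additional error of
  roughly 0.15 kcal/mol that the model does not correct.
- No competing structures: long G/C tracts can form G-quadruplexes or
  i-motifs that the ensemble ignores.
- Mononucleotide repeats only; di-/tri-nucleotide sliding defects and
  multi-bulge or mismatch defects are out of scope.
- The TEEM inference reproduces the core exchange algebra but not
  instrument-level corrections (fluorophore temperature response, quantum
  yield), which belong to assay calibration rather than this model.
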