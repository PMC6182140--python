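# Methods

This note records the models, conventions and numerical choices behind each
analysis, what the synthetic generators do and do not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Coordinate handling and superposition

Trajectories are frames × atoms arrays in Å with PDB-style labels; residue
numbering is 1-based (PDB convention), frame indices 0-based. The canonical
interchange format is multi-model PDB; the reader enforces identical atom
count and ordering across models and names the offending model otherwise.
Alternate locations: blank or 'A' kept, others dropped with a warning. A
thin mdtraj-backed adapter reads binary trajectory/topology pairs into the
same container (nm→Å, ps→ns).

Global motion is removed by Kabsch superposition (SVD solution of the
orthogonal Procrustes problem, reflection branch corrected to det = +1).
The fit set defaults to the Cα atoms of all three clamp chains, equally
weighted, against frame 0; the transform computed on the clamp is applied
to all atoms so DNA motion relative to the clamp is preserved. Fits require
≥3 non-collinear points. Hydrogens receive no special treatment: they are
ordinary atoms that selections may exclude.

## Ring-plane PCA tracking

Chain centres are unweighted Cα centroids per chain per frame (rotation
robust; the centre definition is a configurable selection). The DNA centre
is the unweighted centroid of all atoms of the selected in-ring base pairs
of *both* strands; the selection defaults to explicit residue ranges
(17–21 on strand F paired with 20–24 on strand G for a 40-bp duplex) and an
automatic slab mode (|z| < 12 Å about the ring plane along component 3) is
available.

The PCA pools chain centres across all frames (3N points) so a single fixed
2D subspace describes the whole trajectory; the origin is the pooled grand
mean. Eigenvalues use the (N−1) covariance normalisation, so the sum of
squared in-plane projections of the pooled centres equals (λ₁+λ₂)(N−1) — an
identity the tests assert. Eigenvector signs are pinned deterministically:
component 1 makes the first chain's time-averaged centre project to
positive x, component 2 does the same for the second chain on y, and
component 3 = e₁ × e₂. For an exactly C3-symmetric ring λ₁ = λ₂, so the
in-plane eigenvector *orientation* is set by noise and is arbitrary up to a
rotation; only rotation-invariant quantities (radii, distances, angles
between projected vectors) are meaningful across runs, and the tests
compare only those. The drift summary reports the mean projected position
over the trailing 20% of frames (configurable) and the nearest
time-averaged chain position; a final radius below 1 nÅ is reported as
"centred" with no nearest chain.

## Contacts and switching kinetics

Contact criterion: Euclidean distance from a side-chain nitrogen to a DNA
phosphorus strictly below the cutoff (default 4.0 Å). The donor set is the
exhaustive side-chain nitrogen list for standard residues (Lys NZ; Arg
NE/NH1/NH2; His ND1/NE2; Asn ND2; Gln NE2; Trp NE1); backbone amides are
excluded. Distances are computed with a vectorised all-pairs matrix — at
desk scale this is exact and fast, and its output is defined (and tested)
against a brute-force double loop.

For switching, each residue gets at most one *exclusive* partner per frame:
the nearest contacting phosphate, ties broken by lower nucleotide number
then strand id. A switch event is a partner change between consecutive
frames with both partners defined; dwell is the time from entering the old
partner's run to the first frame of the new partner. Runs ending in a
contact-free frame are tabulated (censored) but emit no event, as does the
run still open at the last frame. Without per-frame times dwell falls back
to frame units with a warning. Classification: sub-ns if ≥2 events with
median dwell < 1 ns, static if no events, slow otherwise. Occupancies are
frame-order invariant; switching statistics are order-dependent by
construction — both properties are asserted.

## CSP titrations and Kd fitting

Δδ = √(ΔδH² + (α·ΔδN)²) with α = 0.2 by default and configurable — the
standard amide weighting; the package does not claim any one published
study used exactly this α. Missing values distinguish `absent_broadened`
(signal lost to intermediate exchange) from `unassigned`; only the former
drives the "intermediate" class, and only at points with ligand:receptor
ratio at or below the substoichiometric limit (default 1.0). The
significance threshold is mean + 2·SD over finite CSPs with the
*population* SD (the sample/population difference is negligible at typical
residue counts; the choice is exposed).

Dilution bookkeeping is exact mass balance: after cumulative stock volume
V_add, receptor = R₀V₀/(V₀+V_add) and ligand = C_stock·V_add/(V₀+V_add).
The saturation criterion compares consecutive points: saturated iff the
maximum per-residue Δδ is ≤ the noise level (inclusive, with a one-ulp
guard).

The Kd fit is a *global* trust-region least squares
(`scipy.optimize.least_squares`) of Δδ(residue, point) =
Δδmax(residue)·f(point; Kd) with one shared Kd across residues — the
statistically coherent reading of "one constant from many residues" —
rather than averaged per-residue fits. Initialisation: Kd = first-point
receptor concentration, Δδmax = last observed Δδ per residue; bounds
Kd > 0, Δδmax ≥ 0; relative tolerance 1e-8. The isotherm uses the
numerically stable quadratic root 2RL/(s + √(s²−4RL)). Degenerate input
(all Δδmax below 1e-12 ppm) is rejected as "no signal".

## Competitive equilibria

g(R) = R + Σ Lᵢ·R/(Kdᵢ+R) − R_tot is strictly increasing with g(0) < 0 and
g(R_tot) ≥ 0, so the root is bracketed; it is found with Brent's method
(a strictly better-converging choice on the same bracket than plain
bisection) and polished with three Newton steps, because for strong binders
(Kd ≪ L) the residual amplification g′(R) would otherwise turn a 1e-12
error in R into a visible mass-balance error. Mass conservation to 1e-9
relative is asserted over randomised 1–5-ligand systems spanning six orders
of magnitude in Kd. Receptor totals are binding-site (protomer)
concentrations: a trimeric clamp with one PIP pocket per subunit at 133 nM
trimer enters as 400 nM sites. This interpretation is flagged prominently
because occupancy percentages change threefold under the alternative. Each
system carries a single explicit unit tag; nothing converts silently.

For the two-ligand bypass-assay condition (40 nM polymerase / Kd 0.4 μM,
400 nM sites, 400 nM peptide / Kd 1.1 μM) the solve gives a polymerase
saturation of 42.7% and a peptide saturation of 21.3%; a pairwise
(one-ligand) depletion calculation for the peptide gives 22.1%. Published
mutually-exclusive estimates in this concentration regime quote integer
percentages whose exact convention (rounding, pairwise vs simultaneous) is
not recoverable; the package reports both conventions and treats the
simultaneous solve as primary.

## Synthetic generators

The trajectory generator emulates the *geometry* of a clamp–DNA complex,
not its physics: three rigid Cα-trace arcs (radius 35 Å, two z-layers at
±2 Å) in exact C3 symmetry about z, and a duplex phosphate trace with ideal
B-form rise (3.4 Å) and twist (36°/bp), 40 bp, strands F and G paired
j = n+1−i. The inter-strand phase offset defaults to 180° rather than the
~154° minor-groove value of real B-DNA: with only P atoms present, antipodal
pairs make the phosphate centroid of any contiguous segment fall exactly on
the helical axis, so the programmed drift *is* the ground-truth centre
offset. (A real all-atom centre is similarly near-axial; a P-only trace at
154° would sit ~1.4 Å off-axis and contaminate every truth record.) Per
frame the DNA is displaced by the drift schedule and tilted about an
in-plane axis; isotropic Gaussian noise (default study condition 0.3 Å) is
added to every atom; an optional global rigid tumble is applied last. Noise
and tumble use independent seeded streams so toggling the tumble leaves the
thermal noise realisation unchanged — the superposition-invariance tests
rely on this. Optional Lys NZ probe atoms on the inner wall give contact
fixtures a controllable true contact set. Not emulated: force-field
energetics, sequence-dependent DNA geometry, correlated motions, solvent.

The titration generator computes stock volumes so ligand *moles* hit the
requested ratios (default 8 points to 6.4-fold excess at 100 μM receptor,
9.52 mM stock, 400 μL start — cumulative dilution ≈ 6.3%, matching the
few-percent regime of a real stepwise titration), then produces shifts
δ = δ_free + f·Δδmax per residue with f from the depletion isotherm at the
true Kd (default 35 μM), splitting each residue's Δδmax between ¹H and ¹⁵N
at a random angle. Noise is Gaussian with σ_H = noise and σ_N = noise/α so
both dimensions contribute equally after weighting. Designated residues are
flagged `absent_broadened` past their disappearance ratio. Passing tests on
these data show the estimators are correct and well-conditioned under the
stated noise; they do not show robustness to peak overlap, assignment
errors, or non-1:1 stoichiometry.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen as the smallest that leave the
estimators' errors clearly resolvable: trajectories of 8–50 frames with
~170 atoms, titrations of 20 residues × 9 points, 20 random seeds for the
stochastic recovery studies. All randomness flows through seeded PCG64
generators; fixture files regenerate byte-identically for a given seed.

## Known limitations

- No helical-axis fitting: DNA "position" is a centroid, blind to tilt/roll
  decomposition (tilt enters only through the generator).
- The exclusive nearest-partner rule makes multivalent contacts (one Arg
  bridging two phosphates) invisible to the switching statistics, though
  they appear in the raw contact log.
- The CSP model assumes pure fast exchange for fitted residues; residues
  near coalescence bias Kd and are only caught if they actually disappear.
- The equilibrium model is strictly 1:1 per site with no cooperativity and
  no distribution over 0–3 occupied sites per ring.
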