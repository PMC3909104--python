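# Methods

`prionmc` models the prion hydrophobic-domain peptides 109–122 and 106–126
(human numbering; acetyl/amide-capped; wildtype and A117V) with an all-atom,
implicit-solvent, torsion-space Monte Carlo scheme, and implements the full
analysis stack used to characterize their folding and aggregation:
per-residue secondary-structure frequencies, RMSD clustering consolidated
into structural families, hydrogen-bond occupancy fold changes, and
oligomer/fibril detection in multi-chain runs.

## Chain model

Bond lengths, bond angles and the peptide torsion ω (fixed at 180°) are
covalent constants; the degrees of freedom are φ/ψ per residue plus a
conventional set of sidechain χ torsions (L:2, K:4, H:2, V:1, T:1, N:2;
A/G none). Backbone constants are Engh–Huber-style values (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°). Only the amide
hydrogen is explicit — it is required by the hydrogen-bond geometry — and
sidechains carry heavy atoms only. The Cβ branch torsion offset (−122.6°
relative to φ about the N–Cα axis) gives the L-configuration: the improper
dihedral N–C–Cα–Cβ evaluates to +122.8°, the canonical value for L-amino
acids. Chains are built from internal coordinates (NeRF); the
torsion→Cartesian→torsion round trip is the identity to 10⁻⁴ degrees, and
structures transform rigidly with their placement frame.

Caps are modelled as pseudo-residues: the acetyl group contributes a
C-terminal-like C=O acceptor before residue 1 and the C-terminal amide an
N–H donor pair after the last residue, so helical hydrogen bonding extends
to the termini as it does for blocked peptides.

## Interaction potential

The potential is a sum of four terms, `E = E_loc + E_ev + E_hb + E_sc`, in
kcal/mol. The functional forms are this package's concrete choices and all
constants live in `ForceFieldParams` (readable from a TOML `[forcefield]`
section):

- **Local backbone electrostatics** `E_loc = κ_loc Σ q_a q_b / r_ab` over
  atom pairs of *adjacent* backbone peptide units (partial charges ±0.42 on
  C′/O and ±0.20 on N/H). This encodes the intrinsic φ/ψ preference; it is
  the only term that survives in the one-torsion testbed used for the
  sampling oracle.
- **Excluded volume** `E_ev = κ_ev Σ [λ_ij(σ_i+σ_j)/r_ij]¹²`, shifted to
  zero at the 4.3 Å pair cutoff. Pairs separated by ≤2 covalent bonds have
  distances fixed by construction and are excluded outright (they would add
  a large conformation-independent constant); 3-bond pairs are softened by
  λ = 0.75. σ per element: C 1.75, N 1.53, O 1.42, H 0.75 Å. The small
  amide-hydrogen radius keeps excluded volume from punishing proper
  N–H···O=C geometry (H···O ≈ 2.0–2.2 Å).
- **Hydrogen bonding** `E_hb = ε_hb Σ (5x¹² − 6x¹⁰) cos²α cos²β`, with
  x = σ_hb/r over backbone N–H···O=C pairs (σ_hb = 2.0 Å, minimum −ε_hb at
  r = σ_hb), α the deviation of N–H···O from linearity and β the deviation
  of N···O=C from linearity; the term gates off at α or β ≥ 90° or
  r > 4.5 Å. Intra-chain pairs closer than two residues apart are excluded;
  inter-chain pairs all qualify.
- **Sidechain contacts** `E_sc = −Σ M_IJ C_IJ` with C_IJ the fraction of
  sidechain heavy-atom pairs within 4.5 Å, over aliphatic groups
  (L, V, A-methyl, T-methyl; M = 0.8 attraction), lysine ammonium pairs
  (M = −0.5, repulsive) and the His ring (weakly attracted to aliphatics).

Default scales (κ_loc 25, κ_ev 0.10, ε_hb 3.0) were calibrated once so that
the ideal α-helix of 109–122 is the lowest-energy conformer among
helix/hairpin/coil fixtures — the ground-state ordering the monomer study
requires — while leaving the 277–333 K ladder workable for tempering. At
this well depth the backbone conformational entropy (roughly 2 kcal/mol per
residue at 277 K for the φ/ψ pair) outweighs the per-residue hydrogen-bond
gain, so the helix–coil midpoint of the free-energy balance sits *below*
the coldest rung: equilibrium ensembles are coil-dominated across the whole
ladder, and tempering mixes well. A deeper well, ε_hb = 4.5, moves the
midpoint inside the ladder (the helix then persists at 277 K and melts by
333 K); this *stability-probe* parameter set is what the qualitative
helix-vs-temperature scan uses (below), at the cost of slower tempering
equilibration. Both are exposed through `ForceFieldParams`; the
energy→temperature mapping is a single configurable scale (default:
nominal Kelvin).

Move-local energy differences recompute only pair terms involving moved
atoms (per-torsion dependency masks precomputed on the topology); agreement
with full recomputation is tested to 10⁻⁶ relative over hundreds of moves.
Periodic systems apply the minimum-image convention to inter-chain pairs
only; chains are never wrapped internally.

## Monte Carlo engine

One cycle = ν elementary Metropolis steps, ν equal to the number of degrees
of freedom (torsions, plus 6 rigid-body degrees per chain in multi-chain
systems). Moves: (1) single-torsion pivot (uniform resample or Gaussian
step, width growing with temperature), (2) semi-local update of up to 4
consecutive backbone torsions (Gaussian, σ = 8°), (3) sidechain χ resample,
and for multi-chain systems (4) rigid-body translation (Gaussian, σ = 1 Å)
plus rotation (uniform ≤ 30°), wrapped into the box. All proposals are
symmetric, so Metropolis acceptance min{1, e^(−βΔE)} preserves detailed
balance; the one-torsion marginal matches numerical quadrature to a total
variation distance well under 0.05 at 10⁶ steps. The move mix shifts toward
small-step moves at low temperature; mixes are configuration, not physics.

Monomer runs use simulated tempering on a geometric 8-rung ladder from 277
to 333 K — geometric, because the printed rungs (…284, 292…) match
equal-ratio, not equal-difference, spacing. Rung changes are attempted with
probability 0.1 per cycle, to a neighbouring rung only, with acceptance
min{1, exp[(β_cur−β_new)E + (g_new−g_cur)]}. Weights g_k are tuned by short
pilot runs iterating `g_k ← g_k − ln max(f_k, 10⁻³)` (recentred) until the
rung-occupancy ratio is ≤ 2; production runs refuse to start without tuned
weights. Multi-chain runs are fixed-temperature (293/303 K designs) in a
periodic cube; 20 chains in a 100 Å box is the production concentration
(33 mM), while the desk preset uses 6 chains in 60 Å.

Cycle counts at desk scale (10⁴–10⁵ monomer cycles, 10³–10⁴ multi-chain
cycles in tests and the reproduction script) keep every bookkeeping ratio
of the full design — snapshots per cycle, analysis stride 20, replicate
count 3 — while running in minutes; the full-scale counts (10⁸ cycles /
1000-cycle output; 2×10⁷ / 500) are preserved in the accounting helpers
and defaults.

## Measurement layer

Hydrogen bonds follow the geometric criterion H···O ≤ 2.4 Å with N–H···O
within 35° of linear. The distance is read as hydrogen-to-acceptor: 2.4 Å
is physically implausible for N···O and is the classic H···A cutoff; an
N···O switch is exposed in `HBondCriteria` for sensitivity checks.

Secondary structure is assigned from torsions with rectangular windows —
helix φ∈[−90,−30], ψ∈[−77,−17]; strand φ∈[−150,−90], ψ∈[90,150]; else coil.
The windows are this package's operationalization (the reference
assignment behind published frequency curves is not printed anywhere), so
frequency-versus-temperature comparisons are directional, not numeric.
Because both caps provide terminal reference atoms, all residues carry
defined φ/ψ and the maximum helix fraction is 1.

β-turns are typed by nearest-centroid matching of the two central residues'
(φ,ψ) against canonical type I/I′/II/II′/VIII centroids with a permissive
45° per-angle circular tolerance and an "irregular" fallback — permissive
because sampled turns deviate substantially from ideal angles; a 5-residue
window anchored by an i→i+4 bond is an α-turn.

Hairpins are detected from the bond register: intra-chain bonds pairing
residues i and j with |i−j| ≥ 3 nest around a loop with (nearly) constant
i+j. Groups of ≥ 2 bonds sharing a register (±1) whose innermost pair
encloses a loop of 2–5 residues are turns; the number of turns is the
hairpin order (single/double/triple). The same innermost-loop rule, run
backwards, infers the turn location implied by a single long-range bond for
the occupancy tables — odd |i−j| gives a 2-residue loop, even a 3-residue
loop, and bonds whose register cannot be nested by a second cross-strand
pair inside the chain report "n/a" (terminal bonds).

## Clustering and families

Ensembles are clustered on backbone heavy atoms (N, Cα, C, O — sidechains
excluded so the A117V variants share a selection) with greedy
neighbour-count clustering: the structure with the most neighbours within
the cutoff (2.5 Å for 14-mers, 3.5 Å for 21-mers) becomes a medoid, its
neighbourhood is removed, and the process repeats; ties break to the lowest
index, making the result deterministic. RMSD uses Kabsch superposition via
the covariance singular values with reflection correction, validated
against an independent superposition oracle to 10⁻⁴ Å.

Clusters are consolidated into families by explicit predicates evaluated on
each cluster representative, in precedence order: triple hairpin (21-mer
only), double hairpin, single hairpin binned by turn location (14-mer:
turns within 113–116 or 117–119; 21-mer: 112–117 or 118–120), helix (helix
fraction ≥ 0.5), coil. The original supercluster criteria are in
unavailable supplementary material; this predicate scheme is a documented
reconstruction parameterized by the turn-location bins printed with the
published family tables. Family percentages average over replicates
unweighted, and fold changes divide unrounded means (undefined, not
infinite, at zero wildtype percentage).

## Aggregation analysis

A pair of chains is linked when it simultaneously has ≥ 3 inter-chain
hydrogen bonds, both chains ≥ 50% strand by residue labels, and strand axes
parallel or antiparallel within 30°; oligomers are connected components of
links. The strand axis is the first-to-last Cα vector of the chain's
longest strand-labelled segment (whole chain as fallback). Each criterion is
independently falsifiable by a constructed fixture that violates only it.
Orientation counts report *chains* in parallel / antiparallel links (a
documented choice; the alternative reading counts links). Persistence
analysis decomposes each pair's inter-chain bond-count series into maximal
runs above a threshold (default 3 bonds; runs of ≥ 5 frames count as
persistent), annotated with per-frame hairpin status of both chains. Energy
landscapes bin (helix fraction, sheet fraction) on a 20×20 grid; minima are
occupied bins (≥ 10 members) below all occupied neighbours, and the saddle
between the two deepest minima is found by a union-find flood in order of
increasing bin energy.

## Synthetic ground truth

The generator produces exactly the objects the analyses measure, with known
labels: ideal helices (φ,ψ = −57°,−47°) and uniform-torsion coils with
Gaussian torsional noise; hairpins built in torsion space (strands at
−120°,130°, loops at the canonical turn centroid) and refined by a short
least-squares pass over the torsions around each loop so the nested
cross-strand bonds actually satisfy the 2.4 Å / 35° criterion — the loop
angles are tethered to their centroid so the turn type survives. Multi-loop
meanders are refined loop-by-loop in a cascade. The noiseless refined
conformation is cached as a template; noisy samples perturb the template
and re-polish. The default triple-hairpin turn locations are evenly spaced
(112–113, 117–118, 122–123) so every middle strand can carry the two nested
bonds the detector requires; more compressed layouts leave 2-residue middle
strands that cannot.

Sheet assemblies dock rigid extended chains at the canonical ~4.8 Å
cross-β spacing by maximizing a soft hydrogen-bond score over the six
rigid-body parameters from geometric initial guesses (Nelder–Mead,
multi-start), replicating the inter-chain transform as a screw operation;
antiparallel and parallel architectures and a low-sheet hairpin docked at
the sheet edge (emulating hairpin-capped fibril ends) are available.
Scripted trajectories stitch dispersed / transient-dimer / growing-sheet
stages into a time course with per-frame ground truth for oligomer counts
and persistence runs.

What the generator does *not* emulate: thermal ensembles (fixtures are
template + independent Gaussian torsional noise, with no correlated
backbone fluctuations), solvent effects, or physically equilibrated decoy
populations. Passing the recovery tests therefore demonstrates that the
measurement/clustering/table pipeline is correct on structures whose
composition is known — not that the simulated ensembles of any particular
force field are reproduced.

## Numerical choices

- Angles are wrapped to (−180°, 180°]; circular distances are used for turn
  classification and round-trip checks.
- The 3×3 symmetric eigensolver behind the RMSD kernel polishes the
  trigonometric closed form with two Newton steps on the characteristic
  polynomial (restores ~10⁻¹⁵ relative accuracy; self-RMSD < 10⁻⁶ Å).
- Atom pairs closer than 10⁻⁶ Å raise a "steric catastrophe" error rather
  than overflowing; the MC engine treats such proposals as rejected.
- Degenerate inputs: empty temperature rungs are reported missing rather
  than zero-filled; empty landscape bins are NaN-flagged; zero-wildtype
  occupancies flag the fold change undefined.
- Seeds: every stochastic routine takes an integer seed or Generator; runs
  are bit-for-bit reproducible per seed.

## Known limitations

- Force-field constants are calibrated defaults, not a reproduction of any
  published parameter set; energy axes are comparable only in shape and
  ordering, and the helix→coil midpoint of the desk-scale model need not
  sit at the physical temperature.
- Desk-scale runs (minutes) demonstrate mechanism and direction — helicity
  falling with temperature, antiparallel preference on association — but
  not converged ensemble percentages; those require production-scale
  sampling. In particular, desk-scale runs do not fold a random coil into a
  helix: the temperature-direction check is therefore a *melting scan* —
  fixed-temperature runs launched from the helical ground state at every
  rung temperature, under the stability-probe well depth, averaged after
  burn-in. It probes equilibrium stability, not folding kinetics.
- The supercluster reconstruction cannot be validated against the original
  (unpublished) criteria; family definitions follow the printed turn bins.
- The His protonation state and its contact strengths are configurable but
  unvalidated; none of the studied conclusions depend on them.
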