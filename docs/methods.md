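# Methods

This note documents the models implemented in `flexscore`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Shift route: the random coil index

Secondary shifts are Δδ = δ_obs − (δ_rc + neighbour corrections). The
packaged random-coil table (`data/random_coil_shifts.tsv`) holds standard
literature random-coil values for the 20 amino acids and the six backbone
nuclei N, H, CA, CB, C, HA; it is an editable TSV, and nearest-neighbour
corrections are supported but ship empty (off by default). Common
non-standard residues (MSE, SEP, TPO, …) map to a declared parent residue;
residues with no parent are undefined for the shift route but still enter
the structure route.

The per-residue statistic is the *unnormalised* weighted sum

    s_i = Σ_n w_n |Δδ_{i,n}|        (over the nuclei observed at residue i)
    RCI_i = min( 1 / max(s_i, floor), cap )

followed by a centred moving average (window 3) over the defined residues.
Defaults: weights CA = CB = C = HA = 1.0, N = H = 0.6 (carbon shifts are
the more reliable secondary-structure reporters), floor 0.5 ppm, cap
0.6 ppm⁻¹, minimum 2 observed nuclei per residue. The sum is deliberately
not divided by the number of observed nuclei: several large secondary
shifts are stronger evidence of structure than one, and the resulting
scale — ideal helix ≈ 1/(3.0+2.0+0.3) ≈ 0.19 ppm⁻¹, coil at the cap —
is the scale the structure route is calibrated onto. The price is a mild
bias towards flexibility at sparsely assigned residues, mitigated by the
2-nuclei minimum. Residues without sufficient shifts stay undefined and
are never interpolated; downstream comparisons use only residues defined
in both profiles, while rigidity is always computed on the full chain
(excluding residues would make their neighbours artificially floppy).

**Re-referencing.** A referencing error shifts every residue of one
nucleus by the same amount; genuine secondary structure shifts only the
structured residues, in correlated directions across nuclei. Estimating
the offset as the median over *all* residues therefore misreads a
helix-rich protein's +3 ppm CA shifts as a referencing error (verified on
synthetic helix-rich sets, where it inverts the scoring). The offset for
each nucleus is instead the median secondary shift over the most
coil-like quarter of residues (smallest mean |Δδ| across observed
nuclei), applied only when it exceeds 0.5 ppm (heavy atoms) or 0.1 ppm
(¹H). This is a no-op on correctly referenced data, recovers genuine
global offsets, and needs at least ~25 % of the chain to be disordered —
a documented limitation for fully structured proteins (a proper
re-referencing tool should be preferred there; `--no-rereference`
disables the step).

## Structure route: body-bar rigidity

The network follows the standard FIRST-style molecular mapping: heavy
atoms are 6-DOF bodies (hydrogens merged onto their heavy atom), single
covalent bonds 5 bars, peptide/double bonds 6 bars, hydrogen bonds 5
bars, hydrophobic tethers 2 bars. Covalent bonds are detected by distance
(heavy–heavy ≤ 1.9 Å), which reproduces the residue templates for
standard residues and degrades gracefully for non-standard ones. Two
deliberate conventions:

* **Terminal-atom rule.** A bond to a heavy atom with no other covalent
  neighbour is locked (6 bars): a lone atom spinning about its own bond
  axis is not a physical internal motion, but with atoms-as-bodies it
  would otherwise count as a floppy mode (carbonyl O, CB without modelled
  hydrogens, chain-terminal N).
* **Exclusions by bonded distance.** Hydrogen-bond and tether candidates
  separated by ≤ 3 covalent bonds are skipped (they would spuriously lock
  genuine dihedrals).

Hydrogen bonds use a Mayo-style 12–10 energy,
E = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·F with V₀ = 8 kcal/mol, d₀ = 2.8 Å, and a
cos²-based angular factor F = cos²θ·cos²(φ − φ₀) (θ = donor–H–acceptor,
gate at 90°; φ = H···acceptor–antecedent, φ₀ = 120° sp², 109.5° sp³).
The default energy cutoff is **−1.0 kcal/mol** (config-exposed and easy to
sweep): bonds weaker than roughly thermal energy cannot act as mechanical
constraints, and at a permissive cutoff the marginal i→i+3 helix contacts
(≈ −0.4 kcal/mol) make helices so redundant that the rigidity profile
stops responding to genuine hydrogen-bond loss. −1.0 kcal/mol is the
common choice in rigidity-dilution work and keeps an ideal helix fully
rigid. Hydrophobic tethers join C/S atoms of different residues within
vdW contact + 0.25 Å. Ligands (HETATM) are excluded by default
(`include_ligands` to keep them); salt bridges and metal-site constraints
(e.g. zinc fingers) are not modelled — structures organised around them
will read as too floppy.

**Pebble game.** The (6,6) pebble game inserts bars one at a time; a bar
is independent iff 7 pebbles can be gathered on its endpoints. Free
pebbles beyond the 6 trivial motions per connected component are the
internal floppy modes; failed insertions mark over-constrained regions;
pairwise 7-pebble queries along bars give the rigid-cluster partition
(mutual rigidity is transitive and clusters are bar-connected, so testing
bar endpoints suffices). Results are independent of insertion order; the
test suite checks the game against a brute-force generic rigidity-matrix
rank oracle (random generic bar placements, SVD rank at 1e-8 tolerance)
on 200 random graphs, exact agreement required. Within one connected
component floppy modes are monotone under bar addition/removal; note that
a bar *merging two components* legitimately raises the internal count (12
trivial motions become 6), which is why the monotone invariant is stated
at fixed connectivity.

**Flexibility index.** Per covalent bond: in a flexible region (connected
component of the cluster-contracted bar graph), floppy modes ÷ rotatable
bonds of the region; in an over-constrained region, −redundant
constraints ÷ bars of the region; 0 at isostatic rigidity. Per-residue
values average the residue's backbone bonds (N–CA, CA–C, C–N′). The raw
index in [−1, 1] is mapped to RCI units by x ↦ a·max(x, 0) + b with
defaults **b = 0.19** and **a = 0.41**: the rigid limit is aligned with
the RCI of ideal regular structure (≈ 0.19 ppm⁻¹, see above) and the
fully flexible limit with the RCI cap. Mapping rigid residues to 0
instead (b = 0) would paradoxically favour half-broken helices, whose
profile lands nearer the shift route's 0.19 plateau than a fully rigid
one; the calibration is config-exposed because the "true" rescaling is a
modelling choice, not physics.

## Scoring

Spearman's ρ (average ranks for ties; defined as 0 for a constant
profile) and RMSD are computed over the residues defined in both profiles
(≥ 5 required). Centiles against the reference use mid-rank tie handling;
the correlation score counts reference values below ρ, the RMSD score
counts reference values above the RMSD (lower is better); no
interpolation between reference values (centiles are step functions —
resolution is set by the reference size). The combined score is their
sum, [0, 200]. Ensemble aggregation: component-wise mean, or best model
(ties to the lowest model index). Multi-entry accessions average
per-entry scores first, then difference (two-level averaging).

The packaged reference (`data/reference_synthetic.tsv`) is the frozen
output of `synthdata.build_reference_distribution` — 60 synthetic
structures spanning sizes 28–52, H-bond retention 0.2–1.0, shift noise
0–0.4 ppm, with one fifth deliberately mismatched. Centile scores are
only meaningful within a stated reference, so its provenance is embedded
in the file and carried into every output; real-data work should supply a
reference built from real structures.

## Comparison pipeline

Filters (all inclusive): single chain; shift completeness ≥ 0.75 over the
mapped region (expected pairs exclude GLY CB and PRO H); ≥ 20 residues.
All three are always evaluated, so reason codes are order-independent.
The NMR side is scored on the full deposited chain per model; the
predicted side per mapped segment, extracted in reference (UniProt-style)
numbering and renumbered into the deposited frame. One flanking residue
on each side of a segment is kept as mechanical context so the cut ends
are not artificially floppy; scored residues are still those with shifts.
Secondary structure uses the Kabsch–Sander electrostatic criterion
(E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond below
−0.5) with helices from consecutive i→i+4 turns and strands from
(anti)parallel bridge patterns; protein classes use helix/strand fraction
cutoffs 0.15/0.05 (config-exposed; proteins matching no class are
excluded from the class breakdown). pLDDT is read per residue from the CA
B-factor; well-defined regions are *input* intervals (the package does
not re-derive them). The significance partition on the ensemble-mean
difference uses an inclusive ±50 threshold. Pearson's r between mean
pLDDT and the predicted side's score uses the t transform with n−2
degrees of freedom, two-tailed.

## Synthetic data

Backbones are built from internal coordinates (NeRF): helix φ/ψ =
−57°/−47° — which places i→i+4 amide–carbonyl pairs in hydrogen-bonding
geometry by construction — strand −120°/+120°, coil φ ∈ U(−130°, −60°),
ψ ∈ U(110°, 170°) (an extended, polyproline-II-like baseline chosen so
disordered segments rarely pack back against the core), resampled per
model with jitter 20°·`coil_dispersion` so coil regions are "ill-defined"
across an ensemble while structured regions superpose. Chains get
acetyl/N-methyl caps on the ideal backbone continuation so every scored
residue has both φ and ψ defined — without caps the terminal dihedrals of
even a perfect helix are genuinely floppy in any body-bar treatment. Caps
are excluded from sequence maps and profiles. Only N, CA, C, O, CB and
the amide H are built.

Shifts are random-coil value + canonical offsets (helix ΔCA +3.0, ΔC
+2.0, ΔHA −0.3; strand −1.5/−1.5/+0.3 ppm; generator constants, not
claims about real proteins) + Gaussian noise, thinned to an exact
completeness target. Hydrogen-bond degradation reflects a seeded fraction
of amide protons through their nitrogen, so the bonds fail the angular
gate while the chemistry stays valid. The default 10-pair study corpus
plants three strongly degraded NMR sides (retention ≈ 0.1; expected
difference ≥ +50), one degraded predicted side (≤ −50), three matched
controls, and one violation of each filter; predicted-side pLDDT tracks
the planted quality (structured-core level 55 + 40·retention). Planted
outcomes are stable across generator seeds (checked over 20 seeds).

What the generator does **not** emulate: side chains beyond CB (so
hydrophobic packing and side-chain H-bonds are absent), real coil shift
statistics, correlated assignment errors, ligands, salt bridges, or
physically relaxed geometry. Passing tests therefore demonstrate the
machinery's correctness and sensitivity under controlled conditions, not
performance on experimental data; absolute scores on real structures
additionally require a real reference distribution.

## Numerical choices and problem sizes

Pebble-game cluster queries reuse the end state of the game (pebble
rearrangements are basis-preserving). Flexible-region floppy modes are
computed by re-running the game on the induced subnetwork.
Over-constrained region shapes depend mildly on insertion order (their
redundancy totals and all scores do not). Degenerate inputs: constant
profiles give ρ = 0; empty shift sets re-reference to themselves;
disconnected networks are handled per component. Test and acceptance
workloads use 19–48-residue proteins, ensembles of 1–4 models, 10-pair
corpora, 50-seed recovery panels and 200 random oracle graphs — sizes at
which the full suite runs in about half a minute on one CPU.
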