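# Methods

This note documents the models and procedures implemented in `phstab`, the
parameters that matter, the design choices made where conventions differ,
and what the synthetic-data validation does and does not establish.

## Trajectory model and structural statistics (`structio`)

A trajectory is a fixed atom roster plus coordinate frames in Å at a
constant save interval (default 5 ps). Multi-model PDB is the interchange
format: every MODEL block must carry the same roster; crystallographic
waters and ions are ordinary atoms and survive round trips. Residue
numbering is 1-based per chain; the α/β chains of the penicillin-acylase
heterodimer map to PDB chains A and B, and the domain architecture is
expressed as named residue ranges (A1 α3–149, A2 α150–179, the
three-segment αββα core B1 β1–72 + β146–290 + β452–536, B2 β73–145,
B3 β291–451; 766 residues over both full chains).

Superposition is the least-squares rigid fit (proper rotation, via
`scipy.spatial.transform.Rotation.align_vectors`); the test suite checks it
against an independently implemented Kearsley quaternion oracle. RMSD
series superpose each frame onto the first production frame over a *fit*
selection and evaluate RMSD over a *measure* selection. Because the source
protocol does not state whether per-domain RMSD used a global or local fit,
both are provided: the default `fit=local` (fit = measure) isolates
internal deformation; `fit=global` or a named anchor domain preserves
rigid-body displacement of a domain relative to the rest. "Backbone" is
{N, CA, C, O} (carbonyl O included — the common convention; the narrower
{N, CA, C} set changes values by well under the replicate SD). RMSF of Cα
atoms is computed about the mean structure of a trailing window (default
2000 frames = 10 ns) after aligning the window to its first frame.

## Protonation (`protonate`)

Constant-protonation MD fixes each titratable group's state up front: a
group is protonated iff its pKa is **strictly** greater than the target pH
(equality → deprotonated). pKa values arrive as a plain-text table
(`chain resnum resname pKa`); a textbook model-pKa fallback (Asp 3.8,
Glu 4.2, His 6.0, Lys 10.5, Arg 12.5, Cys 8.3, Tyr 10.1, N-term 8.0,
C-term 3.5) covers quick screening. Manual overrides — per-pH or
pH-independent — take precedence and are logged; overriding a residue that
is not in the table is an error. Protons notionally attach to the standard
heavy atoms (OD/OE/NZ/NE/NE2-or-ND1/N/O); neutral His defaults to the NE2
tautomer, doubly protonated His (pKa > pH) adds ND1. Hydrogen geometry
construction is deliberately out of scope — the MD engine owns it.

## Hydrogen bonds (`hbond`)

Acceptance window: donor–acceptor distance ≤ 3.5 Å **and** D–H–A angle in
[145°, 180°], both boundaries inclusive. Donors are N/O/S heavy atoms with
a covalently attached hydrogen (H within 1.25 Å); acceptors are N/O/S;
waters act as both; intra-residue contacts are excluded. For hydrogen-free
crystal structures a heavy-atom fallback accepts on distance alone and
flags the output. A residue pair "has a bond" in a frame if any qualifying
atom triple exists; persistence is the fraction of window frames with a
bond, reported per run and pooled when replicates are given (the source
protocol's 90–98% range does not say which; both are available).
Residue-level networks are `networkx` graphs seeded on residues of
interest; bridging waters contribute all their bonds within one water hop,
so a buried water like the one linking the two β-sheets of the αββα core
appears with its full degree.

## Near-to-attack conformation (`nac`)

A frame is productive iff three distances are ≤ 3.5 Å (inclusive — "did
not exceed"): catalytic Ser Oγ (`OG`) to the substrate carbonyl carbon, and
the substrate carbonyl oxygen to the oxyanion-hole backbone N and side-chain
amide N (`ND2`). Substrate atom names vary by compound and are part of the
configuration. The NAC fraction is the percentage of productive frames in
the trailing window (default 1000 frames = 5 ns); replicates are
summarised as mean ± sample SD (n−1), the convention of the reported
tables. Whether a published SD is over replicate fractions or pooled
frames is generally ambiguous; replicate-level SD is the primary output.

## Trajectory comparison (`tscmp`)

The comparison protocol is: trim each RMSD series to the trailing
`expected_length` frames (default 2000 = 10 ns), smooth with a centered
10-frame moving average (edges truncated, length preserved; for even
windows the extra element is taken on the left), align with banded DTW,
then read off Δ_RMSD (mean of RMSD₂ − RMSD₁ over aligned element pairs)
and f (fraction of pairs with RMSD₁ ≥ RMSD₂, non-strict as printed).

DTW specifics, pinned for reproducibility: local cost |aᵢ − bⱼ|; unit-weight
steps {(1,0), (0,1), (1,1)}; fixed endpoints; Sakoe–Chiba band |i−j| ≤ w;
deterministic traceback preferring diagonal, then the step consuming the
first series. Window 0 means *no DTW* — the identity pairing, requiring
equal lengths. Averaging is over path elements (a warped frame that pairs
multiple times counts each time). The DP is exact; tests verify the
minimal cost against memoized-recursion and exhaustive path-enumeration
oracles on all instances up to 20 frames, and the inner loop is
numba-compiled when numba is available (a pure-Python fallback keeps the
package functional without it).

Replicate sets are compared over all ordered pairs (3×3 = 9), Δ_RMSD as
mean ± sample SD over pairs, f as the mean; f ≤ 0.05 is labelled
significant (configurable). Windows {0, 100, 250, 500, 750, 900, 1000}
are available for sensitivity checks; 500 is the reporting default.

## Subfamily-specific positions (`ssp`)

Pipeline: (1) discard sequences scoring < 0.25 bits/column against the
template (strict rule; ties retained) — the score is a BLOSUM62 global
alignment (gap 11/1) converted to bits with the standard ungapped
Karlin–Altschul constants (λ = 0.3176, K = 0.134) and divided by alignment
length; (2) single-linkage clustering at > 95% pairwise identity
(matches / columns where either row is non-gap), one representative per
cluster — first in input order, template always kept; order of the two
filters is configurable (bits first by default). (3) Score each column by
the mutual information between residue identity and subfamily label over
non-gap entries, in bits, with the Miller–Madow small-sample correction,
clamped to the information-theoretic range [0, min(H(residue), H(label))].
The clamp matters: the raw MM correction is *positive* for a clean
two-subfamily, two-residue column and would push the score past its
theoretical 1-bit maximum; clamping keeps the score exact in that case and
non-negative everywhere. Columns with > 50% gaps are skipped and flagged.
(4) Significance by permutation of subfamily labels across sequences
(seeded; ≥ 100 permutations, default 1000; p = (1 + #{null ≥ obs}) /
(1 + n)), ranking by descending score, and per-subfamily residue
frequencies reported as e.g. `N(50%) D(50%)` with template residue
numbering attached.

The published specificity statistic this stage emulates is defined in
external software; corrected MI is a documented, testable scoring rule
with the same qualitative behaviour. Published score values
(1.894/1.885/1.582) are *not* reproduction targets.

## Kinetics (`kinetics`)

Inactivation: A(t) = A₀·e^(−k_in·t), t in min, fitted by trust-region
least squares with analytic Jacobian, initial guesses from log-linear
regression, three scaled restarts, k_in bounded ≥ 0; SEs from the fit
covariance (the published errors are not identified as fit-SE vs
replicate-SD; fit SE is what is reported here, labelled as such).
Michaelis–Menten: v = k_cat·E₀·[S]/(K_M + [S]), [S] and K_M in µM, k_cat
in s⁻¹; initial guesses K_M = median([S]), V_max = max(v); a fitted K_M
far outside the sampled substrate range is flagged poorly constrained.
Catalytic efficiency k_cat/K_M is reported to two significant figures;
stabilization fold is k_in(reference)/k_in(variant).

## Synthetic data (`synth`) — what it emulates and what it does not

All generators are pure functions of (config, seed).

*Trajectories*: each domain is a spatially separated cluster of pseudo-Cα
atoms fluctuating i.i.d. Gaussian (σ, default 0.3 Å per coordinate, giving
a stationary backbone RMSD of ≈ 0.5 Å) about the frame-0 reference;
destabilized domains additionally translate coherently (default 0.1 Å/ns),
producing the ascending-RMSD signature with an analytically known RMSD
(rate × frame for a noise-free domain measured against a fixed anchor).
The two-model experiment (`gen_replicate_models`) generates 3 + 3
replicates of 4000 frames (20 ns at 5 ps) so that, as in a real unfolding
study, drift has accumulated before the trailing 10 ns analysis window
opens; the drifting domain then separates cleanly (f ≈ 0) while stable
domains overlap (f ≈ 0.5). Not emulated: force-field physics, solvent,
rotational drift, correlated internal motions — so passing tests show the
*statistics* behave correctly on their defining signal shapes, not that
any particular enzyme is (de)stabilized.

*Alignments*: a conserved background consensus with subfamily-distinct
residues planted in chosen columns, plus i.i.d. substitution noise
(default 10%); subfamily sizes default to (20, 10, 10, 4), mirroring the
small, unbalanced groups typical of curated superfamily subdivisions. No
gaps, no phylogenetic correlation — the permutation test's exchangeability
assumption holds exactly here, which is the point of the validation and
also its limit.

*Kinetics*: exact model curves plus Gaussian noise — absolute (fraction of
A₀) for decays, relative (fraction of each rate) for initial rates,
matching how error enters each assay type; negative draws truncate at 0.

*H-bond frames*: a minimal donor–H–acceptor triad toggled between a
conforming geometry (2.9 Å, 165°) and a stretched one (4.5 Å) in a
Bernoulli(p) subset of frames, giving persistence with a known target.

## Problem sizes

The validation studies use: 3 + 3 replicates × 4000 frames × 150
pseudo-atoms for the trajectory experiment; 100 random series pairs of
length ≤ 20 for the DTW oracle; 20 seeded alignments (44 sequences × 100
columns, 100 permutations) for SSP recovery; 100 seeds at 2% noise for
kinetics parameter recovery and 200 for SE calibration. These sizes give
stable pass/fail behaviour for the planted effects while the full suite
runs in a few minutes.

## Known limitations

- The DTW band requires |len(a) − len(b)| ≤ window; open-ended or
  multivariate alignment is out of scope.
- Heavy-atom H-bond detection overcounts (no angular filter by design);
  it is a screening mode for unprotonated crystal structures.
- The SSP stage takes subfamily labels as input; it does not infer
  subfamilies from tree topology, and its bits/column filter uses ungapped
  bit-conversion constants on a gapped alignment score (a documented
  approximation — the filter's semantics, a threshold on template
  similarity, are what is preserved).
- Protonation decisions are per-residue and static; tautomer placement
  beyond the His default and coupled titration are not modelled.
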