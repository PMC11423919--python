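# Methods

## Model and procedure

`fragmap` nominates minimal receptor-binding motifs from fragment-based
complex predictions. The underlying assumption is that a short bait
peptide which genuinely binds the receptor will, across the overlapping
windows that contain it, consistently produce predicted complexes with
many inter-chain contacts at high model confidence, while non-binding
windows produce few or low-confidence contacts. The method therefore
scores *predicted interface density*, not binding energetics.

### Tiling

The bait of length *L* is tiled into windows of `window` residues advanced
by `step` (defaults 50/25). Full windows start at 1, 1+step, …; when
`(L − window) mod step ≠ 0` the grid does not reach the C-terminus, and
under the default `anchor_tail` policy one extra full-length window is
anchored at `[L − window + 1, L]`. Tail windows are never truncated, so
every fragment has identical length and fragment scores remain comparable.
For L = 315 this yields 11 grid windows plus an anchored tail at 266–315.
`drop_tail` is available when an exact grid is wanted; trailing residues
are then uncovered and reported as missing in the profile. All coordinates
are 1-based inclusive internally; BED/bedGraph exports convert to 0-based
half-open at the boundary.

### Contact counting

A contact is a (bait residue, receptor residue) pair with any heavy-atom
distance ≤ `cutoff` (default 4.0 Å, inclusive — the boundary convention
must be fixed somewhere, and "within" is read inclusively). Hydrogens,
waters and non-amino-acid heteroatoms are excluded before counting, and
alternate locations are resolved to the highest-occupancy atom (ties to
the first encountered), so the count does not depend on protonation or
altloc bookkeeping. The default counting unit is the deduplicated residue
pair, the standard interface-contact convention, robust to side-chain
completeness; `atom_pair` counting is selectable where a weighting by
atomic contact multiplicity is wanted. The search uses a KD-tree over
receptor atoms but is exact: the test suite verifies integer equality
against an exhaustive all-pairs double loop on random structures.

### Confidence weighting and the residue profile

Each fragment's score is `S_f = C_f × P̄_f`, where `P̄_f` is the
unweighted mean pLDDT over *all* of the fragment's bait residues (not only
contacting ones): a fragment predicted with low overall confidence is
penalised even if a few contacts are confident. pLDDT is read from the
B-factor column (default from the CA atom; structure predictors write the
same per-residue value on every atom, so `atom_mean` differs only for
third-party files) and kept on its native 0–100 scale — no /100
normalisation, since only relative profile heights matter downstream and
scaling invariance is covered by a linearity property test. Zero contacts
force `S_f = 0` regardless of confidence.

The per-residue profile averages fragment scores over the fragments
covering each residue: `r_i = (Σ_{f ∋ i} S_f) / c_i`. Fragments without a
scored structure are excluded from both numerator and denominator (not
treated as zero — a failed prediction carries no evidence either way), and
residues with zero coverage are NA, never 0. The bookkeeping identity
`Σ_i c_i·r_i = Σ_f S_f·len(f)` holds to 1e-9 relative tolerance and is
asserted on every full run in the tests.

### Motif calling

The bait is split at `floor(L/2)` (the only boundary needing no extra
information; configurable via `split`). The peak threshold default is
`mean + 1·sd` over the defined profile values of the whole profile, which
is scale-free under the linearity property. Within each half, residues at
or above threshold form maximal contiguous runs (undefined residues break
runs); the run containing the half's maximum is the best peak, ties to
the leftmost run. A degenerate all-equal profile has sd 0, so every
residue qualifies and each half returns whole — this is the documented
outcome, not an error. A half whose values all fall below threshold
yields no peak, with a warning: with a single dominant binding site, the
global threshold deliberately refuses to call a peak in a half with no
comparable signal.

Peak refinement formalises what is otherwise a manual structure-inspection
step: among the peak's supporting fragments the one with the highest
`S_f` is chosen (leftmost on ties), its contacting bait residues are
grouped into runs allowing internal gaps ≤ `gap_tolerance` (default 1,
so a single non-contacting residue does not split a motif), and the run
with the largest total contact count whose span is ≥ `min_motif_length`
(default 5) becomes the motif. The defaults are sized so that motifs in
the 9–15-residue range typical of minimal binding peptides are
recoverable. All tie-breaks everywhere are leftmost, making calls
byte-reproducible.

## Synthetic data generator

The generator emulates the *geometry and metadata* the scorer consumes —
two chains of heavy atoms, residue numbering, per-residue B-factor
confidence — without any biophysics. The bait is a CA/CB trace at the
canonical 3.8 Å CA–CA spacing; the receptor is a CA trace on a parallel
line 20 Å away. Planted bait residues receive `floor(contact_density)`
receptor partner atoms (plus one more with probability equal to the
fractional part, always ≥ 1, partners distinct) placed 2.5–3.2 Å from the
residue's CA; with the default density 2.0 the planted contact counts are
exact, so the planted interface strength is a controlled condition rather
than a sampling outcome. Decoy contacts are Poisson-sampled per
non-planted residue at `decoy_rate`, and every injected pair is recorded
in `ground_truth.json`, keeping oracle comparisons exact rather than
statistical. Gaussian coordinate noise (default sd 0.1 Å) is applied
last with rejection resampling: a draw is accepted only if a KD-tree
re-check reproduces the intended contact classification on the
coordinates as they will be written (3-decimal PDB precision).

Geometric margins: planted contact atoms sit ≥ 4.3 Å from neighbouring
bait residues (the 3.8 Å backbone spacing bounds how close they can get),
and baseline receptor atoms are 20 Å away, so the planted/non-planted
distinction survives the noise levels the defaults use. Residues adjacent
to a planted residue therefore see receptor atoms nearer than 8 Å — an
unavoidable consequence of backbone geometry — but never within the
contact cutoff.

What the generator does *not* emulate: folded conformations, side-chain
packing, chemically plausible interfaces, correlated pLDDT structure, or
partial/failed predictions. Passing recovery tests therefore demonstrate
the correctness of the scoring and calling machinery under known ground
truth, not the adequacy of any structure predictor on real proteins.

## Default conditions and problem sizes

The validation study runs at the scale of the motivating screen: a
315-residue bait, window 50 / step 25 (12 fragments), a 119-residue
receptor (the length of the three LDL repeats used as the receptor
construct), cutoff 4.0 Å, uniform pLDDT 80, and one planted segment per
half at residues 28–36 (9 aa) and 197–209 (13 aa). The clean condition
uses no decoys; the stressed condition adds `decoy_rate = 0.05` and pLDDT
noise of sd 5, and recovery is measured as interval Jaccard ≥ 0.5 per
half across 20 seeds. These sizes keep a full run under a few seconds
while exercising every stage at the screen's real dimensions.

## Numerical and degenerate-input choices

- Distances and profile values in double precision; TSV output at 6
  significant digits; profile NA encodes undefined, never 0.
- Cutoff comparison inclusive; contact dedup at the residue-pair level.
- The manifest's `global_start` — not numbering inside the structure file
  — is the coordinate authority, because predictors renumber each chain
  from 1; a mismatch between manifest and tiling is a hard error rather
  than a silent shift.
- Multi-model files: first model only, with a warning. pLDDT outside
  [0, 100] passes through with a warning (garbage B-factors should be
  visible, not silently clamped).
- Empty chains yield zero contacts with a warning; an empty pLDDT map is
  an error (a fragment score without confidence is undefined).
- All generator randomness flows from one explicit seed; per-fragment
  seeds are derived arithmetically so datasets are byte-reproducible.

## Known limitations

- The interaction score is a contact census, not an affinity estimate; it
  cannot rank two true binders by strength.
- The fixed half-split calls at most one motif per half; baits with more
  than two binding sites need a different peak policy.
- The global mean+1·sd threshold can suppress the weaker half's peak when
  one site dominates the profile; a per-half quantile policy is available
  when both halves must always report.
- Receptor-side confidence is ignored: only bait-fragment pLDDT enters
  the weighting.
- PAE (predicted aligned error) is not parsed; in real screens it carries
  complementary interface evidence.
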