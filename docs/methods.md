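# Methods

This note documents the models and procedures implemented in `fwdyn`, the
parameter choices that matter, what the synthetic-data generators emulate,
and the numerical decisions taken where the design was genuinely open.

## Data model and I/O (`fwdyn.structio`)

Residue indexing is 1-based per chain with inclusive ranges; all coordinates
are in Å and all times in ps. Trajectories are interchanged as multi-model
PDB (one MODEL per frame, parsed and written via biotite), which keeps the
package free of MD-engine formats; PDB's fixed-point coordinate field limits
round-trip fidelity to 10⁻³ Å. Antibody numbering is *not* computed:
FW1–FW4/CDR1–CDR3 region maps are ingested as TSV tables (produced externally
by IMGT-scheme tools) and validated so that ranges within a chain never
overlap. Elements map to masses through standard atomic weights. Result
tables are TSV (floats at 6 significant digits, NaN as `NA`) or JSON.
Trajectory analyses accept a frame stride/window because published analyses
do not always use every frame; the coupling stage exposes the analysis
window as a tail fraction (default 0.5, i.e. the last half of each replica,
the equilibrated part of a production run).

## Saturated mutational scanning (`fwdyn.mutscan`)

The harness masks one position at a time and asks a scorer for 20 scores at
that position, invoking it exactly L times for a length-L chain. Scorers
declare `emits = "logits" | "probabilities"`; logits pass through a plain
softmax at temperature 1. Per position the wild-type (WT) probability and
rank are reported; rank uses the strictly-greater convention (1 + number of
amino acids scored strictly above WT), so ties share the best rank — a
deterministic rule that is optimistic for the WT. Region summaries report
median and inter-quartile range per aligned position across antibodies.
Per-antibody WT confidence can be aggregated by mean or median over
positions (both exposed; mean is the default) before rank-correlating with
germline identity; Spearman's ρ uses an exact enumeration p-value for
n ≤ 9 tie-free samples and the large-sample approximation otherwise.

ΔΔG handling: negative ΔΔG (kcal/mol) is stabilizing, positive
destabilizing; ΔΔG = 0 is classified destabilizing so that "stabilizing"
always means strictly favourable. Double-mutant filtering requires
(a) a negative double-scan ΔΔG and (c) repertoire occurrence of each mutant
residue above a threshold (default 1%); sign agreement between the double
ΔΔG and the sum of single ΔΔGs (b) is recorded but *not* required, because a
pair of individually destabilizing substitutions can be jointly stabilizing
(e.g. through charge compensation) and such pairs are legitimate designs.
The candidate set is monotone in the occurrence threshold by construction.

## Geometric descriptors (`fwdyn.geomdyn`)

All selections are mass-weighted centers of mass (COM) unless disabled.
The antigen-engagement proxy is the Euclidean distance between the CDR-loop
COM and the antigen juxtamembrane-region COM, per frame. The VH–VL packing
angle is the planar angle at the VL COM between the vectors to the
light-chain-CDR COM and the VH COM — the vertex is configurable, and fixed
at VL by default because the light-chain CDR and VH flank the VL domain.
RMSD superposes the selected atoms by mass-unweighted Kabsch (proper
rotations only) before averaging. Native contacts are heavy-atom pairs
within 4.5 Å in the reference, excluding pairs fewer than 3 residues apart
in the same chain; a contact is retained in a frame if its distance stays
within 1.2× the cutoff. All three numbers are configurable and recorded in
run manifests; they are conventional literature values, not fitted.

Unbinding detection: the baseline is the mean of the first `baseline_window`
frames (default 5% of the series); an event is called when, after the last
frame that dips below the baseline, the series exceeds 1.5× baseline for at
least 10% of all frames. The "after the last dip" clause encodes
*unrecovered* excursions: a transient spike that returns to baseline is not
an unbinding event. The call is monotone in the factor. These are heuristics
for flagging candidate events for inspection, not a kinetic model.

## Interaction classification (`fwdyn.contacts`)

Every detector is a two-test geometric rule; boundary equality satisfies a
criterion, and comparisons carry a 10⁻⁹ absolute guard so that geometries
constructed exactly on a boundary are classified identically regardless of
coordinate roundoff. Defaults (all configurable, all recorded in the
manifest):

| interaction | distance test | angle test |
|---|---|---|
| hydrogen bond | H…A ≤ 2.5 Å | ∠D–H…A ≥ 120° |
| π–π stacking | COM_ring–COM_ring ≤ 5.5 Å | inter-normal ≤ 30° |
| CH/NH–ring | X–COM_ring ≤ 4.5 Å | ∠X–H–COM_ring ≥ 120° |

Ring normals come from the best-fit plane (smallest principal axis of the
centred ring atoms); since a plane normal is sign-ambiguous the inter-normal
angle is folded to [0°, 90°] via min(θ, 180°−θ). Donor hydrogens are paired
to their heavy atom by a 1.3 Å covalent-distance rule on the first frame, or
supplied explicitly. Intra-residue pairs are never events.

Networks: an edge is an (unordered residue pair, interaction type); its
frequency is the fraction of frames with at least one such event (presence,
not multiplicity). Edges below a minimum frequency (default 0.1) are
dropped. Differencing two networks takes the union of edges (absent = 0),
reports Δfrequency per edge, and defines the perturbed-residue set as the
endpoints of edges with |Δfrequency| ≥ 0.25.

## Structural-alphabet coupling (`fwdyn.coupling`)

Fragment i covers residues i..i+3; its state in a frame is the alphabet
prototype with minimal Cα RMSD after optimal superposition, ties broken to
the lowest label. Fragments spanning a residue without a Cα are excluded
from all pairs. The bundled 25-state alphabet file
(`src/fwdyn/data/alphabet_synthetic_m25.tsv`) is a *synthetic* stand-in
carrying the canonical schema and cardinality of the M32K25 alphabet, whose
published prototype coordinates are not redistributed here; any real
alphabet in the same TSV schema (state, point 1–4, x, y, z) is accepted.

Coupling between two fragment-state series is the corrected normalized MI

  nMI = clamp₀¹ (I − b) / (H(X,Y) − b),

where I is the plug-in MI (bits) of the frame-wise contingency table and
H(X,Y) the joint entropy. The correction b is, in analytic mode, the
first-order plug-in bias (R_X−1)(R_Y−1)/(2 F ln 2) with R the occupied state
counts; in permutation mode, the mean MI over seeded shuffles of one
sequence. Subtracting b from numerator *and* denominator was a deliberate
choice among the plausible normalizations: it keeps identical non-constant
sequences at exactly 1 (I = H(X,Y) cancels), sends independent sequences to
≈ 0 (measured mean 1.5 × 10⁻⁴ at F = 2000, M = 4 over 50 seeds), and stays
within [0, 1] by clamping. Two constant sequences define nMI = 0.

Differential coupling compares per-replica mean nMI between bound and
unbound ensembles: log2FC = log2((m_b + ε)/(m_u + ε)) with pseudocount
ε = 10⁻⁶ guarding zero coupling. Three p-value options are provided:

* **permutation** (default) — replica-label permutation of the mean
  difference, exhaustive when the number of assignments is at most
  C(10,5) = 252, otherwise 10 000 seeded draws. Exact, but with 3 vs 3
  replicas the null has only 20 assignments, so the smallest achievable
  two-sided p is 0.1 — too coarse for FDR < 0.01.
* **welch** — Welch's unequal-variance t. On these data the bound and
  unbound coupling variances differ strongly, the Welch–Satterthwaite
  degrees of freedom collapse toward 2, and the heavy-tailed null costs most
  of the power at small α.
* **student** — pooled-variance t with df = 2(R−1). With *equal group
  sizes* the pooled test retains its nominal size under variance
  heterogeneity, and at R = 3 the extra degrees of freedom matter; this is
  the recommended (and the analysis scripts' and acceptance checks') test
  for hub calling at α = 0.01 with 3 replicas. Its null calibration was
  verified directly: the average fraction of pairs reaching BH-adjusted
  p < 0.01 under no injected difference is ~10⁻⁴ over 100 runs.

BH (Benjamini–Hochberg) adjustment runs across all fragment pairs. Hubs are
pairs with |log2FC| > 2 and adjusted p < 0.01 (both thresholds
configurable); direction is bound-favoured for positive log2FC. Per-residue
hub frequency counts, for each residue, the hub pairs with a member fragment
covering it (pair counting; unique-fragment counting is available).

## Synthetic data (`fwdyn.synthdata`)

All generators draw from `numpy` Generators seeded by the user seed plus a
stable per-component offset, so every output is bit-reproducible and new
outputs never reshuffle existing streams. Each generator emits machine-
readable ground truth.

* **State sequences** — fragments are i.i.d. uniform over M states except
  injected pairs, where fragment j copies fragment i with probability s and
  redraws uniformly otherwise. This noisy copy channel has closed-form MI
  (P(Y=X) = s + (1−s)/M), so a target coupling or fold change can be set
  analytically; `strength_for_nmi` inverts the channel. The default
  two-condition contrast couples one pair at nMI 0.4 (bound) vs 0.05
  (unbound) — log2FC = 3 — against a background of independent fragments,
  with 3 replicas × 2000 frames per condition, M = 4. A weak unbound
  baseline (rather than nothing) makes the true fold change well-defined;
  with strictly zero unbound coupling the ratio is pseudocount-dominated.
* **Toy complexes** — two rigid antibody-like bead domains (Cα + sidechain
  bead per residue) plus an antigen blob; optional linear antigen drift
  (Å/frame) emulates unbinding and gives an analytic threshold-crossing
  onset; ring-pair and donor–H–acceptor motifs are placed at exact target
  geometry in frame 0 with Gaussian jitter thereafter. The generator writes
  valid PDB records so the I/O layer parses them unchanged. These toys have
  no force field, no solvent, no internal domain motion: tests against them
  validate the *measurement* code (geometry, classification, statistics),
  not any physical realism of antibody dynamics — conclusions about real
  trajectories still require real MD input.
* **Mock scorers** — per-position standard-normal logits with the WT logit
  raised by a per-region bias, emulating the empirical contrast in which
  sequence models are near-certain of framework residues but uncertain in
  the CDRs. At bias 0 the WT rank is uniform on 1..20; at large bias every
  rank is 1.
* **Repertoires** — sequences sampled from per-position residue
  distributions over a consensus background; the emitted profile holds the
  empirical fractions, so recounting the FASTA reproduces it exactly.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` exercise: the MI implementation
against an independent contingency-table oracle on 1000 random pairs
(agreement to 10⁻¹² bits); corrected-MI calibration (independent mean
≤ 0.01 at F = 2000 over 50 seeds; identical sequences exactly 1); hub
recovery on 3v3 × 2000-frame ensembles with the injected log2FC = 3 pair
over 50 seeded runs (recovery and zero-false-hub rates reported) plus null
calibration over 100 runs; permutation-test exactness against full
enumeration on 100 instances; rigid-motion invariance of all geometric
descriptors under 100 random rotations+translations (≤ 10⁻⁶); detector
truth tables on 10×10 distance–angle grids including exact boundary points
(100% agreement required); unbinding-onset accuracy within ±10 frames of
the analytic crossing on drift trajectories and zero false calls on 50
flat-with-jitter trajectories; the FW/CDR median-rank contrast over 50
seeds; and 20-point filter-threshold monotonicity. These sizes keep the
whole verification run in the low tens of seconds while leaving each
statistical check comfortably powered.

## Known limitations

* The bundled alphabet is synthetic; encodings of real trajectories should
  load the published M32K25 prototypes.
* Interaction cutoffs are generic literature values; study-specific cutoff
  tables can be dropped in via `GeomCriteria`/config.
* The unbinding detector is a flagging heuristic with three tunables, not
  an estimator of kinetics.
* Trajectory input assumes whole (imaged) molecules; no PBC handling.
* Salt bridges and cation–π interactions are not specialised detectors;
  the H-bond and distance machinery covers the geometry but not the
  chemistry-specific typing.
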