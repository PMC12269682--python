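# fwdyn — antibody framework mutagenesis triage and trajectory coupling analysis

Antibody engineering usually concentrates on the complementarity-determining
regions (CDRs), the loops that touch the antigen. The immunoglobulin
**framework** (FW) that scaffolds those loops is mutable too: FW substitutions
can raise thermostability, and — because conformational changes propagate from
the paratope through the FW toward the constant domains — they can also alter
antigen binding and Fc-mediated effector function from a distance. `fwdyn`
implements the computational side of a design workflow for FW mutations in two
directions:

* **structure-first triage** — saturated per-position mutational scanning with
  pluggable scorers (masked-prediction language-model style), wild-type rank
  statistics by FW/CDR region, classification of stability scans
  (ΔΔG<sub>folding</sub>, negative = stabilizing), and filtering of double
  mutants by predicted stability and natural repertoire occurrence;
* **dynamics-first design** — descriptors of molecular-dynamics ensembles
  (CDR–antigen center-of-mass distance as a binding proxy, VH–VL packing angle
  and distance, RMSD, native-contact retention, unbinding detection), geometric
  classification of non-covalent interactions (Baker–Hubbard hydrogen bonds,
  π–π stacking, CH/NH–ring) with differential residue-interaction networks, and
  structural-alphabet coupling analysis that localizes antigen-binding-coupled
  backbone motion.

## The coupling statistic

Each trajectory frame is coarse-grained into local backbone states: every
fragment of four consecutive residues is assigned, by minimal Cα RMSD after
optimal superposition, to one prototype of a structural alphabet (canonically
the 25-state M32K25 alphabet; a synthetic stand-in with the same schema is
bundled, and any M-state alphabet file loads in its place). For fragment-state
time series X, Y over F frames the coupling strength is a corrected,
normalized mutual information

```
nMI(X,Y) = clamp[0,1] ( I(X;Y) − b ) / ( H(X,Y) − b ),
b = (R_X − 1)(R_Y − 1) / (2 F ln 2)        [bits]
```

with I the plug-in MI of the frame-wise contingency table, H(X,Y) the joint
entropy and b the first-order finite-sampling bias (R = occupied state counts;
a permutation-null correction is available as an alternative). Comparing mean
coupling between antigen-**bound** and **unbound** replica ensembles gives per
fragment pair a log2 fold change and a p-value (replica-label permutation,
Welch, or pooled-variance Student t), BH-adjusted across pairs. **Hubs** are
pairs with |log2FC| > 2 at FDR < 0.01; projecting hub membership onto residues
(fragment i covers residues i..i+3) maps binding-coupled motion onto the
sequence, flagging positions whose mutation may decouple binding from
function.

## Worked example

The numbered scripts under `analysis/` run both workflows end to end on
synthetic data with known ground truth (no downloads):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_mutational_scan.py
python analysis/03_dynamics_descriptors.py
python analysis/04_interaction_networks.py
python analysis/05_coupling_hubs.py
```

Output of `05_coupling_hubs.py` (bound/unbound ensembles, 3 replicas × 2000
frames, one coupling injected at analytic log2FC = 3 between fragments 2
and 7):

```
injected coupled pair(s): [(2, 7)]
called hubs: [(2, 7)]
  fragments 2-7: log2FC 3.02 (bound-favoured), padj 9.72e-04
hub residues: [ 2  3  4  5  7  8  9 10]
```

The injected pair is the only called hub; its measured fold change matches the
analytic value and the hub residues are exactly the residues covered by the
two member fragments. Earlier stages print the FW-vs-CDR wild-type rank
contrast (`median WT rank: FW 1, CDR 10.0`), the destabilizing fraction of a
synthetic ΔΔG scan (`0.951`), the detected unbinding onset against its
analytic expectation (`onset 68, analytic 69`), and the residues whose
interaction network a destabilising variant perturbs.

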