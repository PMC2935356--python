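# Methods

## The protocol

`rdhmm` scores a three-dimensional protein model by its ability to retrieve
its own amino-acid sequence. The chain of reasoning: a correct backbone in a
crystal-like equilibrium conformation (bond lengths, angles and dihedrals
distributed as in X-ray structures) constrains which residues fit at each
position; an ensemble of sequences designed onto that fixed backbone with no
functional information therefore carries a structural signature of the fold;
a profile hidden Markov model compiled from that ensemble will assign a high
log-odds score to the natural sequence of the protein — and to little else —
if and only if the backbone is right. The pipeline is:

1. **Design** (`design_engine`): `n` independent Metropolis simulated-
   annealing runs, each from a fresh uniformly random sequence, on the rigid
   backbone.
2. **Alignment** (`ensemble_msa`): trivial for a single structure (all
   sequences share the backbone's length and residue correspondence);
   multi-structure combined models propagate a master gap pattern taken from
   an external structural alignment.
3. **Profile** (`profile_hmm`): match/insert/delete profile HMM with
   background-weighted pseudocounts and Laplace-smoothed transitions,
   calibrated by a maximum-likelihood Gumbel fit to scores of random
   background sequences.
4. **Search / assessment** (`hmm_search`, `model_assess`): scan a FASTA
   database, rank hits by bit score, convert to E-values, and judge a model
   from the score of its native sequence relative to its length.

## Design energy

The design stage is intentionally coarse: the backbone is rigid, side chains
are reduced to scalar properties, and the energy has four terms

    E = w_rama  * sum_i -ln P(aa_i | rama class_i)
      + w_burial* sum_i b_i (1 - h_i)
      + sum_{contacts(i,j)} [ -w_pair h_i h_j + w_chg q_i q_j ]
      + w_steric* sum_i v_i crowd_i

with h = Kyte–Doolittle hydropathy rescaled to [0, 1], q in {-1, 0, +1}
(Asp/Glu negative, Lys/Arg positive), v = normalized side-chain volume,
b_i = 1 when the CA neighbor count within 8 Å (excluding sequence neighbors)
reaches 6, contacts = CA pairs under 8 Å with |i-j| >= 3, and
crowd_i = max(0, neighbors within 6 Å - 3). The Ramachandran classes are a
four-way partition of the torus (right-handed helical, extended, left-handed
helical, other), and the propensity table P(aa | class) is a coarse
secondary-structure-propensity stand-in in which positive-phi (alphaL)
positions strongly favor Gly, then Asn and Asp — the residues that tolerate
strained backbone dihedrals. All tests that touch the table are
table-relative; no test hard-codes a residue ranking that the shipped table
does not imply.

Default weights (1.0, 1.0, 1.0, 0.5, 0.5) put the backbone-conditioned term
and the hydrophobic terms on comparable scales. Annealing defaults: T from
5.0 to 0.05 on a geometric schedule, 200 proposed single-position
substitutions per residue, so an 80-residue design runs in tens of
milliseconds and a 200-sequence ensemble in a few seconds. Energy deltas are
evaluated incrementally (only terms touching the mutated position) and a
property test pins them to full re-evaluation within 1e-9.

A full-atom design program writes a random sequence into the structure first
and then rebuilds it, producing strained high-energy intermediates. In a
backbone-only energy this first stage collapses to random initialization of
the annealer, which is how it is implemented here: one random start, one
designed sequence.

## Profile construction and scoring

Columns with gap fraction below 0.5 become match states. Match emissions use
background-weighted pseudocounts, p_a = (n_a + alpha·bg_a)/(n + alpha) with
alpha = 1 by default; the background is uniform 1/20. Transitions are counted
from per-row state paths with +1 smoothing; the state set is M→{M,I,D},
I→{M,I}, D→{M,D} per node (the rare I→D and D→I events in an alignment are
routed through the nearest legal move).

Scoring is **glocal** Viterbi in log2-odds: the model must be traversed from
node 1 to node M (deletions allowed), while any prefix and suffix of the
target sequence are free; insert emissions equal the background so inserted
residues cost only transitions. This mode was chosen deliberately over a
fully local free-entry/exit mode: with free entry and exit the best local
score of a *random* sequence is a maximum of many non-negative path starts
and is almost always positive, which destroys "positive bits" as a decision
boundary. Under glocal scoring a random sequence must pay the log-odds of
every column, so unrelated sequences score strongly negative (tens of bits
below zero), well-fitting sequences score proportionally to model length,
and retained hits near the E-value threshold can carry negative scores —
the regime in which the joint cutoff "bits > 0 and E <= 1" eliminates false
positives outright. Scores are comparable across runs of this tool only;
parity with any external HMM package is a non-goal, and Viterbi (not
forward) scores are used throughout. The vectorized scorer and the
path-reporting scorer are pinned to each other and to exhaustive path
enumeration on all toy models with M <= 4 over a 4-letter alphabet.

Calibration scores `n_samples` (default 1000) i.i.d. background sequences
with lengths Normal(M, 0.2·M) truncated at 10, and fits a Gumbel law by
maximum likelihood; E = n_db · (1 − exp(−exp(−lambda(s − mu)))) uses the
exact survival function. The fit recovers a known Gumbel(−5, 0.7) from 5000
draws to within ±0.15 in mu and ±0.05 in lambda.

## Verdict rules

With L the model's length, the native-score thresholds are 0.3·L (good
model) and 0.6·L (crystal-like). A model is rejected when its native bits
are non-positive or the native E-value exceeds 1 — the operating point at
which decoy databases produce no false positives. Any gap in the native
alignment demotes crystal_like or good one level, because a correct model
retrieves its own sequence gaplessly. The native E-value needs a database
scale; the report uses a configurable `db_size` (default 1000, the decoy
database size used throughout the desk-scale experiments). The reference
score-vs-length line is always refit from user-supplied (L, score) points —
only the 0.3/0.6 rule is built in.

## Synthetic fixtures: what they emulate and what they do not

Backbones are built in internal coordinates (NeRF placement) with ideal bond
lengths (N–CA 1.458, CA–C 1.525, C–N 1.329 Å), ideal angles and trans
peptides; only phi/psi vary. The default test subject is an 80-residue mixed
fold (three helices, two strands, two three-residue positive-phi turns).
Dihedral noise emulates the backbone divergence between X-ray and NMR or
modeled coordinates: phi/psi receive i.i.d. Gaussian noise and the chain is
rebuilt. Because there is no loop closure, torsion noise propagates down the
chain with a lever arm, so the Cartesian RMSD per degree of noise is much
larger than in a real relaxed structure (sigma = 10 degrees gives ~10 Å on
an 80-mer); the perturbation level should be read as dihedral-space noise,
with the achieved RMSD reported alongside. Decoy databases are i.i.d.
background sequences with lengths Normal(250, 100) truncated at 20 —
typical globular-protein lengths — and "homolog"/pseudo-native sequences
are column-wise samples from a profile's match emissions at a temperature
(argmax consensus as T→0). Since no natural protein family is involved,
passing tests demonstrate the internal consistency and discriminative power
of the protocol on idealized geometry, not retrieval performance on real
databases; real backbones carry correlated deviations from ideal geometry,
side-chain-dependent packing and composition biases that these generators
do not model.

The pseudo-native deserves emphasis: for a synthetic fold there is no
natural sequence, so the protocol's "native" is a temperature-1.0 sample
from the fold's own design-derived profile, labelled pseudo-native
everywhere. Scores per length for such sequences (~3 bits/residue) sit well
above the 0.6·L crystal-like threshold, as expected for a sequence drawn
from the very distribution the model encodes; the thresholds themselves are
calibrated for natural sequences and are exercised by the rule tests, not
by the pseudo-native's absolute score.

## Structure input

PDB parsing keeps the four backbone heavy atoms only. Residues missing any
of N/CA/C/O are dropped with a warning (they cannot be designed on);
alternate locations collapse to the highest-occupancy copy (kept rather
than discarded, to preserve usable input, and flagged by the validator);
selenomethionine maps to methionine; other non-standard residues are
dropped at parse time and flagged if constructed directly. Validation is
report-only: zero B-factors, non-standard names, retained altlocs, and
chain breaks at CA–CA > 4.3 Å (trans peptide ≈ 3.8 Å). Superposition RMSD
uses the Kabsch least-squares rotation over the intersection of author
residue numbers, atom set N, CA, C, O by default.

## Numerical choices and problem sizes

- All dynamic programming in log2 space; no linear-space probability
  products along paths. Ties in the Viterbi maximum resolve toward the
  match state (argmax order M, I, D), which is irrelevant to scores.
- Per-run seeds derive from a root seed via `numpy.random.SeedSequence`
  spawning, kept below 2^31; every generator is a pure function of
  (spec, seed).
- Dihedrals are degrees in [-180, 180); the builder and the measurement
  agree with the IUPAC sign convention (checked against an independent
  plane-normal oracle and Biopython).
- Default experiment sizes — 200-design ensembles, 1000 calibration
  samples, 1000-decoy databases, five replicates per noise level — were
  chosen so a complete retrieval experiment runs in seconds on one core
  while leaving the stochastic acceptance margins wide; the ensemble size
  is configurable up to the hundreds-to-thousands used for combined
  multi-structure models.

## Known limitations

- The design energy is not a physical potential; ensemble composition
  statistics (not absolute energies) are the meaningful output.
- Unihit scoring only: a sequence containing two copies of the fold is
  counted by greedy re-scoring with masking (`count_domains`), not by a
  multi-hit model architecture.
- No null-model composition correction; scores of biased-composition real
  sequences would shift accordingly.
- mmCIF input, side-chain reconstruction and force-field minimization are
  out of scope.
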