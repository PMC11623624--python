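# Methods

## Scientific setting

Proteins from hyperthermophilic organisms carry a characteristic
compositional signature — more charged and apolar residues at the solvent
surface, fewer polar uncharged ones, a denser apolar core — that correlates
with strongly elevated melting temperatures. An inverse-folding model
trained on such proteins internalises that signature and can transfer it to
backbones from mesophilic organisms, which is the premise of this package:
curate a predicted-structure dataset, train a message-passing
sequence-design network on it, quantify the compositional and electrostatic
signatures, and redesign an oligomeric subunit while freezing its assembly
interfaces.

## The model

Each residue is a node of a k-nearest-neighbour graph (CA distances,
default k = 48). Edges carry

* radial-basis-expanded distances between all 25 ordered pairs of
  N/CA/C/O/virtual-CB atoms of the two residues — 16 Gaussian bases with
  centres evenly spaced on 2–22 Å, width (22−2)/16 Å;
* a one-hot relative sequence position, clipped to ±32, valid only within a
  chain;
* a same-chain flag.

The virtual CB is always constructed from the backbone frame (1.52 Å from
CA, tetrahedral, L-configuration), so glycine and side-chain-free inputs are
handled uniformly. Node features start at zero; all structural information
enters through edges.

The encoder (default 3 layers, hidden width 128) updates node states with a
three-layer message MLP over (h_i, h_j, e_ij), mean-aggregated over the k
neighbours, followed by a position-wise feed-forward block; both are
residual with layer normalisation, and each encoder layer also updates the
edge states. The decoder (3 layers) is autoregressive under a uniformly
random decoding order: for each directed edge, a neighbour that was decoded
earlier exposes its amino-acid embedding and live decoder state, while a
not-yet-decoded neighbour exposes only its encoder state. A linear map and
log-softmax produce per-position distributions over the 20-letter alphabet.

Training uses teacher forcing with a fresh random decoding order per
example, isotropic Gaussian noise on backbone coordinates (default
0.2 Å, applied before any distance computation), dropout 0.10, one random
member per training cluster per epoch, and token-capped batches (default
10,000 tokens, 300 epochs, 20,000 examples per epoch). Validation and
sampling run with noise and dropout disabled. Perplexity is the
exponentiated mean per-residue cross-entropy (20 = uniform); accuracy is
argmax recovery. Sampling divides logits by a temperature (default 0.001 in
the design workflow, i.e. near-greedy), emits fixed positions verbatim while
conditioning on them, and scores a finished sequence by the global score:
mean negative log-likelihood over all positions under a teacher-forced
re-scoring with the same decoding order (lower is better). A designed-only
variant (`score_designed`) is provided.

### Numerical substrate

The network runs on a small reverse-mode automatic-differentiation engine
over numpy float64 arrays written for this package (`thermodesign.autograd`):
broadcast arithmetic, matmul, gather/scatter, concat, reductions, ReLU,
exp/log, layer normalisation and log-softmax, with gradients verified
against central finite differences in the test suite. The optimizer is Adam
(β₁ = 0.9, β₂ = 0.98, ε = 1e-9) with global gradient-norm clipping at 1.0
and three schedules: `constant`, `cosine` (decay to zero over the planned
step budget), and `reference` (inverse-square-root warmup). ReLU is used in
the message and feed-forward MLPs. Model initialisation is Glorot-uniform
and fully determined by the configuration seed.

## Synthetic data

Every test runs on generated structures, built atom-by-atom with ideal bond
lengths/angles via natural-extension-reference-frame placement:

* `build_chain` — single or multi-chain backbones at canonical (φ, ψ):
  helix (−57°, −47°), strand (−139°, +135°), coil (−75°, +150°); CB placed
  at explicit tetrahedral geometry; optional constant or per-residue
  confidence values.
* Sequences are explicit, uniform-random, or *propensity*-sampled: 75% of
  probability mass on a secondary-structure-specific residue set
  (helix AELKQRM, strand VIFYTWL, coil GPSNDTK). The propensity mode exists
  because uniform-random sequences carry no learnable sequence–structure
  signal at all — uniform prediction is then optimal, which makes
  generalisation tests meaningless. Propensity sequences emulate the
  composition-level signal of real data.
* `build_salt_bridge_toy` — an extended chain whose only charged groups are
  requested (basic, acidic) pairs with the basic nitrogen placed at an exact
  distance from a carboxylate oxygen; cross-pair groups are > 8 Å apart.
  Side chains are simplified extended geometries carrying the correctly
  named charged-group atoms; no rotamer realism is claimed.
* `build_assembly` — multi-chain fixtures whose minimum inter-chain CB
  distance is set by bisection on the translation axis (converged to
  0.01 Å).

What the fixtures do **not** emulate: packing-quality cores (generated
chains are largely solvent-exposed), real rotamers, loop irregularity,
missing density, or the compositional signature of any real proteome.
Passing tests therefore demonstrate correctness of the machinery — geometry
handling, featurization, training dynamics, counting rules — not predictive
performance on natural proteins, which would require the proteome-scale
dataset and compute that are explicitly out of desk scale here.

## Curation

Confidence filtering keeps structures with mean pLDDT ≥ 70 by default. A
per-residue local cutoff is implemented but disabled by default, since no
specific threshold value is established for it; when enabled it requires
every residue to clear the cutoff.

Pairwise identity uses global alignment with free terminal gaps (match +1,
mismatch 0, gap open −10, extend −1; biotite's aligner). Identity is matches
over alignment columns excluding terminal-gap columns; coverage is aligned
columns over the shorter sequence length. Because co-optimal alignments
exist, the pair is canonically ordered before aligning, which makes the
function exactly symmetric. Clustering is greedy incremental
(CD-HIT-style): longest sequence first, each sequence joins the first
representative meeting both thresholds (default identity 0.30,
coverage 0.80), otherwise founds a cluster. Externally computed
representative→member tables (mmseqs easy-cluster TSV dialect) are accepted
as a drop-in replacement via `read_clusters_tsv` / `--clusters-tsv`.

Splits are cluster-level only. Bucket sizes are floors of the exact
fractional counts with the remainder assigned by largest fractional part,
so 100 clusters at 0.90/0.06/0.04 give exactly 90/6/4. Default fractions
follow those proportions; the split is a seeded permutation and fully
reproducible. Exported datasets are one HDF5 record per structure plus a
JSON manifest; pseudo-ids are 4 base-36 characters from a stable hash with
deterministic collision resolution.

## Metrics

* **SASA** — native Shrake–Rupley: each atom's solvent-extended sphere
  (r + 1.4 Å probe) is sampled with a 960-point golden-spiral lattice; a
  point is accessible iff outside every other extended sphere. Van der
  Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å. Per-residue SASA is the
  sum over the residue's atoms, so totals decompose exactly. Tests compare
  against a million-point Monte-Carlo oracle (agreement well inside 2%) and
  the closed-form sphere area. Backbone-only inputs are computed on
  backbone+CB and flagged approximate.
* **Surface/core** — surface iff per-residue SASA > 30 Å² (ties → core).
  The threshold is configurable; 30 Å² of area is the intended reading of
  the conventional cutoff.
* **Composition** — counts pooled over structures, normalised per region;
  the class scheme is Arg/Lys positive, Asp/Glu negative, Asn/Gln/Ser/Thr
  polar, Ile/Leu/Met/Phe/Trp/Tyr/Val apolar, Ala/Cys/Gly/His/Pro other
  (His deliberately *not* counted as positively charged). Differences are
  percentage-point subtractions and antisymmetric by construction.
* **Charge** — Henderson–Hasselbalch summation; positive groups (N-term,
  K, R, H) contribute 10^pKa/(10^pKa+10^pH), negative groups (C-term, D, E,
  C, Y) contribute −10^pH/(10^pKa+10^pH). The default pKa table is the
  EMBOSS set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
  C 8.5, Y 10.1); the table is named and swappable, and Cys/Tyr titration
  can be disabled. The isoelectric point is found by bisection to
  |z| < 1e-4 (net charge is strictly decreasing in pH, so the root is
  unique).
* **Salt bridges** — count of (basic, acidic) residue pairs with any basic
  side-chain nitrogen (R: NE/NH1/NH2; K: NZ; H: ND1/NE2) within 4.0 Å of
  any carboxylate oxygen (D: OD1/OD2; E: OE1/OE2), each pair counted once.
  The geometric definition (cutoff, His inclusion) is this package's own
  documented specification, exposed in the configuration. Backbone-only
  structures fall back to a CB-proxy (charged-pair CB–CB ≤ 6 Å), logged as
  approximate.
* **Contact order** — *absolute* contact order: Σ|i−j| / N_contacts over
  same-chain pairs with |i−j| ≥ 3 and any heavy-atom distance ≤ 6 Å.
  The absolute (not relative) form is used because the proteome-scale
  reference values for this quantity are far above 1, which relative
  contact order cannot reach. Structures without qualifying contacts
  return 0 with a warning.
* **Radius of gyration** — unweighted RMS distance of CA atoms from their
  centroid.

## Design workflow

Interface residues of the target chain are those whose CB (inferred for
glycine) lies within 10 Å of any partner-chain CB — a plain distance
criterion; the vector-angle refinement used by some interface detectors is
deliberately not replicated, since only the distance cutoff is an
established parameter here. The design mask is the complement of the
interface on the target chain; all other chains are fully fixed. A batch
(default 200) of sequences is sampled at temperature 0.001 with per-design
seeds spawned from the master seed, ranked by ascending global score, and
the top ⌈fraction·n⌉ (default 10% → 20) feed a per-position majority
consensus. Modal ties break toward the letter with the higher mean model
probability at that position, then lexicographically; score ties at the
rank boundary are all included. Consensus identity to the parent and net
charge at pH 7 are reported alongside a per-position mutation table.

## Problem sizes and study conditions

Desk-scale sizes used by the test suite and the acceptance script, chosen
so the whole pipeline runs on a single CPU in minutes:

* memorization benchmark: five chains (helix 10, strand 11, coil 12,
  helix 13, strand 14 residues), hidden width 64, full neighbourhoods
  (k = 13), no noise, no dropout, cosine-decayed Adam at 3e-3, 200 epochs,
  one structure per batch. The five backbones are geometrically distinct on
  purpose: two congruent backbones with different random sequences would
  make the memorization target ill-posed (the model would have to split
  probability mass between the two sequences wherever decoding context has
  not yet disambiguated them).
* one-epoch generalisation check: 450 propensity-sequence chains of 8
  residues, hidden 32 — one epoch beats the uniform-guessing baseline.
* design workflow: a two-chain helix assembly (12+12 residues) at 7 Å
  minimum CB separation, 200 designs.

## Known limitations

* The training defaults (300 epochs, 10,000-token batches, k = 48, hidden
  128) reproduce the published protocol's configuration, but training at
  that scale needs the proteome-scale dataset and GPU compute; the package
  is validated at desk scale only.
* The numpy engine is single-threaded and eager; it is adequate for
  hundreds of structures of tens of residues, not for 29k-structure
  training runs.
* Charged-residue side chains in fixtures are geometric stand-ins; metrics
  on real structures should use full-atom models.
* The salt-bridge and contact-order definitions are documented
  re-specifications, not bit-compatible reimplementations of any particular
  molecular-modelling suite's internal terms.
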