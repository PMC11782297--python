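# Methods

## Problem and scope

`glycorules` mines human-readable annotation rules that distinguish
O-glycan isomers sharing a precursor mass in negative-mode MS² of reduced
(alditol) glycans. A rule is a conjunction of threshold conditions on
spectrum features — the normalized intensity of a 0.5-Da m/z bin, or the
ratio of two such bins — together with two quality metrics measured on
spectra from experiments never used in training:

* **confidence** — of the test spectra satisfying the rule, the fraction
  whose true label is the rule's isomer (precision);
* **coverage** — of the isomer's test spectra, the fraction satisfying the
  rule (recall).

The package targets singly deprotonated ions ([M−H]⁻) only; multiply
charged species, positive-mode adducts, and permethylated glycans are out
of scope.

## Mass calculus

Residue masses are dehydrated monoisotopic masses from elemental formulas
(Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, Neu5Ac C11H17NO8, Neu5Gc
C11H17NO9, Kdn C9H14O8; sulfate adds SO3, phosphate HPO3). An intact
glycan is Σ residues + H2O; the alditol adds H2; deprotonation subtracts
the proton mass (1.007276 Da), not the hydrogen-atom mass — the choice that
reproduces printed monoisotopic precursors to ~2 mDa. Sulfate and
phosphate are isobaric at nominal mass; annotation-table "S" is stored as
sulfate.

Fragment m/z values follow glycosidic-cleavage bookkeeping: a fragment's
neutral mass is the free-molecule mass of its residue set (Σ residues +
H2O, +H2 if it retains the reduced root), minus one water per B-type or
Z-type terminus (C-type and Y-type termini add nothing). This yields
B = Σres − H⁺, C = B + H2O, Y = substructure alditol [M−H]⁻, Z = Y − H2O,
and the exact complementarity mz(B) + mz(Y) = precursor − proton for every
single cleavage, which the test suite verifies on random structures.
Double cleavages produce composite fragments (internal pieces and double
branch losses). A-type cross-ring ions are modeled as configured neutral
losses on the intact ion or Y fragments (⁰ʼ²A ≙ −C2H4O2, ²ʼ⁴A ≙ −C4H8O4)
rather than by general ring-bond combinatorics — sufficient for the
reducing-end cross-ring ions that appear in practice at unit resolution.
The default neutral-loss set {H2O, 2·H2O, CO2, C2H4O2, C2H6O3, C2H6O4}
covers water/carboxylate losses and the sialic-acid acetyl/glycolyl losses
that make M−78 and M−94 diagnostic for sialylation of the reducing-end
GalNAc.

## Preprocessing and features

Intensities are expressed as fractions of the base peak, so a "1%" rule
threshold is 0.01 and every feature is invariant to uniform rescaling of a
spectrum's raw intensities — the property that makes mined rules robust to
systematic inter-laboratory intensity shifts. Peaks are summed into
half-open bins [k·0.5, (k+1)·0.5) Da anchored at zero (the anchoring is a
convention; nothing in the data fixes it), keeping the intensity-weighted
mean m/z per bin so that rule conditions can be reported at exact m/z
(0.1 Da precision) rather than as bin indices. No low-mass cutoff is
applied, and precursor-region peaks are retained — losses from the intact
ion (e.g. M−78) are legitimate features.

Ratio features are formed between all ordered pairs of bins whose mean
normalized value on the *training* spectra is ≥ 0.01 (eligibility on
training only, to avoid leakage). Zero denominators are floored at
ε = 1e-4, keeping ratios finite and monotone.

## Trees, depth selection, and rules

The tree learner is written from scratch: exhaustive search over every
feature and every midpoint between consecutive distinct values, choosing
the split that maximizes information gain IG = H(parent) − Σ (n_c/n)
H(child) with H the Shannon entropy in bits. Ties in gain (within 1e-12)
break toward the lower feature index, then the lower threshold; samples
equal to a threshold go left; leaf predictions break count ties toward the
lexicographically smallest label. Training is therefore fully
deterministic. min_leaf defaults to 5 — a deliberate floor above the
library-default 1, preventing singleton leaves whose "100% confidence"
would be noise; the config echoes this deviation in run logs.

Depth is the only tuned hyperparameter, selected on the validation split
from candidates 1–4 by macro-averaged per-class accuracy under a
**one-standard-error rule**: the smallest depth whose validation score is
within one binomial standard error (√(p(1−p)/n_val)) of the best is
chosen. On a few hundred validation spectra, per-depth accuracy
differences of less than one SE are chance; a strict argmax chases them,
appending noise conditions to decision paths and needlessly cutting rule
coverage. The 1-SE rule is the standard parsimony device for tree models
and matches the package's goal of small, interpretable rule sets; plain
argmax remains available (`one_se=False`).

For each class, every root-to-leaf path predicting it is a candidate
rule; the path maximizing confidence × coverage on the held-out test split
is kept. Rules matching no test spectrum keep an undefined confidence and
are flagged `unvalidated` rather than dropped; rules under 60%
confidence or coverage are flagged `low-performance` but retained for
audit. Rule bins are mapped back to exact m/z via training-set offsets and
annotated with candidate fragments of the group's structures (tolerance
±0.2 Da, suited to unit-resolution ion-trap data).

### Topology-then-isomer hierarchy

A mass group (all spectra whose labeled composition's theoretical [M−H]⁻
falls within ±0.5 Da of a common value) may span several topologies
(residue connectivity with linkage positions erased). When it does *and*
at least one topology holds more than one isomer, a topology tree is
trained first and separate isomer trees per topology after; when every
topology holds exactly one isomer, topology classification already decides
the isomer, so a single flat tree is trained — a hierarchy would duplicate
it. A topology with a single isomer receives an empty-condition rule
recording its test-set purity ("implied by topology").

The hierarchy helps through two mechanisms: conditional thresholds (the
same feature can cut differently per topology) and, more decisively,
feature eligibility — a fragment pair confined to one topology of a
three-topology group has its group-wide mean diluted ~3×, which can push
it under the 1% ratio-eligibility floor for a flat model while it clears
the floor within its own topology's training subset. The three-topology
synthetic fixture is built around exactly this regime, and the acceptance
suite checks the hierarchy's held-out accuracy is at least that of a flat
tree of equal total depth.

## Splitting

Each classification task is split 70/20/10 into train/validation/test at
the granularity of whole provenance keys (dataset_id, filename) — an
experiment never straddles splits, so test metrics measure generalization
across experimental set-ups, not within-run memorization. Assignment is
greedy: a seeding pass gives every class one key in every split (scarcest
classes first), filling proceeds largest-key-first into the split with the
largest remaining spectrum deficit, and a repair pass relocates keys if a
class is missing anywhere. Classes present in fewer than three keys are
rejected up front ("cannot guarantee presence in all splits"). The
procedure is a deterministic function of the seed and invariant to input
order (keys are sorted before the seeded shuffle). The 70/20/10 fractions
are targeted on spectrum counts while assigning whole keys, so realized
fractions deviate by up to a key's worth of spectra.

## Synthetic data

The generator emulates the statistical structure the learner exploits:
per-isomer characteristic peaks (Bernoulli presence × log-normal
intensity), shared backbone peaks, planted intensity-ratio pairs with
per-class log-normal ratio distributions, Poisson noise peaks at uniform
m/z, Gaussian m/z jitter (default SD 0.05 Da, small against the 0.5-Da
bins), and per-provenance-key systematic intensity scale factors
emulating inter-laboratory shifts. It is a pure function of (config,
seed).

The two packaged fixtures define the package's study conditions:

* **Planted-ratio fixture** — two HexNAc2 isomer alditols (GlcNAc-GalNAc
  vs GalNAc-GalNAc) at one precursor, separable by the intensity ratio of
  two planted peaks (class medians 0.4 vs 3.0, log-SD 0.35, straddling
  1.5); the numerator peak is present with probability 0.9 in both
  classes, and 5% of the low-ratio class draws its ratio from the
  high-ratio distribution (annotation noise). A recovered ratio rule for
  the high class therefore has expected coverage ≈ presence (0.9) and a
  confidence governed by the 0.9 × 0.05 contamination flow — both checked
  by the acceptance suite against binomial bounds, pooled over 20 seeds.
* **Three-topology fixture** — a Hex1HexNAc2dHex1-like group, 3 topologies
  × 2 linkage isomers, with per-topology marker peaks (p = 0.97) and
  per-topology diagnostic ratio pairs whose abundance is tuned so they are
  ratio-eligible within their topology but not group-wide (see above).

What the generator does **not** model: CID fragmentation physics,
chemically consistent fragment ladders, isotope envelopes, profile peak
shapes, retention time, or correlated annotation errors. Passing tests
therefore demonstrate that the pipeline recovers statistical structure of
the planted kind from realistic intensity noise and provenance structure —
not that real spectra contain such structure; that evidence belongs to the
source data the method was developed on.

## Numerical and reproducibility notes

* All tie-breaks (split search, leaf prediction, depth selection, rule
  selection, key assignment) are deterministic; reruns with the same
  inputs and seed are byte-identical apart from file timestamps.
* Rule-set JSON is schema-versioned, serialized with sorted keys; floats
  round-trip exactly via Python's repr-based JSON encoding.
* Base-peak normalization divides by the spectrum maximum. Rescaling a
  spectrum's raw intensities by a power of two is exact in IEEE-754
  arithmetic, so the whole pipeline is *bitwise* invariant to dyadic
  per-key scale factors; for arbitrary factors the division can differ in
  the last ulp, so invariance is exact in the semantic sense (same
  features, comparators, confidence/coverage; thresholds to ~1e-9). The
  test suite checks both forms.
* Problem sizes used by the test and acceptance suites (500 spectra per
  class × 20 seeds for rule recovery; 250 per class × 5 seeds for the
  hierarchy comparison; 50 small corpora for split integrity) were chosen
  so binomial tolerances are meaningful at desk scale.

## Known limitations

* The structure grammar covers the condensed dialect used for common
  O-glycans (branches in brackets, optional `-ol`, `Gal3S`-style
  sulfation); GlycoCT/WURCS import is out of scope.
* Domon–Costello branch letters are assigned per branching node from the
  canonical (heaviest-first) child order; deeply nested multi-branch
  naming is simplified and labels are not guaranteed unique across
  distinct cleavages of equal depth (catalog entries are keyed by label
  *and* m/z).
* Confidence estimates are empirical fractions with no shrinkage or
  calibration; small test splits give coarse values, and rules for rare
  isomers should be read together with their `n_test`.
* The greedy splitter guarantees disjointness and class presence, not
  optimal balance; with few, large provenance keys the realized fractions
  can deviate noticeably from 70/20/10.
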