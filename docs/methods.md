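# Methods

## Problem and scope

Microbial (type I) rhodopsins are seven-transmembrane photoreceptors that
bind retinal through a Schiff-base lysine in the seventh helix.  A small
set of pocket residues determines what a given rhodopsin can do: pump
protons, gate an ion channel, or act as a light sensor feeding a coupled
effector domain.  *Modular* rhodopsins carry such effector domains
(histidine kinase, response regulator, cyclase, and others) in the same
open reading frame.  modrhod implements the annotation workflow used to
characterise these proteins: topology validation, transfer of reference
residue numbering by alignment, rule-based classification from the residue
fingerprint, conservation tabulation, and distance-based phylogeny.  It
deliberately excludes database mining, external MSA tools, domain-
architecture services, interaction networks, maximum-likelihood tree
verification, and any spectroscopic modelling.

## Topology validation

Hydropathy is the Kyte–Doolittle scale; the per-residue score is the mean
over an odd window (default 19, the canonical transmembrane setting)
centred on the residue.  At the termini the window shrinks rather than
leaving scores undefined, so short tails are still scored.  Helices are
maximal runs with score ≥ threshold (default 1.6, dimensionless KD units);
runs separated by at most `max_gap` (default 3) sub-threshold residues are
merged, absorbing the gap, and merged runs shorter than `min_len` (default
15 residues) are discarded.  A candidate validates iff exactly seven
helices are found and at least one lysine lies inside the seventh.  The
original analysis does not state how its helices were delimited, so these
are free, overridable parameters of this package, not claims taken from
elsewhere.  Raising the threshold can only shrink or drop runs, so total
helix coverage is monotone non-increasing in the threshold (a property the
tests check).

With unknown residue X scoring 0, an X-rich sequence will under-segment;
this is intended conservative behaviour.

## Reference position mapping

Published key positions are numbered "with respect to" a reference protein
(BR, ChR2, green proteorhodopsin).  modrhod transfers that numbering by
*pairwise* global alignment of each query to the reference scaffold —
Needleman–Wunsch under BLOSUM62 with affine penalties, a length-L gap
costing `open + (L-1)·extend` with open 10 and extend 0.5, the de-facto
protein defaults (no parameters are published for the original multiple
alignment).  Pairwise projection replaces the original Clustal multiple
alignment: it removes the external-tool dependency while preserving the
numbering semantics, at the cost of ignoring information from other family
members when placing gaps.  Alignment is delegated to Biopython's
`PairwiseAligner`; its first-reported optimum is deterministic, and the
test suite checks optimality against an exhaustive enumeration of all
alignments for short pairs.  A key position whose alignment column is
gapped in the query maps to an explicit GAP with no coordinate; mapped
coordinates are 1-based, as in the published subscript notation.

## Classification rules

* **Channel competence** (ChR2 numbering): proton acceptor 253 ∈ {D, E},
  proton donor 156 = D, DC-gate 128 = C, stabilising arginine 120 = R,
  retinal attachment 257 = K.  The acceptor admits both D and E because the
  reference protein itself is described with a glutamate acceptor while
  tables print D.
* **Pump competence** (BR numbering): acceptor 85 ∈ {D, E}, donor 96 = D,
  counterion 212 = D, attachment 216 = K.  Positions 89, 90 and the
  proton-release pair 194/204 are recorded as per-rule evidence but do not
  gate the call: the single genuinely pump-competent modular entry (AsRh4)
  carries Gly at 194, so gating on proton release would contradict its
  uniqueness.
* **Non-retinylidene**: any entry whose attachment role is not K, since no
  retinylidene chromophore can form.  Everything else failing a gate is
  sensory/atypical.
* **Spectral tuning** (proteorhodopsin 105): nonpolar
  {A,V,L,I,M,F,W,P,G,C} → green, polar-uncharged {S,T,N,Q,Y} → blue,
  charged {D,E,H,K,R} → unassigned; gaps and missing cells are unscored.
  The published comparison only exemplifies L/I/M → green, Q → blue and
  D → unknown; the partition extends those examples consistently and can
  be overridden.
* **Cyclase activity**: class-III nucleotidyl cyclase consensus — two
  metal-binding aspartates, a substrate-specifying residue in {E, K}, and a
  transition-state stabiliser in {N, R}; any miss is a degenerate cyclase,
  and entries without a cyclase domain are not applicable.  The published
  figure marks these residues by arrowheads without printing a residue
  table, so the packaged cyclase table is a *synthetic* stand-in
  (`cyclase_synthetic.tsv`) encoding the consensus, with the two known
  degenerate entries (Cop5, Vop5) lacking all three residue groups.

Conservation counts run over modular (non-reference) entries only; a table
cell printed blank is stored as MISSING, stays in the denominator and never
matches a residue set.

## Packaged residue tables

The fixtures transcribe the published tables verbatim, with the subscript
coordinates kept as separate integer columns.  Grouped row labels
(`GtRh2/3`, `Cop9-10`, `BgRh1/2`) denote multiple proteins sharing one
residue row and are expanded to one entry per numeral, yielding 46 modular
entries from the 43 printed rows — the expansion required to reproduce the
printed conservation counts (14 Asp/Glu and 17 Gln at 85, 6 Asn at 212, 25
Glu at 204, 46 retinal lysines).  The accompanying prose speaks of 47
modular rhodopsins, 43 Ser/Thr at 89 and 4 Asp at 194, which the printed
table does not reproduce (46, 43 and 3 respectively); the package follows
the printed table and reports only table-reproducible counts.  The
spectral table lists GpRh3 in two rows with different residues; the loader
keeps the assignment from its sensory-family group row (methionine) and
flags the duplicate in row metadata — both candidate residues are nonpolar,
so the spectral call is unaffected.  Fixture files are checksummed
(SHA-256) and verified on access.

## Phylogeny

Distances are p-distances (mismatches over pairwise non-gap columns) by
default, with a Poisson-corrected option −ln(1−p); a saturated pair
(p ≥ 1) is an error rather than an infinity.  Neighbor joining follows the
Saitou–Nei agglomeration, breaking Q-criterion ties toward the lowest
index pair for determinism; a negative branch length is clamped to zero
with the excess moved to its sister branch, which leaves the tree's path
metric unchanged.  The final three lineages are joined in a trifurcation
with closed-form branch lengths, and the result is an unrooted dendropy
tree.  On exactly additive matrices the output's path-length matrix
reproduces the input to floating-point precision; an independent NJ
implementation (scikit-bio) is used as a topology cross-check in tests.
Bootstrap resamples alignment columns with replacement, rebuilds the tree
per replicate under the same namespace, and annotates each internal
bipartition of the full-data tree with its replicate frequency × 100;
supports are mapped by bipartition identity, not node order.  The
published analysis used 1000 replicates; the CLI default is parameterised
and the tests use 20–200 replicates, which is ample for the synthetic
alignments they score.

## Synthetic data

The generators emulate the structure the pipeline assumes.  Scaffolds
alternate hydrophilic loops (alphabet {D,E,N,Q,K,R,S,T,G,H}, default
length 8) with hydrophobic helices (alphabet {A,V,L,I,F,M}, default length
30).  The helix length leaves margin over the detector's `min_len`: the
window-19 mean erodes roughly five residues from each helix end, so a
30-residue helix yields a ≈20-residue super-threshold run even with one or
two planted polar key residues inside it.  Key positions sit at fixed
helix-interior offsets (≥ 7 from helix edges; the attachment lysine at the
centre of the last helix) so that smoothing cannot detach them from their
helix.  Variants plant specified residues at the key coordinates and apply
background substitutions elsewhere at a configurable rate (≤ 0.2),
restricted to the same hydrophobicity class so topology is preserved.
Families evolve along a given tree under a uniform replacement model: each
site substitutes on each branch with probability rate × branch length,
replacement uniform over the other 19 residues — no gamma rate variation,
no empirical exchangeabilities, no indels.  Every generator takes an
explicit seed and is a pure function of (parameters, seed).

Because the toy sequences are clean — hydrophobicity-pure helices, no
indels, i.i.d. substitutions — passing the recovery tests demonstrates the
machinery is self-consistent, not that the default thresholds are optimal
for real membrane proteins.

## Problem sizes in tests and the reproduction script

The property experiments use 200 scaffold replicates for detection
recovery, 200 planted variants for pipeline closure, 100 random 4–8-taxon
trees for NJ additivity, 60 random short pairs (combined length ≤ 12) for
brute-force alignment equivalence, and 50 simulated 8-taxon families for
topology recovery; these sizes give stable rates while keeping the whole
suite and the reproduction script in the seconds range.

## Known limitations

* Hydropathy segmentation is a deliberately simple detector; real
  rhodopsins with marginal helices (or signal peptides) may need tuned
  thresholds, and no orientation prediction is attempted.
* Pairwise projection can misplace key positions when a query is highly
  diverged from the scaffold; the original multiple-alignment context is
  not recovered.
* Reference scaffolds for real use (BR, ChR2, GPR sequences) must be
  supplied by the user; the package does not redistribute them.
* The cyclase residue table is a synthetic consensus, not a transcription.
* The spectral rule is a binary polarity heuristic; it does not predict
  absorbance maxima.
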