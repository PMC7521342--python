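# Methods

## The assembly-line model

The core object is a linear acyl chain tethered as a thioester, with
carbons numbered from the carbonyl carbon C1 and double bonds written as
locant/geometry pairs (Δn, E/Z; Δn is the bond between Cn and Cn+1). A
chain also carries a transient β-carbon state — `keto` right after
condensation, `hydroxyl` after ketoreduction, `saturated` once tailoring
is complete — enforced as a state machine: each elementary step checks its
precondition and raises otherwise, so illegal domain orders cannot be
simulated silently.

Elementary steps per module cycle:

1. **Condensation** (KS/AT/ACP): chain grows by the extender's carbon
   count (default 2, malonyl after decarboxylation), every existing locant
   shifts up by the same amount, β becomes keto. Geometries are untouched.
2. **Ketoreduction** (KR): keto → hydroxyl.
3. **Dehydration** (DH): hydroxyl → a new Δ2 bond, β saturated. The
   geometry is Z if the previous module passed down an E Δ2 bond,
   otherwise E. This covers the first module (no predecessor → E) and any
   module following a δ-module (predecessor retained nothing → E). The
   behaviour after a retained Z bond is not constrained by the chemistry
   we model; defaulting to E is the minimal closure of the rule and is the
   documented assumption.
4. **Enoyl reduction** (ER): removes the Δ2 bond.

Module classes are derived from domain sets: γ = {KR, DH}, δ =
{KR, DH, ER}. Domain sets with DH but no KR, or ER but no DH, are
rejected. Classes that would leave a β-keto or β-hydroxyl group in the
product (no reductive loop, or KR alone) are accepted by the type system
but refused by the simulator unless `allow_extended=True`, because their
downstream locant-shifting behaviour is undefined in this model; with the
flag, the chain is left in its partial state and a subsequent condensation
fails its precondition, which is the honest propagation of that gap.

Offloading requires a fully tailored chain and produces either the free
acid or, given an amine token, the N-alkyl amide. Thioesterase substrate
selectivity is not modelled: offloading always succeeds on a tailored
chain.

**SMILES.** Chains render to isomeric SMILES written C1→Cn with
directional single-bond marks flanking each C=C (same mark = trans,
flipped = cis, consistent for conjugated runs because the shared single
bond is reused); canonicalization is delegated to RDKit, and structure
equality means canonical-string equality. The affinin amide canonicalizes
identically to an independently hand-written reference SMILES (test
`test_offload_affinin_smiles_matches_reference_structure`).

**Retrobiosynthesis.** `infer_architecture` enumerates every module-class
sequence of the length fixed by carbon arithmetic ((target − starter) /
extender, with parity errors raised) and keeps the sequences whose forward
simulation reproduces the target exactly. This is exhaustive over
|classes|^m and is feasible for any chain a plant alkamide plausibly has
(m ≤ 8 → ≤ 256 simulations).

## Synthetic data

The generators emulate the comparative study design rather than any real
dataset, and every generator is a pure function of its config and seed
(seeds are combined with per-generator offsets through
`numpy.random.default_rng([seed, k])`).

* **Counts.** Per gene, a log-normal baseline mean (log-mean 4.6 ≈ median
  100 counts, log-sd 1.0 — a typical mid-depth bulk RNA-seq spread); 100
  of 2,000 genes planted at log2FC = 3 in the producer-root group (the
  screen's published thresholds sit at log2FC 2, so planted effects are
  detectable but not trivial); negative-binomial sampling with common
  dispersion φ = 0.1 (variance μ + φμ²; Poisson below φ = 1e−12);
  per-sample depth factors uniform in ±30% to force normalization; 4
  groups × 2 replicates. The simulator records its generative depth
  factors as the library sizes: realized column sums additionally absorb
  the planted composition shift, which is a normalization artifact a real
  pipeline corrects upstream. The screen defaults to column sums when no
  library sizes are supplied.
* **Transcripts.** 600-nt random sequences; planted genes embed the
  reverse-translated motif of their assigned domain (one fixed codon per
  amino acid — codon usage is irrelevant to protein-level scanning) at a
  random position, on a random strand. The domain motifs are short
  synthetic consensus blocks (42–52 aa) bundled in
  `alkapks.domain_profiles`; they are labelled synthetic and carry no
  biological information, which is exactly what makes false-positive
  calibration clean.
* **KS clades.** Four clade ancestors derive from one random root by
  per-site substitution at divergence 0.5, keeping between-clade
  p-distances (~0.6–0.7) well below the saturation cap of the distance
  correction; clade members and queries then derive from their ancestor at
  per-site rate 0.15. The simulation is star-shaped within clades — no
  rate heterogeneity, no indels — so passing tests show the placement
  machinery is correct, not that it would resolve hard real phylogenies.
* **qPCR.** Ct tables encode planted expression ratios as
  `Ct = base − log2(ratio)` plus Gaussian technical noise, with a flat
  reference gene, 3 biological × 3 technical replicates.

What the generators deliberately omit: read-level artifacts, isoforms, GC
bias, batch effects, gene-length/expression coupling, alignment errors.
Recovery results on synthetic data are therefore statements about the
statistical machinery under its own assumptions.

## The expression screen

FPKM follows counts × 10⁹ / (length × library size). The test conditions
on each gene's total after equalizing library sizes (scaling every sample
to the geometric-mean size and rounding): if sample counts are NB(μ, φ),
group sums are NB with sizes n_A/φ and n_B/φ sharing the success
probability, so the group-A sum given the total t is beta-binomial(t,
n_A/φ, n_B/φ) — free of μ. Two-sided p-values accumulate every outcome
whose probability does not exceed the observed one (ties counted once,
with a 1e−10 log-slack so exact mirror ties are not lost to rounding). At
φ = 0 this is the binomial split test, verified against full rational
enumeration. The common dispersion is a method-of-moments estimate:
per-gene pooled within-group variance s² and grand mean m on scaled
counts give (s² − m)/m², and the median over genes (clipped at 0) is
robust to the planted minority. BH adjustment is delegated to statsmodels
behind `bh_adjust`. Calls: up iff q ≤ α and log2FC ≥ τ, down iff q ≤ α
and log2FC ≤ −τ (α = 0.05, τ = 2 by default; the fold-change threshold is
applied symmetrically); log2FC uses a 0.5 pseudocount for display, the
test uses the counts themselves.

Measured behaviour at the defaults (fixed seeds, reported by the tests
and the pipeline report, not asserted here): recall of planted genes
0.97–1.00, empirical FDR 0, null raw-p rate ≈ 0.065.

## Domain scanning

Profiles are ungapped log-odds matrices, log2(((count + pc·bg)/(n +
pc))/bg), built from the bundled seed alignments (8 rows, ~8% mutated
copies of the consensus) against a uniform background. Scanning slides
the profile over each of the six frames (stops render `*`, N-codons `X`;
unknown residues contribute 0 bits) and keeps the best window, leftmost on
ties. Thresholds are calibrated empirically per profile at a 5%
false-positive rate on the unit actually scanned — the best window across
all six frames of a random 600-nt transcript (500 transcripts, fixed
seed); a per-protein calibration (95th percentile of best-window scores on
1,000 random 300-aa proteins) is available separately. Coordinates are
0-based half-open internally. The composite "oxide reductase" (OR) label
covers the KR and ER profiles in reports. Candidates are genes called up
in the producer contrast that carry at least one hit.

## KS phylogenetics

Distances are proportions of differing sites under pairwise deletion of
gap/X columns, Poisson-corrected as d = −ln(1 − p) and capped (with a
warning) at p = 0.95 where the correction diverges. Neighbor joining is
delegated to scikit-bio (negative branch lengths clamped to zero) and is
verified to recover random additive 8-taxon matrices exactly; bootstrap
support for each internal bipartition is the percentage of
column-resampled replicates containing it. Clade assignment works on
unrooted bipartitions, so it cannot depend on rooting: a query takes a
reference clade's label when some edge separates the query plus that
entire clade (other queries allowed) from every other reference, choosing
the smallest such side and reporting that edge's support; queries that
group with no complete clade fall back to the nearest reference by
distance with support 0 and lexicographic tie-breaking. Pairwise global
alignment (Needleman–Wunsch, linear gap penalty −8, BLOSUM62, ties
diagonal > up > left) is provided for unaligned pairs; progressive
multiple alignment is out of scope and the generators emit aligned blocks.

## qPCR quantification

Technical replicates are averaged before biological ones (the standard
ΔΔCt order). ΔCt = mean Ct(target) − mean Ct(reference) per sample; ΔΔCt
subtracts the calibrator group's mean ΔCt; RQ = 2^−ΔΔCt, so the
calibrator's RQ is 1 by construction and any global Ct shift cancels.
Amplification efficiency is fixed at 2; efficiency correction from
standard curves is out of scope. The default calibrator is the
non-producer species' leaves, the tissue most distant from the producer
root.

## Problem sizes and determinism

Defaults are chosen so the full suite runs in well under a minute and the
complete screen in ~2 minutes on one core: 2,000 genes (5,000 for null
calibration), 500-transcript threshold calibration, 20 reference + 40
query KS sequences of 120 aa with 200 bootstrap replicates, exhaustive
architecture checks to six modules. Every stochastic component takes an
explicit seed; the pipeline report embeds its config hash and seed, and
rerunning a configuration reproduces the report byte for byte.

## Known limitations

* The DH geometry rule after a retained Z bond is an assumption (default
  E); chains whose correct geometry depends on that case would need the
  rule revisited.
* Architecture search answers the combinatorial question only; it does
  not model how module counts are selected in vivo for longer (C12–C18)
  chains.
* Acetylenic (triple) bonds, odd-carbon ω-methyl-acetylenic chains and
  bornyl esters are outside the chain grammar; the amine moiety is an
  opaque token.
* The screen implements a two-group exact test with common dispersion —
  no GLM designs, TMM/quantile normalization, or per-gene dispersion
  shrinkage.
* Profiles are ungapped PSSMs, not profile HMMs; domains split across
  frames or interrupted by indels would be missed.
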