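# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinates, isoforms and promoters

All genome coordinates are 1-based inclusive (GFF3 native); intervals
are stored sorted ascending regardless of strand. When a locus has
several mRNAs the one with the longest total CDS is kept for all
downstream stages — the standard convention in gene-family surveys,
where one representative protein per locus is profiled and aligned.
The "promoter" is defined as the 2000 bp immediately 5' of the CDS
start (the ATG), strand-aware. Measuring from the translation start
rather than a transcription start is deliberate: annotation sets for
non-model genomes frequently lack reliable 5' UTRs, and upstream-of-ATG
is what promoter-scanning practice in family surveys uses.

## Member identification

The primary interface consumes the tabular outputs of hmmsearch
(`--domtblout`; the per-domain independent E-value is used) and BLASTP
(`-outfmt 6`). Candidates pass at E ≤ 1e-10 per source; evidence
sources are combined by union by default (a candidate pool merged
before manual domain confirmation), with intersection available.
Isoform redundancy is removed by mapping proteins to loci and keeping
the longest.

So the pipeline can run with no external search tool, the module also
ships a PSSM scanner: per-column log2-odds
`log2((f + pc·bg) / ((1+pc)·bg))` built from a seed alignment (columns
with > 50% gaps dropped; default pseudocount 1, uniform background),
scanned over every window, overlapping hits greedily merged. E-values
come from a Gumbel location/scale fit to the maximum window scores of
residue-shuffled input sequences (1000 shuffles by default, seeded) —
a Karlin–Altschul-style calibration that is an acknowledged
approximation: it models the per-sequence maximum, is
composition-dependent, and is not comparable across profiles. It is
adequate for the planted-domain recovery setting it serves.

## Physicochemical statistics

* Molecular weight: sum of average residue masses plus one water
  (18.01524 Da); `X` contributes the mean residue mass.
* pI: root of the Henderson–Hasselbalch net-charge function over the
  N-terminus, C-terminus and the D/E/C/Y/H/K/R side chains, with the
  ExPASy/Bjellqvist pKa set (terminal pKa keyed on the terminal
  residues; the EMBOSS set is selectable). The charge is strictly
  decreasing in pH so bisection on [0, 14] converges to the unique
  root; default tolerance 1e-3 pH units. Note that because the
  Bjellqvist set keys terminal pKa on the terminal residues, pI is the
  one statistic other than the instability index that is not strictly
  permutation-invariant.
* Instability index: (10/L) Σ DIWV(x_i, x_{i+1}) over the Guruprasad
  dipeptide weights (> 40 = "unstable" by the ProtParam convention; the
  class is exposed even though hydropathy, not stability, is the
  dichotomy a family table usually reports).
* GRAVY: mean Kyte–Doolittle score, `X` excluded from numerator and
  denominator; hydrophilic iff GRAVY < 0 strictly — the only reading
  consistent with an even 9/9 split around values like −0.007.
* Aliphatic index: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole
  percent.

Constant tables (residue masses, Kyte–Doolittle, DIWV) are taken from
Biopython's data modules; the statistics themselves are implemented
here and cross-checked against Biopython's ProteinAnalysis in tests.

## Duplicate pairs, Ka/Ks and dating

Candidate pairs come from Needleman–Wunsch global protein alignment
(BLOSUM62, gap open −10, extend −0.5). Identity is computed over
aligned (both non-gap) columns; coverage is aligned columns divided by
the longer sequence's length. Both thresholds (identity > 85%,
coverage > 0.75) are strict inequalities. Identity is computed at the
protein level — the self-consistent choice when the threshold is an
amino-acid identity.

Tandem vs segmental: a pair is tandem only on the same chromosome with
either ≤ 100 kb between the gene spans or ≤ 5 intervening annotated
genes; otherwise segmental. The window and gene-count defaults are
configurable; they encode the usual "closely spaced copies" notion
rather than any synteny inference.

Ka/Ks is Nei–Gojobori (1986) on a protein-guided codon alignment
(gapped columns dropped). Site counts follow NG's convention: per codon
position, the synonymous fraction is taken over the non-stop
single-base changes (nonsense mutations are eliminated), and N + S = 3
per codon, averaged over the two sequences. Differences average over
all orderings of the observed per-codon changes with equal weight,
excluding pathways through stop codons (if every pathway is blocked,
all are used with stop-entering steps counted as nonsynonymous — a
degenerate case not reachable from stop-free sequences one substitution
at a time). Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is applied
to pN and pS separately; p ≥ 3/4 is reported as saturated (None)
rather than extrapolated.

Dating uses T = Ks/(2λ) with λ = 1.5e-8 synonymous substitutions per
site per year, reported in Mya; pairs with Ks > 2.0 are not dated, to
avoid saturation artifacts. Published per-pair Ka/Ks tables are treated
as *inputs* to the ratio/selection/dating operations in the worked
examples: the exact algorithm and version behind any given published
table is generally unknowable, so printed Ka and Ks are not targets the
estimator is tuned to.

## Promoter scanning

Matching is exact IUPAC comparison of published consensus strings on
both strands; minus-strand hits are reported at plus-strand coordinates.
`N` in a promoter matches nothing. This deliberately avoids PlantCARE's
matrix models: presence/absence and position claims are served by
deterministic, auditable exact matching, at the cost of missing
degenerate variants a profile model would score. Categories follow the
four functional groups a promoter survey reports (light, hormone,
stress, growth/metabolic); the drought flag is ≥ 1 ABRE or MBS hit.
The per-window match probability of a consensus is analytic
(product of code-set sizes / 4), which the background-rate test checks
against simulation.

## Phylogeny and classes

Distances are Poisson-corrected protein distances d = −ln(1 − p) with p
over shared non-gap columns. The tree is Saitou–Nei neighbor joining
with negative branch lengths clamped to zero and Q-ties broken by the
smallest (cluster label, cluster label) pair, labels being each
cluster's smallest leaf id — NJ is therefore a deterministic function
of the matrix. Bootstrap resamples alignment columns with replacement;
support of an edge is the percentage of replicate trees containing the
same leaf bipartition (replicates whose resampled matrix saturates are
counted as non-supporting). Classes are formed by cutting the k−1
longest internal edges and numbering the resulting leaf components by
decreasing size; k = 1 and k = leaf count short-circuit to the obvious
answers. A maximum-likelihood tree under an empirical substitution
model would be the heavyweight alternative; for a family of ~18
members, distance NJ reproduces the class structure, which is the
target of this stage — branch lengths are not interpreted.

MSA construction is out of scope: the module consumes an existing
alignment (the generator emits equal-length proteins whose trivial
alignment is exact; real use can import any aligned FASTA).

## Expression and phenotype formulas

log2 transform uses a +1 pseudocount (zeros are routine in FPKM
matrices; the pseudocount is configurable). qPCR quantification is
Livak 2^-ddCt with dCt = mean target Ct − mean reference Ct per sample,
anchored at a calibrator sample; this assumes ~100% amplification
efficiency for both genes. Survival rate and leaf RWC are the standard
percent formulas. Heatmap rendering (diverging palette, rows ordered by
tree class) is cosmetic and only smoke-tested.

## Synthetic data: what it emulates, and what it does not

The genome generator plants `n_members` family genes (default 18) on 7
chromosomes among 50 decoys. Members share a 60-residue domain
consensus, mutated ~5% per clade and ~5% per member, inside
clade-specific flanks (members diverge ~25% from their clade ancestor's
flanks); clade sizes default to 14/1/3. Two duplicate pairs are created
by evolving a common ancestral CDS at known (Ks, ω) = (0.05, 0.3) and
(0.10, 0.3), so pair identity (~94–98%) clears the duplicate threshold
while all other member pairs (~60–70% identity) stay well below it.
Exon counts are drawn from 1..34 (intron counts 0..33), introns are
60–200 bp, and every member promoter carries planted ABRE and MBS
elements at recorded positions; the random promoter background is
re-randomized wherever it would spuriously match a planted element
type, so scans recover exactly the planted truth. Chromosomes are
packed gene-block by gene-block (promoter + gene body + gap) rather
than placed at random offsets, which guarantees non-overlap and makes
byte-identical determinism trivial.

The codon-evolution model is deliberately the estimator's own model:
uniform single-base proposals (Jukes–Cantor-like), stop-creating
proposals rejected, nonsynonymous proposals thinned by ω (synonymous by
1/ω when ω > 1), with each lineage receiving a Poisson(Ks/2 × S)
synonymous-event budget counted against the ancestor's NG synonymous
sites. Recovery tests therefore probe the estimator — site counting,
pathway averaging, JC correction — not model mismatch. The residual
worst-case bias (mean Ks ~7–9% low at Ks = 0.5, ω = 2, driven by
pathway averaging over multi-hit codons) is the estimator's, and is the
reason recovery tolerances are 10% (Ks) and 15% (ω).

None of the generators attempt real maize sequence composition, codon
usage bias, splice-site motifs, transposon content, or realistic qPCR
efficiencies. Passing the end-to-end tests shows the pipeline's logic
is correct under its stated assumptions; it does not show that a 60-row
PSSM scan matches HMMER sensitivity on diverged real families, nor that
exact IUPAC matching reproduces PlantCARE output on real promoters.

Expression/phenotype tables: FPKM values are log-normal around per-gene
means; Ct replicates are Gaussian (SD 0.15 cycles) around a mean offset
by −log2(fold) from the planted fold change; water-stress survival
defaults to 10/16, 9/16 and 3/16 across a tolerant/intermediate/
sensitive line trio, with fresh weights back-computed from a survival-
linked RWC trajectory.

## Problem sizes

The recovery grid uses 500-codon ancestors, 50 replicates per (Ks, ω)
condition; the end-to-end checks use the default 18-member/50-decoy
genome, 300 calibration shuffles, and 1000 bootstrap replicates. These
sizes give stable means (Monte-Carlo SE well under the tolerances)
while keeping the whole suite fast on a laptop.

## Known limitations

* The PSSM scanner's E-values are calibrated per input set and are not
  portable numbers; use them for ranking/thresholding within a run.
* NG86 underestimates at high divergence; pairs near Ks ≈ 2 are close
  to the dating cutoff for good reason.
* Tandem/segmental classification uses geometry only — no collinearity
  or synteny-block evidence.
* IUPAC consensus scanning has no notion of binding affinity; counts
  are motif occurrences, not predicted occupancy.
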