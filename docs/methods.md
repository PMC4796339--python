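# Methods

This note documents the models and procedures implemented in `braincoex`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that affect
results.

## Gene-based association

Each gene's window is the closed interval `[start − flank, end + flank]`
in 1-based inclusive coordinates, flank 15 kb by default (the distance
within which most expression-modifying variants fall).  A SNP may belong
to several overlapping windows; genes with no SNPs get an undefined gene
P and are excluded from the Bonferroni denominator.

The gene statistic is an extended Simes combination.  With ordered SNP
P-values p(1) ≤ … ≤ p(M),

    P_gene = min_j  Me(M) · p(j) / Me(j),

where Me(j) is the effective number of independent tests among the j most
significant SNPs: Me = j − Σ (λ − 1) over eigenvalues λ > 1 of their
P-value correlation matrix.  For an identity correlation this is exactly
the Simes statistic; for perfect correlation it is min p.  Ties in p are
broken by genomic position, so the reported top SNP is deterministic.
P_gene ≥ min p always, and P_gene ≤ M·p(1) (the Bonferroni bound).

**P-value correlation transform.**  Association-test P-values are less
correlated than the underlying genotypes: for two-sided tests of
bivariate-normal z-scores, corr(P_i, P_j) ≈ 0.17 at r = 0.5 and ≈ 0.70 at
r = 0.9.  The default transform (`"gaussian"`) evaluates this correlation
exactly by folded Gauss–Legendre quadrature over the positive quadrant
(the |z| kink makes Gauss–Hermite converge poorly), tabulated once per
process on a 201-point grid in |r| and interpolated; the table matches a
2-million-sample Monte-Carlo estimate to four decimals.  The cruder
`ρ = |r|` transform is kept as an option for comparison with
implementations that use it, but it overstates P-value correlation and
inflates the null tail (measured fraction of null genes with P < 0.05
around 0.06–0.07 under exchangeable LD blocks with r = 0.3–0.8, versus
0.046–0.052 for the Gaussian transform); the Gaussian transform is
therefore the default.  Any callable r → ρ can be plugged in.

**Null distribution.**  Under within-gene independence the gene P is
exactly Uniform(0, 1) (Simes equality), and the test suite verifies this
by Kolmogorov–Smirnov on 10,000 simulated null genes.  Under positive LD
any Simes-type statistic is conservative in the bulk of its distribution
even when its tail is calibrated — this is a property of the statistic,
not an implementation artifact — so under LD the suite asserts tail
calibration (fraction of null genes with P < 0.05 within three binomial
standard errors of 0.05) rather than bulk uniformity.

## Spatial co-expression

The biweight midcorrelation of two vectors median-centres them and
down-weights points by Tukey's biweight, w = (1 − u²)² for |u| < 1 with
u = (x − med) / (9·MAD), then correlates the weighted vectors.  The
constant 9 is the standard biweight tuning.  Degenerate cases: a vector
with MAD = 0 but non-constant falls back to unit weights on the
median-centred values (robust-correlation convention); truly constant
vectors have no defined correlation and raise.  Genes constant in any
donor are dropped from the whole panel with a warning before the matrix
is built.

Correlations are computed per donor across that donor's samples and
averaged element-wise over donors.  Because a per-donor additive offset
is constant across samples it cannot affect within-donor correlations;
averaging removes residual donor idiosyncrasy.  The per-donor
leave-one-out consistency score (correlation between one donor's
vectorised upper triangle and the mean of the others') is reported as QC
only and never filters data.

The full gene × gene matrix is held in memory; at the default synthetic
scale (≤ 5,000 genes, ~200 MB at float64 for 5,000) this is comfortable
on a laptop.  Larger panels are out of scope for this version (a
row-block streaming path is a known limitation, not yet implemented).
The matrix persists as a dense `.npy` plus a plain-text gene sidecar that
also records the donor count; the pair round-trips exactly, which the
byte-identical re-run guarantee relies on.

## Modules and enrichment

Agglomerative clustering uses distance 1 − bicor and complete linkage by
default, cut into k = 18 modules (the scale at which brain-wide
transcriptome panels typically resolve regional programs).  `select_cut`
scores any (linkage, k) grid by the minimum module enrichment P and
returns the argmin, ties broken toward smaller k then lexicographic
linkage, so module detection can be targeted at the phenotype rather than
at abstract cluster-quality indices.  Cluster labels are renumbered by
first appearance; SciPy's linkage is deterministic, making partitions
reproducible across runs and platforms.

Fisher tests are one-sided ("greater"): the question is whether a module
holds *more* candidates than expected.  A Benjamini–Hochberg column is
emitted for information, but module selection uses nominal P (five
modules at nominal P < 0.05 is the intended operating point, and the
LD-corrected test serves as the robustness check).

**LD-corrected Fisher.**  Neighbouring genes can share a top SNP or sit
in one LD block, so candidate counts can overstate the number of
independent signals.  Each cell of the 2×2 table is replaced by the
effective number of independent genes: the effective-number rule applied
to the LD correlation matrix of the cell members' top SNPs, computed per
chromosome (and per LD block, which is exact because the correlation
matrix is block-diagonal) and summed.  Effective counts are rounded to
the nearest integer, floored at 1 for non-empty cells; with mutually
independent top SNPs the corrected table equals the raw one exactly.
Rounding can move the corrected P by a factor comparable to one count in
the smallest cell; this sensitivity is visible by comparing `eff_*`
columns with the raw counts.

**Cell-type signatures.**  A gene is specific to a cell type iff its
RPKM there strictly exceeds 10× the mean RPKM of the other profiled
types.  With fold > 1 the rule can hold for at most one type, so
signatures are provably disjoint.  Enrichment of modules (or seed-network
local modules) against signatures is the same one-sided Fisher test.

**Worked-example universe.**  The four published worked examples shipped
in the tests and the acceptance script (neuron enrichment of two cortical
modules and one small module, oligodendrocyte enrichment of the
white-matter module) are recomputed from their printed 2×2 counts against
a universe of 22,458 genes — the size of the mouse brain cell-type
RNA-seq catalogue from which the signatures derive.  The four printed
P-values are mutually consistent only with a universe of that size (a
least-squares scan over the universe puts the joint optimum at ≈ 22,400),
not with the 19,972-gene human expression universe; with N = 22,458 all
four reproduce within ~1% on log10 P, and the residual is attributable
to the exact ortholog filtering of the original catalogue, which is not
recoverable from the printed numbers.

## Seed networks

A seed's local module is every gene with signed co-expression strictly
above the threshold (default 0.6 — high enough to keep only strong links
given that bicor is conservative, low enough that most seeds recruit
partners).  Strong negative correlations do not recruit by default
(`absolute=True` changes that).  The merged network draws an edge between
*every* pair of member nodes above threshold, not only seed–neighbour
pairs, so recruited genes interconnect and seeds can be joined by
indirect paths; a star topology is available by flag.  Raising the
threshold never adds nodes or edges (asserted over a grid in the tests).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Expression** — n_donors (default 3) matrices over one gene set;
  samples are allocated to labelled regions by fixed proportions (default
  four regions).  A gene in a planted module reads
  `region_mean + strength·f + ε`, with f a per-sample standard-normal
  latent factor shared within the module and donor, strength ∈ [0, 1]
  (default modules use 0.85), and ε Gaussian noise (sd 0.5).  Background
  genes are pure noise.  A per-(donor, gene) offset (sd 0.3) models donor
  level differences.  Defaults: 200 genes in five 40-gene modules,
  300 samples per donor.
* **GWAS** — z-scores drawn block-wise from exchangeable multivariate
  normals (default 2,000 SNPs; block sizes cycling 1/2/5/10 with r
  0/0.3/0.6/0.8, a crude stand-in for the mix of isolated SNPs and tight
  LD found in real panels).  For each associated gene the noncentrality
  (default 5) is added to the SNP nearest the gene midpoint within its
  window and propagated as r·δ to block partners.  P = 2Φ(−|z|); the
  returned LD reference carries the true block correlations.
* **RPKM** — i.i.d. log-normal(1, 1) across five cell types for
  non-specific genes; a designated specific gene first draws the other
  types and then sets its own type to fold × mean(others) × U(1.2, 5), so
  the strict tenfold rule holds by construction.

All three generators are deterministic functions of the seed, with named
substreams so the expression draw does not perturb the GWAS draw.

**What it does not emulate:** realistic human LD maps or allele
frequencies, genotype-level sampling, anatomically faithful region
geometry or sample autocorrelation, probe-level noise, batch effects, or
heavy-tailed expression noise.  Passing tests therefore demonstrate that
the machinery is correct and calibrated under its stated assumptions;
they do not certify performance on atlas-scale data, where module
structure is weaker and LD far more heterogeneous.

## Pipeline determinism

Every run writes its configuration verbatim (`run_config.yaml`), every
artifact's SHA-256, and the stage list into `manifest.json`; re-running
with an identical configuration (including output directory) reproduces
every file byte for byte.  Manifests deliberately contain no timestamps;
wall-times go to the structured stderr log only.  Exit codes: 0 success,
2 configuration error, 3 data error, 4 stage failure (the failing stage
is named, and artifacts from completed stages are retained).

## Problem sizes used in the checks

The shipped checks run at desk scale by design: uniformity of the null
gene statistic at 10,000 genes / 30,000 independent SNPs; tail
calibration at 4,000 genes / 12,000 SNPs in mixed LD blocks; module
false-positive rate over 500 label permutations of an 18-module,
2,000-gene partition; module recovery on the 200-gene default panel; and
detection of a planted GWAS-enriched module over 100 GWAS replicates at
noncentrality 5 (chosen so single-gene detection is near-certain and
module-level detection exercises the enrichment test rather than the
gene test).
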