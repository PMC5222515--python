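# Methods

## Herb–disease association

For a corpus of N articles of which K mention the disease, a herb with n
articles and k disease co-mentions is scored with the upper-tail
hypergeometric probability

    p = P(X ≥ k),   X ~ Hypergeometric(N, K, n),

a one-sided enrichment test of the herb–disease co-mention rate against
independence. Herbs with p ≤ α are selected; α defaults to 0.01 and no
multiplicity correction is applied across herbs (each herb is judged on
its own evidence; a Benjamini–Hochberg option exists behind
`adjust="bh"` for users who prefer family-wise control across a herb
panel).

Defaults for the corpus constants are N = 104 544 921 and K = 791 592,
the PubMed+CNKI totals of the packaged worked example; both are plain
config values.

Numerics: at N ≈ 10⁸, binomial coefficients are far outside float range,
so the tail is computed from log-gamma pmf terms with a suffix
log-sum-exp (`numpy.logaddexp.accumulate` over the reversed support).
This keeps the result accurate arbitrarily deep in the tail; the same
table is cached per (N, K, n) so scoring many herbs against one corpus
is O(1) per herb after the first. A feasible k is clamped to the
smallest positive float rather than underflowing to zero, so a strict
α = 0 never selects anything. The implementation is verified against
exact rational enumeration for all N ≤ 60 (|Δ| ≤ 1e−12) and against
`scipy.stats.hypergeom.sf` at moderate scale.

## ADME screening

Oral bioavailability (OB, percentage scale) is always an input — the
upstream OB predictor is a pretrained commercial-descriptor model that
is not reconstructible — and the screen applies the inclusive rule
OB ≥ ob_min (default 30).

Drug-likeness (DL) is the Tanimoto similarity between a compound's
8-descriptor vector and the component-wise mean (centroid) of a
reference drug collection, thresholded inclusively at dl_min = 0.18
(the reference collection's own average similarity). The descriptor
space of the original DL index is under-specified in the literature
this follows, so the default backend divides each component by the
reference set's per-component standard deviation before the similarity;
without that scaling the molecular-weight axis dominates the dot
product and the other seven descriptors are effectively ignored. A raw
(unscaled) backend is available for comparison. The packaged reference
table is a synthetic 200-drug stand-in generated from the published
group means/SDs (it is labelled synthetic in its filename); users with
a licensed drug collection can supply their own TSV.

Rescue is an explicit ID list in config — the auditable equivalent of
literature-justified inclusion of known actives that fail the numeric
thresholds. Rescue never changes scores; it only moves listed compounds
into the candidate set with reason code `rescued`.

Deglycosylation is record-level and best-effort: a SMARTS pattern for a
pyranose ring linked through an exocyclic anomeric oxygen identifies
O-glycosides; every glycosidic C–O bond is cleaved (the oxygen staying
with the aglycone, as in enzymatic hydrolysis), sugar fragments are
discarded, and the unique aglycones are emitted as `*_qt` records with
descriptors cleared for recomputation. N- and C-glycosides, furanose
sugars and ester glycosides are not detected; unparsable structures
pass through untouched with a warning.

## Consensus target acceptance

Interaction scores from two independent predictors are inputs. A pair
is accepted iff rf > 0.8 AND svm > 0.7 — strict inequalities, matching
the stated "greater than" rule — and, when a curated whitelist is
given, the target is on it. The predictors' published performance
(sensitivity 80%, specificity 93%, concordance 86%) describes the
upstream models and is context only; nothing here retrains them. The
83→33 target curation of the worked example is likewise not an
algorithm: it ships as the packaged 33-target whitelist.

## Networks and herb roles

Both networks are bipartite by construction. The compound–target
network keeps only compounds with ≥ 1 accepted target (dropped
compounds are reported by ID) and targets with ≥ 1 incident edge;
duplicate accepted pairs collapse to one edge with a warning. Degree is
the only centrality used.

Herb roles formalise a narrative classification: herbs are ranked by
(active-compound count, total degree) descending, ties broken by
herb_id and flagged. Rank 1 is *jun* (monarch); the next
⌈chen_fraction · (H−1)⌉ herbs are *chen* (minister); the rest are the
merged *zuo_shi* (assistant/guide) tier, which the tradition
distinguishes pharmacologically but no degree statistic can separate.
chen_fraction defaults to 0.35, giving the canonical 1 / 7 / 12 split
for a 20-herb formula. The fraction is applied to the H−1 non-monarch
herbs: this is the only reading consistent with both the 20-herb split
and a 3-herb example yielding 1/1/1.

## Descriptor comparison

Group summaries are arithmetic means and sample SDs (n−1). The
two-group comparison defaults to Welch's two-sample t-test per
descriptor — the compared groups have visibly unequal variances — with
a permutation test (difference of means, 10⁴ resamples) available both
as a config switch and as the validation oracle; the two agree within
Monte-Carlo error (|Δp| ≤ 0.02) on n = 50 synthetic cases. Significance
is reported as mutually exclusive tiers (ns, p<0.05, p<0.01) with no
correction across the eight descriptors, matching the starred-table
convention this reproduces. Identical samples are reported as p = 1;
two constant groups compare their constants.

An optional structure backend computes the eight descriptors from
SMILES with RDKit (Ertl TPSA, Wildman–Crippen logP as the lipophilicity
estimate, a hydrophilicity index from hydroxyl/amine counts); these
approximate, but do not reproduce, commercial descriptor software.

## Over-representation analysis

ORA reuses the association statistic: for a selection of n targets from
a universe of N genes and a term annotating K of them with overlap k,
p = P(X ≥ k). The EASE variant scores P(X ≥ k−1), the conservative
score of the DAVID service; which variant a given published analysis
used is often unstated, so both are exposed and `standard` is the
default. Terms are intersected with the universe before testing
(default universe: all genes in the GMT collection). Retention uses raw
p ≤ 0.05 — the stated rule of the workflow this implements — with BH
adjusted values reported alongside. Ties in p are broken by term_id, so
rankings are deterministic.

## Synthetic data

The default scenario mirrors the worked example's scale: 20 herbs, 1618
ingredients with joint OB/DL pass probability 150/1618 ≈ 0.0927, 33
targets, and degree tiers (1 herb at mean 12, 7 at 7.24, 12 at 6.74
accepted targets per compound). Ingredient counts per herb follow the
tiered weights 32 : 41/7 : 57/12 (the candidate shares of the monarch,
minister and assistant tiers in the worked example), so the monarch
herb leads on both ranking keys. Descriptors are drawn per component
from the published group means/SDs — Gaussian, counts rounded and
clipped at 0, MW/TPSA truncated at their floors — independently across
components; real descriptors are correlated (MW with RBN and nHAcc,
etc.), so passing tests demonstrate pipeline correctness, not realism
of any chemical model. OB/DL draws are a threshold-anchored mixture
(pass draws uniform above both cutoffs, failures uniform below, failure
mode uniform among ob/dl/both), which spans the filter boundaries but
does not imitate real OB/DL marginals. Gene sets are uniform draws from
the 33 targets padded with 300 background genes; one planted term
covers a configured fraction (default 1.0) of a designated selected
subset. Literature counts are Binomial(n, f·K/N) with per-herb
enrichment factor f (f = 1 is a calibrated null herb; f = 0 forces
k = 0; defaults f = 3, n = 50 000 per herb).

Seeding: one root integer drives `numpy.random.default_rng([stream,
seed])` with a fixed stream offset per generator, so each stage's draws
are reproducible independently of the others. No valid chemistry is
generated (SMILES are absent from synthetic records); deglycosylation
is tested on a small fixed pool of real glycoside structures instead.

Problem sizes used in the shipped tests were chosen for statistical
resolution: tier-mean recovery uses 1000 compounds per tier (standard
error ≈ 0.11 at mean 12, comfortably inside the ±0.5 check), the
association null calibration uses 10⁴ factor-1 herbs (binomial SE
≈ 0.001 around the nominal 0.01), and the role-recovery simulation
uses 100 replicates at 1000 compounds per herb.

## Degenerate inputs and tie-breaks

Empty herb lists return empty results (not an error); an empty gene-set
collection yields an empty T-P network; a single-herb formula is its
own monarch. k ≤ 0 gives p = 1 exactly; k > min(n, K) is a domain
error. All-equal herb aggregates are ranked lexicographically and every
assignment is flagged tied. Zero-variance descriptor components in the
reference set pass through the DL scaling unscaled.

## Known limitations

- OB values and interaction scores are consumed, never predicted; the
  pipeline's biological validity is bounded by whatever produced them.
- The DL backend is a deterministic descriptor-space similarity;
  fingerprint-based drug-likeness would need a structure for every
  compound and is not implemented.
- Deglycosylation handles pyranose O-glycosides only.
- Jun-Chen-Zuo-Shi tiering is an explicit, configurable formalisation
  of a qualitative traditional notion; the 1/7/12 default encodes one
  published reading, not a biological ground truth.
- Enrichment results depend entirely on the supplied GMT collection;
  no ontology-graph propagation is performed.
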