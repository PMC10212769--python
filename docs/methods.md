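# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
underlying definitions left room.

## HLA sampling density

For one protein and one HLA class, the score is

    D = K / (L − 8)        (HLA-I)
    D = K / (L − 14)       (HLA-II)

with L the protein length in residues, so the denominator counts the
possible 9-mer (15-mer) windows, and K a weighted count over the
*distinct* peptide sequences mapped to the protein — intensity and
observation multiplicity are deliberately ignored. Each peptide x
contributes P(x|N), a function of N, the number of proteome entries
containing x:

- `weight_mode="literal"` (default): P = 1 + (1 − q)^N. This is the
  published form. It lies in (1, 2] and decreases with N but never
  below 1, so even a widely shared peptide still contributes a full
  unit to K.
- `weight_mode="saturating"`: P = 1 − (1 − q)^N, the form one would
  expect if P is read as the probability that at least one of the N
  sharing proteins generated the peptide; it lies in (0, 1) and
  increases with N.

The two differ by exactly 2·(1−q)^N per peptide. We suspect the
literal form is a sign typo for the saturating one, but we do not
assert that: the literal form is the default for fidelity, and both are
tested against a brute-force oracle. q = 0.2 is the a-priori expected
peptide yield per protein; it is exposed but there is no reason to move
it. Peptide-to-protein mapping is exact substring search with I and L
treated as distinct residues. Proteins are collapsed to genes by the
maximum D over their proteins (the collapse rule is not specified
upstream; max preserves "this gene was presented this densely
somewhere").

Marker panels for immune cell types are the genes of a reference
immune-cell score table lying strictly above the 99th (HLA-I) or 80th
(HLA-II) percentile of the all-gene distribution; a sample's marker
presentation level is the mean D over panel genes, with absent genes
contributing 0. Mean rather than sum was chosen so panels of different
sizes are comparable; the aggregation is a parameter in spirit and
trivially replaceable.

## TME scoring

All expression statistics run on log2(TPM+1). The inflammation score is
the mean over an inflammation gene panel (a configurable `aggregate`
hook accepts any other signature-style aggregation); cell-type
abundance is the same mean per cell-type panel. The tumor-versus-stroma
contrast is

    z_i = (⟨A_i⟩ − ⟨B_i⟩) / sqrt(var(A_i) + var(B_i))

with sample variances (ddof = 1) of the **values** of each group, not
standard errors. Consequently for equal group sizes n the null spread
of z is ≈ sqrt(1/n), and |z| > 2 selections are conservative; this is a
property of the published definition and is covered by a test. (The
source prints the same group twice inside the square root; one variance
per group is the only non-degenerate reading.) Quartile splits use
type-7 (linear interpolation) percentiles with inclusive boundaries;
the all-equal case returns empty sets.

Micro/macro concordance: per (micro-region, macro-region) pair of a
patient, Pearson r over the shared measured genes; per micro-region the
variance (ddof = 1) of r across the patient's macro-regions; per
patient the mean of those variances. Restriction to tumor micro-regions
is a parameter, as is the gene universe (default: all shared genes).

PCA fraction of variance: columns are mean-centered before SVD (FOV as
a variance decomposition requires centering; the uncentered variant is
available via `center=False`), and FOV_i = d_i²/Σd_j².

## TAA selection and presentation efficiency

A gene is a TAA iff max tumor-region TPM > t AND max adjacent-healthy
TPM ≤ t AND max GTEx-style 90th-percentile TPM over normal tissues
(testis exempt by default) ≤ t, with t = 1 TPM. The healthy/GTEx side
uses ≤ (strict `<` selectable via `strict_healthy`, matching the other
published phrasing). P_eff is computed on linear normalized values for
both E_i and E_HLA; ε is the 0.1th percentile of detected micro-region
values, where "detected" excludes exact zeros by default
(`exclude_zeros=False` selectable — with zeros present the percentile
collapses to 0, which is why exclusion is the default). The guard
E_HLA + ε > 1 is enforced; below it the normalization factor is not
positive and the score is meaningless. Region means ⟨P_eff⟩ are
arithmetic over the expressed TAAs, including P_i = 0 entries.

## Immune-editing statistics

Hotspot membership is allele-agnostic exact string matching of the
wild-type counterpart peptide against the database; the allele
representation bias this ignores is corrected by the synonymous
control, which experiences the same bias but no immune pressure.
F_ex and F_ex,syn are peptide-level fractions over binders
(rank ≤ 2%); a mutation is "exact" when at least one of its predicted
binders is exact (used for the immunogenicity model and RI counts).
Units with an undefined fraction are imputed with the minimum defined
value of their annotation group; units without synonymous binders can
instead be dropped. Clonality: truncal if present in
≥ n_regions − offset regions (offset 1 by default, per-patient
overrides of 2 or 3 for low-mutational-load patients), else private if
present in ≤ 2, else shared — truncal takes precedence in the overlap,
and "shared" is the category elsewhere called clonal. Smoking: binary
smoker iff tobacco-signature contribution > 50%; three-level light
≤ 30%, heavy ≥ 70% AND ≥ 70 pack-years, else intermediate (missing
pack-years block the heavy label).

The immunogenicity model is purely empirical: f_ex and f_nonex are the
immunogenic fractions among exact and nonexact labeled mutations;
"not tested" labels are excluded from the denominators by default
(counting them as nonimmunogenic is selectable — the upstream handling
is not stated, and exclusion is the conservative choice). RI is the
exact convex combination (N_ex·f_ex + N_other·f_nonex)/N_total. The
neoantigen quality ratio q = ⟨Q_truncal⟩/⟨Q_private⟩ consumes
externally computed quality values Q; the quality model itself is out
of scope. Group comparisons are one-sided Wilcoxon rank-sum tests,
exact for small tie-free samples and normal-approximated with tie
correction otherwise; constant pooled input is reported as degenerate
with p = 1.

## Rank-based annotation enrichment

s = 2(R_g − R_o)/n with ascending average-tie ranks, R_g the mean rank
of the term's genes and R_o the mean rank of the complement (the only
reading under which |s| ≤ 1 and negation symmetry hold; the extreme
values are attained when the term occupies the very top or bottom of
the ranking). Terms disjoint from the universe, or covering it
entirely, are undefined. Ontology structure is not traversed — terms
are flat gene sets from GMT files. The 2D selection keeps terms at
distance strictly greater than the threshold (0.3 for fold-change
axes, 0.2 for sampling-score axes). The HLA-II marker rule retains a
candidate gene presented (D > 0) in at least 50% (inclusive) of the
samples of some annotation group.

## The synthetic cohort generator

The generator produces the statistical structure the analyses assume,
not the biology or physics behind it:

- **Proteome and hotspots** — random uniform-composition sequences
  (composition is irrelevant to every statistic); per protein,
  contiguous hotspot intervals covering ≈`hotspot_fraction` of
  residues. The hotspot database contains every 8–12-mer window fully
  inside an interval plus a small leak (`hotspot_leak_prob`, default
  0.02) of windows drawn anywhere, and records the share count N(x) of
  each peptide. Dense within-interval coverage is what makes a
  hotspot-placed mutation's wild-type windows database members.
- **Mutations and neoantigens** — per patient,
  `mutations_per_region × regions_per_patient` distinct mutations;
  `truncal_fraction` of them present in all regions. A nonsynonymous
  mutation is placed inside a hotspot with probability
  `exact_prob_excluded` or `exact_prob_infiltrated` by patient group —
  the gap between the two *is* the implanted editing effect (defaults
  0.10 vs 0.04). Synonymous mutations are placed uniformly and inherit
  the chance-level hotspot hit rate, so F_ex,syn is group-independent
  by construction. Binder ranks carry a point mass below the 2%
  threshold (`binder_prob`) and are uniform above it — only the
  threshold matters downstream. Immunogenicity labels are Bernoulli
  with f_ex = 0.0195 or f_nonex = 0.00392 by the mutation's exact
  status.
- **Expression** — log-normal baselines with implanted shifts: immune
  panel genes +2 log2 units in the stroma of excluded patients and the
  tumor micro-regions of infiltrated patients; TAA genes above 1 TPM
  only in designated tumor macro-regions (and high in GTEx testis
  only); HLA-A/B/C highly expressed everywhere.
- **Peptidome** — per macro-region, peptides sampled from protein
  windows (lengths 8–15 HLA-I, 8–25 HLA-II) with T-cell marker genes
  over-sampled 3× in HLA-II of infiltrated patients.

One RNG stream per table, seeded from the master seed by fixed
offsets, so any table regenerates identically on its own; all
iteration orders in random-draw paths are sorted, making outputs
byte-identical across processes and platforms.

What the generator does **not** emulate: MS spectra and intensities
with physical meaning, codon-level DNA, binding-affinity structure
beyond the rank threshold, linkage between mutations and expression,
and real patient-to-patient heterogeneity. Passing tests therefore
demonstrate correctness and calibration of the statistics under the
assumed structure, not performance on real cohorts.

## Problem sizes and calibration checks

The editing power/type-I checks run at 30 regions per group with ~200
binders per region (60 single-region patients — one region per patient
keeps the rank-sum test's independence assumption honest; regions
within a multi-region patient share truncal mutations and would
inflate the type-I error). At the implanted 0.10-vs-0.04 gap the
one-sided test rejects in ≥95% of replicate cohorts at α = 0.05; at
zero gap the rejection rate is consistent with 5%. Immunogenicity
model recovery is checked at n = 50,000 labeled mutations against
binomial confidence intervals. The shipped demo cohort (8 patients,
32 regions) is sized to run in about a second; at that size the editing
comparison is directionally correct but not significant, which the
README states explicitly.

## Known limitations

- The literal sampling-density weight follows the published formula
  even though its behavior for shared peptides is arguably inverted;
  analyses sensitive to multi-mapping peptides should compare both
  modes.
- Gene-level collapse by max D and the mean-based marker presentation
  level are reasonable but unverifiable choices.
- The consensus-mutation step operates on already-parsed caller
  tables; it does not reimplement any caller or its quality model.
- The hypergeometric utility is a thin core, not a full GO enrichment
  engine (no term curation, no DAG propagation).
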