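# Methods

This note documents the models, defaults and numerical choices behind
`paraprobe`, and what the synthetic-data experiments do and do not show
about real array data.

## Signal model (synthetic data)

Each locus is a diploid cross observed at one *target* annealing site and,
for paralog behaviors, one additional *paralog* site.  Every haplotype at
every site carries an allele code with a channel assignment and a binding
efficiency β:

| code | meaning                              | channel share (X, Y) | β default |
|------|--------------------------------------|----------------------|-----------|
| A    | ordinary A allele                    | (1, 0)               | 1.0       |
| B    | ordinary B allele                    | (0, 1)               | 1.0       |
| D    | B-type allele, diverged probe site   | (0, 1)               | 0.3       |
| n    | null allele (no binding)             | (0, 0)               | 0.0       |
| C    | third allele at the assayed position | (0.5, 0.5)           | 1.0       |

Channel signals are X = Σ β·share_X·a_int and Y likewise (per-allele
channel intensities default to a_int = b_int = 1).  Channels are rescaled
so a fully bound heterozygote at every site reads R = 1, then i.i.d.
Gaussian noise of standard deviation `noise_sd` (default 0.03) is added to
each channel *on that normalized scale* — so the noise magnitude is
comparable across one- and two-site loci — negatives are clipped at 0, and

    Theta = arctan2(Y, X) / (π/2),    R = X + Y.

Using `arctan2` (rather than flooring channels at a small ε) keeps Theta
defined at (0, 0) and makes the noise-free identities *exact*: an AA
sample has Theta = 0, AB exactly 0.5, BB exactly 1, and a β = 0 homozygote
has R exactly 0.  Because noise enters the channels rather than Theta
directly, Theta scatter shrinks toward the 0 and 1 rails, reproducing the
fan-shaped clouds of real cluster plots.

Choices worth flagging:

* **β(D) = 0.3.**  No quantitative binding-efficiency estimate exists for
  real divergent sites; 0.3 makes the relative R separation between the
  fully bound class (R = 1) and the one-divergent-haplotype class
  (R = 0.65) equal 0.35 — a vertical shift of the magnitude that is
  visually unmistakable on a cluster plot, which is the phenomenon being
  modeled.  It is configurable per `SignalModel`.
* **C splits channels evenly.**  Array chemistry for a third allele is not
  modeled mechanistically; an even split puts the AC and BC clusters of an
  AB×AC cross at Theta ≈ 0.205 and 0.795, giving the four distinct
  clusters such loci show in practice.
* **Fixed paralog sites do not segregate.**  A `PARALOG_FIXED` site keeps
  one genotype (possibly heterozygous — a fixed homeologous duplication)
  in every sample; `PARALOG_SEGREGATING` and `MULTI_LOCUS` sites undergo
  independent meiosis.
* The generator never simulates GenTrain scores, raw two-color
  intensities, batch or plate effects.

Default study conditions: 180 offspring plus the two parents, noise_sd
0.03, and per-behavior default crosses (AB×AB single copy; AB×AB target
with fixed AA paralog; AA×AA target with segregating AB×AB paralog; BD×BD;
Bn×Bn; AB×AC; AB×AB at both sites).  The `reference` mix reproduces the
observed re-annotation proportions 202 : 616 : 91 : 33 (divergent-site
including nulls : paralog : four-cluster : more-than-four), with the
divergent class split 96/106 between with-signal and null loci and the
paralog class split evenly between fixed and segregating paralogs.

**What passing tests show — and don't.**  The generator produces compact
Gaussian clouds at analytically known positions.  Recovery results on it
demonstrate that the cascade's geometry rules are mutually consistent and
correctly keyed to the planted phenomena; they do not demonstrate
robustness to the pathologies of real arrays (heteroscedastic noise,
intensity batch effects, partial-binding continua, overlapping clouds), on
which the UNSCOREABLE escape hatch and the tolerances below would need
re-examination.

## Clustering

Per-locus points are agglomerated bottom-up under Euclidean distance in
the (Theta, R) plane: repeatedly merge the closest pair of clusters while
that linkage distance is ≤ the threshold.  Thresholds are swept over
{0.1, 0.15, 0.2, 0.3, 0.4, 0.5}; the working default is 0.15.  Clusters
with fewer than 3 members are then removed, their members reported as
no-calls.

* **Linkage default: average (UPGMA).**  Complete linkage caps cluster
  *diameter*, and with ~90-sample genotype clouds at channel noise 0.03
  the complete-linkage diameter (≈ 0.25) exceeds the 0.15 working
  threshold, shattering genuine clusters; single linkage invites chaining
  between adjacent clouds.  Average linkage coheres a cloud (mean
  within-cloud pairwise distance ≈ 0.06 at these conditions) while keeping
  adjacent genotype clouds ≥ 0.2 apart unmerged.  Complete and single
  remain available (`ClusterConfig.linkage`) and the run metadata records
  the choice.
* Theta and R enter the distance unweighted (an `r_weight` option exists,
  default 1.0).
* **Determinism.**  Samples are canonicalized to sample-id order on entry;
  exact merge-distance ties are broken toward the pair whose smallest
  member id sorts first (then the partner's smallest member id).  The
  partition is therefore invariant to input order, and because the merge
  *sequence* does not depend on the threshold (only the stopping point
  does), partitions are nested across thresholds and the cluster count is
  monotone non-increasing in the threshold for every linkage.
* Implementation uses exact Lance–Williams updates; tests verify equality
  with an O(n³) recompute-from-scratch oracle on random instances n ≤ 12.

## Classification cascade

Tolerances (all configurable, defaults chosen so the noise-free fixtures
classify exactly; real numeric criteria for "clear separation" do not
exist and these are conventions, recorded in run metadata):

| parameter           | default | meaning                                          |
|---------------------|---------|--------------------------------------------------|
| theta_canonical_tol | 0.10    | max \|mean Theta − {0, 0.5, 1}\| to be canonical |
| theta_equal_tol     | 0.05    | max ΔTheta for "same Theta"                      |
| r_null_tol          | 0.05    | mean R below this = null cluster                 |
| r_shift_min         | 0.3     | min ΔR/max(R) to call a vertical shift           |
| alpha               | 0.05    | segregation-test level                           |

Order of decisions: pool floor-hugging clusters, then >4 clusters →
MULTI_LOCUS; 4 → TRIALLELIC; any null class → NULL_ALLELE; same-Theta
vertically-shifted pair → DIVERGENT_SITE; 2–3 canonical clusters →
SINGLE_LOCUS (one cluster → MONOMORPHIC); other 2–3 → PARALOG_SHIFT;
same-Theta pairs that are neither separated nor null → UNSCOREABLE.

* **Null pooling.**  Theta is meaningless at R ≈ 0, so under noise a null
  class smears across Theta and fragments in the cluster engine.  Before
  counting clusters, all clusters with mean R below
  max(r_null_tol, 0.1 × the locus's strongest cluster R) are pooled into
  one null class — "approaching zero" is judged on the locus's own
  intensity scale, as a human reader of the plot judges it.  The NULL
  category itself still requires a pooled cluster below the absolute
  r_null_tol.
* **"Significantly different R"** is operationalized as relative
  separation ΔR/max(R) ≥ r_shift_min, not a statistical test: within-
  cluster R variance is not modeled and a test would manufacture
  precision.
* A single cluster is MONOMORPHIC wherever it sits in Theta; without
  segregation there is no geometric evidence to distinguish a shifted
  monomorphic locus from a canonical one.
* **Segregation fit** tests the class counts (ordered consistently with
  the labels) against 1:1, 3:1 and 1:2:1 by Pearson chi-square; 3:1 is
  entertained only for two-class readouts (dominant-style patterns from
  nulls or divergence).  Best fit = highest p; ties resolve toward fewer
  classes; "none" when everything is rejected at alpha.
* Genotype labels: canonical clusters get AA/AB/BB; divergent patterns
  B B′ notation (BB : BB′ : B′B′), null patterns Bn : nn, with the A/B
  side chosen from the bound clusters' Theta; paralog-shifted loci get
  AA*/AB*/BB* in Theta order, the `*` marking the unresolved paralog
  contribution.
* Germplasm triage (panel mode, no cross): ROBUST = 1–3 well-separated
  fully populated clusters with no null class; AMBIGUOUS = a thin class
  (< 3), a null class, removed samples, or marginal separation;
  UNSCOREABLE = more than three clusters.

## Probe scanning

Exact 50-mer occurrences are found by plain string search on both strands;
the 3′ 24-mer is searched at Hamming distance ≤ 2 via pigeonhole seeding
(the 24-mer is split into three 8-mer chunks, one of which must occur
exactly; candidate windows are verified by mismatch count).  Matching is
substitution-only by design — the scanner is an idealization of a
two-mismatch short-query criterion, not a BLAST replacement: no indels, no
E-values, no gapped alignment, and no attempt to reproduce hit counts
against any specific external assembly.  A '−' strand hit at position p
means the reverse complement of the query occurs at p on the forward
reference; every exact 50-mer hit therefore implies a 24-mer hit at p + 26
('+') or p ('−'), a relation the tests assert.  Hits are deduplicated by
(chromosome, start, strand); coordinates are 0-based half-open internally
and 1-based inclusive in files.

Per-probe categorization (single hit / multi-hit one LG / multi-hit many
LGs) is computed per stringency; the homeology flag and region count
describe the relaxed 24-mer stringency, where paralogous annealing is
visible.  Chromosome names are normalized across `chr05` / `LG5` / `5`
spellings; the Malus homeology map ships as the packaged default and any
map can be supplied as one comma-separated group per line.

## Pipeline and determinism

All randomness flows from one top-level seed; per-locus generator seeds
are drawn below 2³¹.  Outputs carry no timestamps, so identical configs
produce byte-identical files.  Stages degrade explicitly: a missing
manifest/reference skips the scan stage and says so in
`run_metadata.json`, which also records every tolerance used.

## Problem sizes

The test suite simulates at the study conditions (180 offspring, noise_sd
0.03) with 500 loci for the recovery check, sweeps ~150 random instances
(n ≤ 12) against the clustering oracle, and scans a 100 kb planted
two-chromosome reference against the window-by-window oracle — sizes at
which the brute-force oracles remain exact and fast while exercising every
code path at realistic per-locus scale.

## Known limitations

* Cluster-geometry categories are assigned per locus independently; no
  information is shared across loci or with linkage structure.
* The classifier's tolerances are conventions tuned to the normalized
  scale; arrays whose normalization differs need re-tuned defaults.
* Parental-consistency checking of genotype calls covers single-copy
  codominant loci; null/divergent crosses are genotyped but their parental
  phase is not inferred.
* The scanner's substitution-only model understates hits from indel-
  containing annealing sites.
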