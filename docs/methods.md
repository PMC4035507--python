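# Methods

## The selection model

The package models secretome-selective phage display as a composition of a
deterministic display rule and a small stochastic escape channel.

**Display rule.** The phagemid cassette reads: vector ATG … cloning site |
insert | pIII C-domain, with the first base of the downstream flank at codon
phase `frame_offset` (0 in the default cassette).  A clone displays iff

1. the maximal stop-free codon run in the 3'-anchored pIII frame, ending at
   the insert–pIII junction, is at least `min_fusion_len` = 24 codons, and
2. the translated run carries a membrane-targeting signal (any category
   other than background).

The run is *not* required to begin at an initiation codon: translation can
initiate at the cassette ATG and reinitiation is common, so the open-run
definition is the default; a strict mode additionally requires ATG/GTG/TTG.
Translation uses the bacterial code (table 11); IUPAC ambiguity codes are
rejected.

**Lottery expectation.** For a random insert the display probability
factorises into secretome-ORF fraction × orientation × frame
(0.20 × 1/2 × 1/3 ≈ 3.33%).  Enrichment is reported as observed
post-selection frequency over this expectation.  Both values are rounded to
one decimal before taking the ratio (94.4/3.3 = 28.6 → 29-fold); this
reproduces printed report arithmetic, and an exact-ratio mode is available
(`enrichment_fold(..., exact=True)`).  Percentage rounding throughout is
half-up (one decimal for class rows, two for cellulosome-module rows); the
rounding mode is an assumption, as report tables rarely state one.

**Escape channel.** Non-displaying clones survive selection independently
with probability `background_escape`.  The default, 0.002, is calibrated so
that at the default community composition the background is ~5–6% of
selected clones and the observed secretome frequency ~94–95%, matching the
regime of a stringent selection; it lumps all physical causes (cryptic
targeting, detergent resistance) into one free parameter.

## Signal classification

The built-in detectors are deliberately simple, deterministic sequence
rules — decision-logic stand-ins for SignalP/LipoP/TMHMM/PilFind/PRED-TAT
— and external predictor verdicts can be supplied as overrides per category:

* **Type I**: ≥1 K/R in residues 1–5, a ≥7-residue window within residues
  6–20 with mean Kyte–Doolittle hydropathy > 1.6, and an A-X-A motif ending
  at position 15–30.
* **Type II**: lipobox `[LVIFG][ASTVG][GAS]C` with the Cys at position
  12–35 and ≥1 K/R in residues 1–7.
* **Type IV**: Gly at the −1 cleavage position within the first 12
  residues, immediately followed by Phe and a hydrophobic run.
* **Tat**: `[ST]RR.FLK` within the first 35 residues.
* **TMH**: maximal merged intervals of 19-residue windows with mean
  hydropathy > 1.6.

Exactly one category is assigned per ORF with precedence
TYPE_IV > TYPE_II > TAT > TYPE_I > TMH > non-classical > background:
specific motifs outrank generic hydropathy.  Within TMH, a single helix
starting at residue ≤ 40 is an N-terminal anchor; multiple helices or a
single internal helix are the internal/multiple category (multiplicity wins
over position, matching the category's definition).  Sequences shorter than
24 residues are background regardless of content; a non-classical secretion
score (SecretomeP-style, external only) ≥ 0.5 rescues otherwise
signal-less ORFs.  Real predictors will disagree with these rules on real
data; the precedence order itself is a package decision.

## The synthetic community

`generate_community` emulates a plant-adherent community's DNA as circular
replicons densely packed with plus-strand ORFs.  Exactly
`round(secretome_fraction × n_orfs)` ORFs carry a signal (exact-count, not
Bernoulli, so small communities are deterministic), allocated across
categories in the pilot-library proportions 35:8:6:3:1 (Type I : TMH anchor
: TMH internal/multiple : Type II : Type IV) with Tat weighted 0.

Geometry is engineered so the lottery holds *exactly*:

* every ORF is preceded by a fixed 12-nt spacer (`TTAGTTAGTTAA`) carrying
  stop codons in all six frames and ending with an in-frame TAA, so an
  in-frame fusion run always starts at the ORF's own ATG;
* secretome proteins are 200 aa and background proteins 165 aa.  With the
  12-nt spacer, junction positions yielding a ≥24-codon in-frame secretome
  fusion are 177 of the 531 nt of genome per ORF at a 20% secretome
  fraction — exactly `secretome_fraction × 1/3` of positions, so the
  expected selected fraction is `secretome_fraction × p_orientation × 1/3`;
* signal motifs are complete within the first 24 residues of their
  proteins, so every ≥24-codon truncation of a secretome ORF is detectable.

The deterministic spacer replaces i.i.d. random intergenic sequence: it
provides the same guarantee (six-frame stops at bounded spacing) while
keeping the capture arithmetic exact.

**Spurious-fusion suppression.** Out-of-frame and reverse-strand readings
of coding DNA are the false-positive channel for selection.  Two codon-level
measures close it: hydrophobic runs are Val-Val-Leu repeats on GTG/TTG
codons, whose five alternative readings are deterministically
non-hydrophobic; and protein tails are assembled from a library of ten
screened 8-codon cassettes whose alternative readings (including all
pairwise junctions and helix junctions) stay below the transmembrane
hydropathy threshold and contain no lipobox or prepilin motif.  Measured at
10⁵ clones with escape 0, selection produced zero false-positive and zero
false-negative clones relative to ground truth.

**Shearing/cloning.** Insert start positions are uniform on the circular
replicons; lengths follow a log-normal (median 1.5 kb, σ = 0.6) truncated
to 0.7–5 kb — the range is a study condition, the distribution shape an
assumption.  Orientation is Bernoulli(1/2).  Truth flags come from junction
arithmetic: a clone is a true in-frame secretome clone iff its 3' junction
sits on a codon boundary of a signal-carrying ORF, ≥ 24 codons past the
ATG and before the stop, in forward orientation.

**What the simulator does not model** — and hence what passing tests do not
show about real data: sequencing error and homopolymer noise, chimeric
clones, amplification bias between selection rounds, minus-strand genes,
overlapping genes, real codon usage, and the behaviour of the published
predictors on natural sequence.  The 100% classifier/ground-truth agreement
is by construction and calibrates the *pipeline logic*, not real-world
predictor accuracy.

## Annotation and statistics

* **Domain-hit filtering**: keep iff (alignment > 80 aa and E < 1e-5) or
  (alignment ≤ 80 aa and E < 1e-3); long alignments get no relaxed branch.
  For HMMER domtblout input the per-domain independent E-value column is
  used and alignment length is the envelope length.
* **Dedup**: 100%-identity clustering with containment (a sequence joins a
  cluster when identical to or an exact substring of the representative),
  greedy longest-first with lexicographic ties — deterministic and
  order-independent.  Clustered counts tally hits on representatives.
* **Cellulosome calls**: ≥2 dockerin-repeat hits on an ORF form a presumed
  complete dockerin domain (no maximum gap imposed); one repeat plus any
  other CAZyme module, and lone repeats, are their own kinds; cohesin and
  SLH are reported separately.  Dockerin/cohesin/SLH families are exclusive
  to the cellulosome pool and never counted under GH/CBM/etc.  Overlapping
  hits are all retained (counts are hits, not non-overlapping domains).
* **Proportion test**: two-sided two-proportion z-test with pooled
  variance, falling back to Fisher's exact test when any expected cell
  under the pooled proportion is < 5; significance at α = 0.001.  The
  choice of test is an assumption — the asterisk semantics constrain only
  the α level.  No multiple-testing correction is applied.
* **COG rollup**: each Pfam maps to one category letter; unmapped Pfams
  fall into S (function unknown).
* **Taxonomy**: best hit (highest bit score, ties by lower E-value then
  input order).  Insert-level rule: E < 1e-5 and query coverage > 30%
  (coverage reconstructed as aligned-query-span / query length when no
  qcovs column is present; it defaults to 1.0 if lengths are unavailable,
  disabling that filter).  Module-level rule: bit score ≥ 40 for
  cohesin/SLH ORFs, ≥ 35 for dockerin ORFs, rolled up at family rank.
  Rank rollups pool taxa under 0.1% into "Other"; unassigned queries and
  best hits under 30% identity bin as "Unassigned".  Best-hit binning only
  — no LCA.

## Numerical and interface choices

* Coordinates are 0-based half-open internally, 1-based inclusive in report
  files.  Junction anchor ties go to the leftmost match.
* One RNG stream per operation, seeded as (global seed, CRC32 of the
  operation name); fixed seeds give bit-identical FASTA/GFF/TSV output.
* Problem sizes in the test suite (communities of 200–500 ORFs, libraries
  of 3×10³–10⁵ clones) were chosen so the binomial standard error of the
  selected fraction is well below the quantities being checked while the
  suite stays fast.
* The simulator writes FASTA (60-column), GFF3 with a `signal_category`
  attribute, HMMER domtblout / dbCAN 10-column TSV, and BLAST outfmt-6
  (+staxids) dialects; the dbCAN TSV carries no bit score, which is
  recorded as 0.

## Known limitations

* The heuristic detectors are not substitutes for the published predictors
  on natural sequences; supply external predictor tables for real data.
* The escape probability is a single lumped free parameter; it does not
  resolve the physical mechanism of background survival.
* `dedup_sequences` is quadratic in the number of distinct sequences and is
  intended for per-dataset protein sets, not raw read collections.
* Reported class distributions are recomputed from counts; where a printed
  distribution disagrees with its own printed counts, the recomputed value
  is reported.
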