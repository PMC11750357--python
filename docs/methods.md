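# Methods

`paleofv` reconstructs the history of filamentovirus endogenization in
cynipoid wasps from assembled genomes: it catalogs candidate endogenous
viral elements (EVEs), weighs the evidence that they sit on host
chromosomes rather than in co-assembled virions, classifies each viral
gene family's phylogeny, groups loci into endogenization events by
transitive colocation, tests the events' gene sets for core-gene
enrichment, estimates selection pressure on the retained genes, and maps
each event onto a calibrated chronogram.  This note records the models,
parameter choices and numerical conventions, and what the synthetic
scenario generator does and does not emulate.

## Detection and the EVE catalog

Input homology hits are 12-column tabular rows (BLAST/MMseqs2
`outfmt 6`) of wasp scaffolds against a panel of filamentovirus
proteomes.  Coordinates are normalized at parse time to 0-based
half-open intervals on the forward strand; `qstart > qend` marks a
minus-strand hit.  That is the only place coordinate conventions are
handled.

* **e-value ceiling** (`e_max`, default `1e-3`, inclusive): hits above
  it are discarded before locus calling.
* **Locus calling**: overlapping or book-ended same-strand hits on one
  scaffold are unioned into a single locus regardless of subject family;
  the locus family and source virus come from the highest-bitscore
  constituent hit, ties broken by lower e-value, then lexicographic
  subject id.  Book-ended intervals (end == start under the half-open
  convention) merge; this convention is applied consistently in locus
  calling and TE-interval merging and is covered by tests.
* **ORF integrity**: all three frames of the locus sequence (reverse-
  complemented for minus-strand loci) are scanned for readings from a
  recognized start codon — ATG plus the alternative starts TTG, CTG and
  GTG, which filamentoviruses are known to use (`lef-5` being the
  canonical TTG case) — to the next in-frame stop.  A reading covering
  at least 80% of the hit-supported span is `complete`; a stop-terminated
  reading covering less is `premature_stop`; no start or no stop within
  the locus is `incomplete`.  The 80% threshold is this package's
  quantification of an otherwise qualitative "premature stop" annotation;
  it is configurable in code and deliberately generous, since fragmented
  hits make exact span recovery unreliable.

## Integration evidence

Exogenous viral DNA co-assembles with host genomes, so each candidate
scaffold is scored on three independent signals:

1. **GC/coverage envelope.** BUSCO-containing scaffolds are host
   chromosome by definition; per species and per metric the acceptance
   interval is median ± k·MAD over the BUSCO scaffolds, with k = 5.
   The median/MAD rule is robust to the skewed coverage distributions of
   real assemblies; k = 5 keeps essentially all true host scaffolds
   inside while still excluding high-coverage, composition-shifted viral
   contigs.  At least 5 reference scaffolds are required.  Coverage is
   consumed as per-scaffold means (TSV), not per-base depth.
2. **Eukaryotic gene content.** Predicted-protein taxonomy labels are
   majority-voted per scaffold; ties and empty label sets yield
   `unassigned` (conservative: a scaffold is never called eukaryotic on
   a split vote).  Any eukaryotic-labelled protein counts as evidence.
3. **Transposable elements.** TE hits pass with e-value strictly below
   1e-10 and alignment length strictly above 100 aa; survivors are
   merged into disjoint intervals.  Viral genomes essentially never
   carry TEs, so one merged interval suffices as evidence.

The verdict is `endogenized` when (GC ok AND coverage ok) or ≥1
eukaryotic gene or ≥1 TE interval; `likely_exogenous` when none of the
signals fire; `ambiguous` otherwise (e.g. one envelope metric in, one
out).  Envelope similarity alone is sufficient — some genuinely
integrated scaffolds carry nothing but the EVE.

## Gene-tree classification

A virus-to-wasp transfer leaves wasp sequences as a supported
monophyletic clade nested inside the virus diversity, sister to the
donor lineage.  Internal node labels are "aLRT/UFboot" pairs; the
ultrafast-bootstrap (second) component is thresholded, **strictly
greater than 80** by default.  Which support measure to threshold is a
config knob; UFboot is the default.

Trees are rooted on outgroup-tagged virus tips (Hytrosaviridae in the
shipped panel) when present, else at the midpoint; the classification
rules depend only on clade membership within the virus backbone, and the
property suite checks insensitivity to tip rotation and
re-serialization.  Midpoint rooting skips the re-root when the current
root already balances the two deepest directions, which makes repeated
rooting idempotent.

Maximal all-wasp clades are extracted root-to-tip: the first supported
all-wasp node on a path is taken whole; unsupported all-wasp nodes are
split into their children.  Singleton wasp tips always qualify (their
support requirement is vacuous) — necessary because a species-specific
acquisition may be represented by a single sequence.  Each clade's
nearest viral relative is the majority lineage tag of its sister group's
virus tips; a mixed or wasp-only sister triggers a walk toward the root
to the first virus-containing sister, recorded in the call's notes.

* `TYPE_I` — exactly one wasp clade, containing every wasp tip, nearest
  relative in the ancestral donor lineage (LhFV-like).
* `TYPE_II` — the only wasp presence is a single-species clade whose
  nearest relative is the recent donor lineage (LbFV-like).
* `TYPE_III` — exactly one of each pattern co-occurring.
* `UNCLASSIFIED` — everything else: insufficient support, nearest
  relative in neither canonical lineage ("other" is never coerced to a
  type), or clade multisets outside the three patterns (e.g. two
  ancestral-adjacent clades).

## Event assignment

Two loci belong to the same endogenization event when they colocate on
one scaffold of one species, or when they are same-family copies falling
in the same supported wasp clade of that family's tree (descendants of a
single insertion, even without colocation in the second assembly).
Connected components under the transitive closure of both edge types —
computed by union-find — are the events; a brute-force reachability
closure serves as the test oracle.  Unclassifiable families contribute
no homology edges, so their loci are recovered only through colocation;
a singleton component of an unclassified family is reported as
*unassigned* rather than as a one-locus event.  Donor lineage is the
majority vote over member families' nearest-relative tags, restricted to
the clades that actually contain the component's loci; disagreement sets
a conflict flag and is never silently resolved.

Loci are matched to tree tips by a shared naming convention
(`species|family|k`, k ranking the locus among that species-family
pair's loci by scaffold and start coordinate), so catalog and trees line
up without an external cross-reference file.

The presence/absence matrix annotates each species × family cell with
the copy number, `*` when at least one copy is defective, and `#` when a
complete ORF uses a non-ATG start.  The `#` flag deliberately ignores
defective copies: a "start codon" recovered downstream of a premature
stop is an artifact of the ORF scan, not a biological alternative start.

## Selection analysis

dN/dS is estimated by Nei–Gojobori (1986) counting with Jukes–Cantor
correction — a fully specifiable method with an exact hand-checkable
oracle.  Maximum-likelihood estimators (codeml-style) will not match it
exactly, especially at high divergence or strong codon bias; this is a
deliberate trade of statistical efficiency for transparency.

Details fixed by convention and covered by tests: synonymous/
nonsynonymous site counts are averaged over the two sequences; changes
creating stop codons count as nonsynonymous; codons differing at more
than one position are averaged over all minimal mutational pathways,
excluding pathways through stop codons (falling back to all pathways
when every one is blocked); columns with gaps, ambiguity codes, or stop
codons in either sequence are excluded pairwise-complete; the correction
d = −(3/4)·ln(1 − (4/3)·p) is undefined at p ≥ 3/4 and such pairs are
excluded from the family mean but kept in the record.

A family estimate is the mean over defined pairwise omegas with its
standard error (the pairwise convention; pairs sharing a sequence are
correlated, so the s.e. is optimistic — regime calls, not the s.e., are
the supported inference).  Regime: *purifying* when a two-sided
one-sample t test against 1 rejects at α = 0.05 (configurable) with
mean < 1; *neutral* when not rejected; *undetermined* with fewer than 3
defined pairs.  Group comparison between EVE and reference (BUSCO) gene
omegas is a pooled-variance two-sample t test with df = n₁ + n₂ − 2,
over pooled pairwise omegas.

## Enrichment and dating

Core-gene enrichment uses Fisher's exact test on the 2×2 table of event
genes vs the donor's full repertoire, split core vs non-core (core
flags are input metadata on the virus panel, defined upstream at the
level of the dsDNA arthropod viruses).  The reported odds ratio is the
**conditional maximum-likelihood estimate** under the noncentral
hypergeometric model — the convention of standard statistical software —
with the sample cross-product ratio also reported; on the 18-gene
worked example the CMLE is 5.50 where the cross-product is 5.59.  The
two-sided p follows the point-probability rule (sum of probabilities of
tables no more probable than the observed one), stated explicitly
because two-sided conventions differ.  A p-only fast path skips the
CMLE root-finding for bulk comparisons.

Events are dated as intervals, never points: the lower bound is the
crown age of the MRCA of the event's recipient species (0 for a
single-species event), the upper bound the age of the split from the
closest EVE-negative relative; credibility intervals propagate from node
annotations when present.  The chronogram is an ultrametric newick tree
with branch lengths in Myr and optional node comments
`[&age=76.4,ci={55.0,100.0}]`; ages are recomputed from branch lengths
and validated (strictly decreasing root to tips), the comments carry the
CIs.  The shipped fixture chronogram is synthetic in topology detail but
carries the published calibration ages for this wasp group: crown of the
six EVE-positive species 76.4 Myr (CI 55–100), the
*Rhoptromeris*–*Trichoplasta* split 40 Myr (CI 22–59), the *Ganaspis*
split 91.1 Myr, a 145-Myr root, and an assumed 83-Myr attachment for the
EVE-negative *Leptolamina* (any value between 76.4 and 91.1 is
consistent with its position).

## The synthetic scenario generator

The generator emits everything the pipeline consumes — scaffolds with
planted EVE ORFs, coverage, viral and TE hits, taxonomy labels, gene
trees, codon alignments, chronogram, virus panel — plus a truth table,
from a single integer seed (byte-identical regeneration; different
seeds differ).

The reference `two-event` scenario plants: an ancestral event of 18
families (12 core) from an LhFV-like donor across six species (134 loci
after per-species losses and 33 paralog duplications), a recent event of
9 families from an LbFV-like donor in *Rhoptromeris* only (16 loci, 7
with premature stops), 5 families shared between the events, 2 event
families with unresolvable low-support trees (recoverable only through
colocation), and 3 orphan loci of event-free families — 153 loci, 150
assignable.  Scaffold colocation groups are arranged so that transitive
closure recovers exactly the two events: multi-species events chain
across species by rotating the family-to-scaffold grouping, and the
single-species event chains its scaffolds by splitting paralog copies of
classified families across consecutive scaffolds.

Codon evolution is a single-omega (M0-like) continuous-time process
simulated site-by-site with the Gillespie algorithm: single-nucleotide
codon changes at a rate proportional to the target base frequency,
× kappa for transitions, × omega for amino-acid-changing steps; stop
codons are unreachable; branch lengths are expected substitutions per
codon.  **Default kappa = 1** — the regime in which NG86 counting is
approximately unbiased — so the simulator-vs-estimator calibration
property (mean estimate within 15% of truth at omega 0.1/0.5/1.0) is
clean by construction; kappa is exposed for users who want to study the
bias.  Default omega is 0.15 for event families (0.11–0.17 for a few
named ones), 1.0 for the neutral `odv-e66` analogue, 0.08 for the BUSCO
reference genes; alignments are 200 codons.  Wasp-clade guide trees are
the chronogram restricted to the member species, scaled at 0.002
substitutions/codon/Myr (deepest pairs ≈ 0.3 — measurable but far from
saturation); within-species paralogs hang as 0.03-deep cherries, except
in single-species clades where copies form a 0.15-deep star so that
pairwise divergence is informative for the selection analysis.
Pseudogenized copies get a TAA at 30% of the alignment, deep enough that
no downstream reading can reach the 80% completeness threshold.

Genome scaffolds default to host GC 0.35 with a configurable GC offset
for viral inserts (0 by default, so inserts match the host and the
envelope test passes; a nonzero offset creates negative controls);
coverage is Normal(30, 3) for BUSCO scaffolds and Normal(30, 2)
elsewhere.  BUSCO scaffolds are drawn shorter (1.5–3 kb) than EVE
scaffolds, so the reference envelope is computed from the *noisier*
composition estimates — the envelope then contains the longer, tighter
EVE scaffolds with high probability without any tuning.  Scaffold
counts and lengths are deliberately small (tens of scaffolds, a few kb);
the full reference scenario generates in ~2 s and the complete pipeline
run on it takes ~2 s more.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no sequencing reads or assembly artifacts
(chimeras, collapsed repeats, fragmented loci split across scaffolds),
no indels (alignments are gap-free; the pairwise-complete gap rule is
exercised only by unit tests), no among-site rate variation or codon
bias beyond base frequencies, hit boundaries exactly matching ORF
boundaries, and planted hits that are always unambiguous as to family.
Real-data performance on any of these axes is untested by construction.

## Scope limitations

Quantities tied to the scale or identity of real assemblies are out of
scope and are not imitated by the synthetic scenario: per-genome locus
tallies of particular sequenced species, eukaryotic-gene/TE co-occurrence
fractions of particular assemblies, and the thousand-gene BUSCO
comparison (the synthetic reference set is 12 genes, so the group
comparison's degrees of freedom are dataset-sized, not literature-sized).
Site-level (per-site / per-codon) selection classification is also out of
scope: it requires ML site-model machinery (FUBAR/MEME-class) outside
this package's counting-based approach, and no fully specified algorithm
for it was available to reimplement.  Likewise out of scope: homology
search execution, alignment and tree inference, fossil-calibrated
divergence-time estimation, probabilistic reconciliation, and synteny
analysis beyond same-scaffold co-occurrence.
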