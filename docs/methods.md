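# Methods

## Scope and data model

`virodiv` consumes the standard outputs of an assembly-based virome
workflow — assembled scaffolds (FASTA), predicted ORFs (GFF3 + protein
FASTA), tabular protein search results (12-column, outfmt-6-like, with
three optional trailing taxonomy columns), an orthologous-group →
viral-quotient table (TSV), read alignments (SAM), CRISPR spacer and tRNA
FASTA files, and external classifier label tables — and produces TSV
summaries. Coordinates are 1-based inclusive throughout (the GFF3/SAM
convention); 0-based arithmetic appears only at array boundaries. For
minus-strand genes the coding sequence is the reverse complement of the
scaffold slice and all codon indices are in gene orientation. `N` is never
counted as a variant base or toward codon coverage. Scaffolds shorter than
5 kbp (configurable) are discarded on input.

Upstream steps — read trimming, assembly, ORF calling, the homology
searches themselves, and read mapping — are out of scope; the package
consumes their file formats. BAM parsing is likewise omitted: at the scale
this package targets, text SAM suffices (`samtools view` converts).

## Viral identification

Round 1 computes, per scaffold, the percentage of ORFs with an
orthologous-group hit at E ≤ 1e-5 and the added viral quotient (AVQ), the
sum over ORFs of the viral quotient of each ORF's best hit (lowest E value;
ties broken by higher bit score, then lexicographic subject id — fixed for
determinism). A scaffold passes iff percent ≥ 10 and AVQ ≥ 2, both
inclusive. Round 2 counts, per candidate, the number of *distinct*
candidate ORFs with at least one hit passing identity ≥ 30% / bit ≥ 50 /
alignment ≥ 30 aa / E ≤ 1e-5 to each single round-1 scaffold; the
candidate is recruited iff the maximum per-bait count is ≥ 3 and ≥ 20% of
its ORFs (per-bait, never pooled: the criterion names a *single* bait
scaffold). Any passing hit qualifies an ORF by default; a best-hit-only
mode is available (`bait.best_hit_only`). Baiting is a single pass over
round-1 positives; recruits are never reused as bait. Round 3 applies a
curated id list; ids already viral are left unchanged with a warning.

Concordance against external classifiers counts scaffolds flagged by
neither VirSorter (accepted categories 1–6) nor VirFinder (score ≥ 0.7 and
P ≤ 0.05, both inclusive); missing label rows count as discordant with a
warning.

Viral populations are built per sample: pairwise identity is estimated by
shared-k-mer seeding (k = 15) on the modal diagonal followed by ungapped
comparison over the diagonal overlap; two scaffolds link iff identity ≥
95% over ≥ 80% of the shorter sequence, and populations are the connected
components (union-find; singletons allowed). The diagonal method assumes
population members are largely colinear, which is the regime the 95/80
definition describes; structurally rearranged near-identical pairs would
be under-linked.

## Annotation and host prediction

Closest-relative taxonomy is called independently at family, genus and
species rank: per ORF the best passing reference hit votes for its taxon;
the majority wins; ties go to the taxon with the highest mean identity
among its matched ORFs (flagged `tie_broken`). Functional categories come
from an ordered, case-insensitive keyword table (first substring match
wins) shipped with the package, covering the broad triad
replication/structural/metabolism plus regulation and unknown.

Three automated host signals are implemented: genomic homology (best
shared segment ≥ 1 kb at ≥ 90% identity, found by k-mer seeding at k = 21,
span between first and last shared k-mer, exact-match end extension; both
host strands tried), CRISPR spacer matches (≤ 1 mismatch, either strand,
spacers ≥ 20 bp, vectorised sliding-window Hamming), and shared tRNAs
(exact full-length identity). These thresholds are package defaults, all
configurable. The consensus host at a rank is the single taxon all signals
agree on; any disagreement is ambiguous and yields no prediction, and
scaffolds without signals yield none. Manual synteny-based host assignment
is not automated.

## Abundance and diversity

A read counts once, at its highest-scoring alignment (AS tag when present;
ties to the lexicographically first scaffold). Relative abundance is
100·count/total_reads where the denominator is the sample total supplied
by the caller (defaulting to mapped reads when no total is given).
Aggregation by family or host phylum sums member percents exactly
(unkeyed scaffolds fall into `unassigned`). The Shannon index uses natural
log over renormalised proportions — the log base is a deliberate, logged
choice since conventions differ; the index is scale-invariant to
counts-vs-percents input. Subsampling to a fixed read number is uniform
without replacement by read id and deterministic per seed. The
cellular:viral fraction ratio excludes (and counts) scaffolds absent from
the viral fraction.

## Microdiversity

A read contributes to a codon pileup column only when a single aligned
(M/=/X) block covers all three bases — indels or clips inside the codon
exclude the read from that codon. Candidate mutations are distinct variant
codons in a column; a mutation is valid iff count ≥ 4, count/coverage ≥ 1%
and coverage ≥ 5×, all inclusive (the frequency denominator is the codon's
own coverage, the only reading consistent with a per-codon coverage filter
in the same rule). Effects compare translations; stop-gains are
nonsynonymous; reference stop codons and N-containing codons are excluded
everywhere (from calls, neutral totals and assayable-site counts).

The neutral model enumerates each sense codon's 9 single-nucleotide
neighbours with uniform weight (no transition/transversion bias — none is
specified by the quantity's definition, and the synthetic generator uses
the same proposal, keeping simulation and estimator consistent). Gene
fractions are f_S = Σ n_syn/(9·n_codons), f_N = 1 − f_S. Observed counts
are distinct valid variant alleles per site by default; a read-weighted
mode (`snp.count_mode: reads`) is provided because SNP-tabulating tools
differ on this, and the distinct-allele reading matches SNP-style
counting. pN/pS is reported null when S_o = 0 or no mutations survive the
filters. Percent polymorphic sites uses assayable codons (coverage ≥ 5×)
as denominator — sites below the validity floor cannot be polymorphic by
definition; total gene length is available by flag. Group medians include
a gene in the pN/pS median only with pN > 0, pS > 0, ≥ 1 polymorphic site
and ≥ 1% polymorphic sites, and omit groups with fewer than three
qualifying genes; percent-polymorphic medians use all genes with ≥ 1
assayable codon. The per-site consensus profile reports the most frequent
amino acid among spanning reads (ties resolve to the reference amino
acid). Coverage correlations are standard Pearson r, null on degenerate
input.

## Synthetic communities and read simulation

The generator emulates the study conditions the pipeline is built for:
multi-kilobase scaffolds (8–12 kb, ≥ 5 kb floor) carrying 8–12 non-
overlapping, internal-stop-free ORFs of 80–250 aa on random strands, with
a 200-bp gene-free margin at scaffold ends so read windows are never
clipped; category proportions 20/30/15/10/25% for replication/structural/
metabolism/regulation/unknown. Viral scaffolds constructed to pass round 1
receive hits on max(3, 30%) of their genes drawn from groups with
quotients 0.7–1.0 (so AVQ ≥ 2.1 and percent ≥ 25 by construction);
non-viral scaffolds receive ~10% weak hits (quotients ≤ 0.3) and cannot
pass; planted round-2 recruits carry no group hits but max(3, 20%) of
their ORFs match a single round-1 scaffold under passing filters. Planted
taxonomy gives ~60% of ORFs reference hits to the planted family and a
smaller minority to a different one; planted hosts embed exactly one
verbatim signal per pair (32-bp spacer substring, identical 72-nt tRNA, or
1.5-kb shared segment), cycling signal types.

Reads are 150 bp single-end at constant Q40 (the pileup logic is agnostic
to pairing; pair structure, sequencing error, GC and amplification bias
are deliberately not modelled — recovery results therefore measure the
estimator under clean mapping, not robustness to artefacts). Read starts
are uniform over the window overlapping the gene, with read count set so
the expected fully-spanning coverage per codon equals the target.

Variant planting implements selection as an acceptance probability: a site
and one of its codon's 9 neighbours are drawn uniformly; synonymous
proposals are always accepted, nonsynonymous ones with probability alpha;
a rejected proposal redraws **both** the site and the neighbour. This
makes the expected planted N:S ratio exactly alpha·Σn_N : Σn_S over the
gene's codons, hence E[pN/pS] = alpha — rejected nonsynonymous
opportunities vanish from constrained sites, as purifying selection does.
(Redrawing only the neighbour at a fixed site would instead force variants
at nonsynonymous-only codons such as ATG/TGG and bias pN/pS upward at
small alpha.) Each planted site carries one variant codon at a
minor-allele frequency drawn from (0.05, 0.5); reads spanning the site
carry the variant by independent Bernoulli draws, so observed counts are
binomial at the realised coverage. Sites never spanned by a read are
dropped from the truth with a warning. RNG streams are derived per
scaffold/gene by stable hashing of the top-level seed and the id, so
adding a scaffold never perturbs the others and all outputs are
byte-identical given a seed.

Recovery studies (in `virodiv.experiments`) use 50 genes of 300 codons at
50× coverage: ~200 planted sites for the neutral (alpha = 1) study and 100
for the selection studies — at 200/300 density the without-replacement
site filling begins to exhaust synonymous-capable codons under strong
selection and biases the ratio upward, so the selection studies run at the
lower density where the estimator is calibration-clean; these sizes run in
seconds on one CPU. Measured medians: ≈ 1.02 at alpha = 1, ≈ 0.50 at 0.5,
≈ 0.10 at 0.1 (seed-dependent within a few percent).

## Pipeline and reproducibility

`virodiv run` executes simulate → classify → annotate → abundance →
microdiversity; stages communicate only via their documented files. The
manifest records the tool version, full threshold configuration
(defaults: avq 10%/2.0, bait 20%/3, snp 4/1%/5×, population 95/80), seeds,
per-stage row counts and SHA-256 checksums of all simulated inputs; an
identical config + seed reproduces identical manifests. All thresholds are
echoed to the log at startup. Config files are validated (unknown keys,
missing inputs) before any stage runs.

## Known limitations

- The population-clustering and homology detectors are diagonal/ungapped:
  adequate for near-identical or verbatim-planted relationships, not a
  replacement for alignment-based ANI on rearranged genomes.
- Reference bias is not modelled: reads are simulated from, and mapped to,
  the same assembly, so consensus-divergence effects on pN/pS are not
  exercised.
- Multi-allelic planted sites are not generated (the caller can plant two
  variants at one codon; the caller-facing API supports it).
- Taxonomy strings are consumed as-is; no taxonomy-database resolution.
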