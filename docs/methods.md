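# Methods

## Event model and canonical IDs

An alternative-splicing event is a local difference between two isoform
structures of one gene, typed as SE (skipped exon), MXE (mutually exclusive
exons), RI (retained intron), A5SS/A3SS (alternative donor/acceptor site),
or AF/AL (alternative first/last exon). The canonical ID is
`<gene>|<type>|<chrom>|<strand>|<c1>:...:<cn>` with `|` and `:` as
separators (neither occurs in chromosome names, including `_`-suffixed
scaffolds) and all coordinates 1-based inclusive, matching GTF and VCF.

The coordinate tuple is the ascending sorted set of splice coordinates that
determine the event. Its arity is fixed per type — SE 4, RI 4, MXE 6,
A5SS/A3SS 3, AF/AL 5 — and deliberately equals the number of distinct
coordinates carried by the corresponding SUPPA event string. This is the
smallest representation that every supported input dialect can produce, so
converter agreement is structural: rMATS rows, SUPPA strings and generic
rows for the same event are guaranteed to reduce to the same key, rather
than agreeing only after coordinate arithmetic. The cost is that the ID
does not pin down the far boundary of flanking exons (rMATS knows it, SUPPA
does not); flanking extents are recovered from the gene annotation when
needed. The grammar is stable across releases.

Strand resolves the geometric ambiguity of the 3- and 5-coordinate types:
A5SS on `+` and A3SS on `-` vary the left boundary of the coordinate
triple; AF on `+` and AL on `-` place the two alternative terminal exons at
the genomic left. For the dual-region types (MXE, AF, AL) the region
encountered first in transcript order is labelled inclusion-side.

## Region decomposition

`decompose_regions` maps an event to:

* **distinct region(s)** — the segment whose usage differs: the cassette
  exon `[c2, c3]` (SE), the retained intron `[c2+1, c3-1]` (RI), the
  alternative segment between the proximal and distal splice sites
  (A5SS/A3SS), or the two labelled exons (MXE/AF/AL);
* **common regions** — flanking constitutive anchors. Where the event tuple
  carries only a junction coordinate (SE, MXE, A5SS/A3SS, AF/AL) the anchor
  is the single junction-adjacent base; for RI the full flanking exons are
  known and used;
* **boundary windows** — `[site-w, site+w]` around the start and end of each
  distinct region. The default half-width w = 10 bp covers the core splice
  donor/acceptor consensus (the ±3–8 bp most often disrupted by
  splice-region variants) with margin; it is a parameter everywhere it is
  consumed;
* **flanking introns** — the intronic gaps adjoining the distinct
  region(s); empty gaps (adjacent features) are omitted.

A zero-length distinct region (an RI whose flanking exons are adjacent) is
a degenerate event and an error.

## Event enumeration from annotation

Transcript pairs are compared on their intron chains; an intron is the
junction pair (left exon end, right exon start). Introns unique to either
transcript are clustered by genomic overlap and each cluster is matched
against a decision table: 1-vs-0 introns with exonic coverage on the other
side is RI; 2-vs-1 sharing outer anchors with a single cassette exon is SE;
2-vs-2 sharing anchors with disjoint middle exons is MXE; 1-vs-1 sharing
one junction coordinate is a boundary event (A5SS/A3SS by strand) unless
both varying exons are transcript-terminal *and* disjoint, in which case
the terminal interpretation wins and the cluster is AF/AL. Everything else
(multi-exon skips, overlapping terminal exons, compound differences inside
one cluster) is reported as "complex" and excluded from the seven-type
output rather than silently dropped. `enumerate_events` is the
deduplicated, ID-sorted union over all transcript pairs of a gene, so it is
invariant to input order.

## Feature store

The feature database is a single SQLite file with one table per key level
(genomic interval / protein span / isoform) plus the gene model, and UNIQUE
constraints so rebuilding from identical inputs is idempotent and duplicate
records collapse. Genomic overlap queries use the 1-based inclusive
convention (a single shared base overlaps) and are checked against a
brute-force scan in the tests. BED input (0-based half-open) is shifted on
ingestion; VCF contributes site records only (genotypes ignored); exon
usage arrives as a TSV with one PSI column per sample and is stored as a
genomic-interval class with a sample→PSI payload — no cohort ships with the
package.

Protein-space records (domains, PTM sites) reach the genome through a
strand-aware codon projection: amino acids `a..b` map to the CDS nucleotide
range `3(a-1)+1 .. 3b`, walked across CDS exons in translation order, so a
codon can split across a junction and segment lengths always sum to three
per residue. The inverse mapping (used by the fixture generator) reports
only complete codons. Records whose isoform lacks an annotated CDS are
skipped with a warning count.

## Annotation rules and the 23-column table

Each of the 12 feature classes is consumed by exactly one rule:
conservation, repeats, miRNA sites and exon usage over the distinct
region(s); point mutations and splice-site variants over distinct ∪
boundary windows; RBP/splicing-factor sites over (distinct ∪ flanking
introns) minus common regions — the subtraction is interval arithmetic
applied *before* querying, so a site straddling the boundary is truncated
and kept iff ≥ 1 bp remains; domains and PTMs are projected to the genome
and intersected with the distinct region only; NMD, PPI and localisation
are resolved through the inclusion/exclusion isoform partition. For
dual-region events the rules apply to both regions and results are tagged
by side. NMD uses the 50-nt rule (stop codon strictly more than 50 nt
upstream of the final exon–exon junction in mRNA coordinates); a side is
"sensitive" if any of its CDS-bearing isoforms is, "unknown" if none
carries a CDS. It is derived per event from the annotation at query time,
not precomputed. An interaction partner is inclusion-specific iff its edges
touch at least one inclusion isoform and no exclusion isoform; partners
touching neither side (edges only on uninformative isoforms) are reported
as shared.

The output schema is fixed at 23 columns regardless of which classes are
populated: event ID, gene, type, chrom, strand, coords, p, FDR, dPSI, then
14 feature columns covering the 12 classes, with DOMAIN and PTM each
carrying a protein-space and a genome-space column. The composition is this
package's own stable definition; schema stability is favoured over
guessing any particular external layout.

## Statistics

Enrichment is a hypergeometric over-representation test of the unranked
differentially spliced gene list — the input is a gene list, not a ranked
expression profile, so a ranked-walk GSEA would have no natural ranking to
consume. Set membership and the query are intersected with the universe
before sizing; sets with effective size < 20 (configurable) are excluded;
p = P(X ≥ k) with Benjamini–Hochberg adjustment across tested sets. The
default universe is the annotation's gene complement, overridable.
Feature dependency is a two-sided Fisher exact test over the event-level
2×2 presence/absence table (sidedness chosen to penalise both co-occurrence
and avoidance); an all-zero margin is a degenerate-table error rather than
a p-value.

## Synthetic fixtures

The generator builds one planted event per gene on a short contig (genes
10 kb apart, ≈3 kb gene bodies), two transcripts realising the inclusion
and exclusion forms, CDS on both (30 bp terminal trims, with a 30 %
chance of an early stop in the penultimate exon to exercise NMD), and an
extra shared exon so transcripts carry at least two junctions. Strand is
random; for strand-asymmetric types the geometry is mirrored so the planted
label matches what the classifier must report. Defaults — 50 genes, a
uniform mix over the seven types, feature density 0.6 per class, half of
events significant with |dPSI| ≈ 0.3–0.5, p < 0.05 — describe a small
cohort with clearly differential events at the effect size the field
treats as meaningful.

Feature tracks are planted deliberately inside the class's query region or
deliberately outside it (decoys on common exons, 1 bp beyond boundary
windows, or intergenic), and the per-event expectation is recorded as a
ledger the annotation run must reproduce exactly. Gene-set fixtures draw
decoy sets uniformly and admit each universe gene to the query with
probability sigmoid(logit(0.15) + 3·[gene ∈ target]); log-odds 0 makes the
target indistinguishable from the decoys, which is the null used for rank
calibration. All generators are pure functions of the spec: one master
seed, independent spawned streams per generator, byte-identical outputs on
repeat.

What the fixtures do *not* emulate: nucleotide sequence (the pipeline is
coordinate- and identifier-driven), overlapping genes, multi-event genes,
realistic exon length/GC distributions, read-level noise, or annotation
errors. Passing tests therefore demonstrate correctness of the conversion,
region logic and statistics — not robustness to messy real-world
annotation, which is limited by the user's tracks.

## Numerical and design choices

* Coordinates are 1-based inclusive at every interface; only BED ingestion
  converts.
* Boundary windows must stay on-contig (`site > w`), otherwise a validation
  error: windows are never silently clipped, so their width invariant
  (2w+1) always holds.
* Rows whose statistics fail to parse keep their event with absent stats;
  significance filtering (p, |dPSI|) is an explicit caller choice exposed as
  flags, never hard-coded.
* Conversion reports count rows, not events: a spliceR-style row can emit
  several events (all carrying the row's statistics) or legitimately none
  (identical isoform pair); the accounting identity input = converted +
  duplicates + failed holds in all cases.
* Odds ratios use the sample (a·d)/(b·c) with Haldane 0.5 on all cells iff
  any cell is zero; the Fisher p always comes from the uncorrected table.
* Figures are verified via JSON sidecars (lane labels, edge counts, bar
  order), not pixels; layouts use fixed seeds.
* Problem sizes in the test and acceptance runs (≤ 220 genes, 1000 records
  × 100 queries, 200 enrichment replicates) were chosen so every
  brute-force oracle remains exact and sub-second while exercising all
  seven types and every rule edge case.

## Known limitations

* Single-gene, single-chromosome-namespace model: chromosome names are
  plain strings, no liftover between genome builds.
* AF/AL detection requires disjoint terminal exons; overlapping alternative
  promoters/terminators fall back to A5SS/A3SS or "complex".
* The NMD rule is the positional 50-nt heuristic; it ignores uORFs, long
  3'UTR effects and EJC-independent decay.
* No de novo discovery from reads/BAMs and no PSI computation: events come
  from annotation comparison or caller output only.
* The isoform-PPI partition trusts the user's edge list; it does not model
  domain-mediated interface loss beyond isoform membership.
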