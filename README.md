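# splicescope

Junction-incorporating, multi-omic annotation of alternative-splicing (AS)
events.

Differential-splicing callers (rMATS, SUPPA, spliceR, ...) tell you *which*
exons change between conditions, but not *why* they matter: the skipped exon
and its flanking regions carry splice-site variants, splicing-factor binding
sites, conserved and repeat elements, miRNA target sites, protein domains
and modification sites, and they decide whether an isoform is degraded by
nonsense-mediated decay or rewires its protein interactions. `splicescope`
collects that evidence per event, for analysts working downstream of bulk or
single-cell RNA-seq splicing analysis, with no hosted database: every
feature arrives as a user-supplied standard track (GTF, BED, VCF, TSV, gmt)
and lives in a single local SQLite file.

## What it does

1. **Canonical event IDs.** Each event is one of seven types — SE, MXE, RI,
   A5SS, A3SS, AF, AL — identified by
   `<gene>|<type>|<chrom>|<strand>|<c1>:<c2>:...:<cn>` where the `c_i` are the
   ascending 1-based splice coordinates that determine the event (SE and RI
   use 4, MXE 6, A5SS/A3SS 3, AF/AL 5). Converters map rMATS `*.MATS.JC.txt`,
   SUPPA `.dpsi`/`.ioe`, spliceR-style isoform pairs and a generic TSV onto
   these IDs, so the same event from any caller collapses onto one key.
   Isoform-level input passes through a two-step conversion: isoform ids →
   exon chains (via the annotation), then exon chains → events (intron-chain
   comparison).
2. **Region-rule annotation.** Each event decomposes into distinct region(s)
   (the cassette exon, retained intron, alternative segment or terminal
   exons), common flanking anchors, ±w bp splice-site boundary windows
   (default w = 10), and flanking introns. Twelve feature classes are
   queried each through its own rule (e.g. point mutations over distinct ∪
   boundaries; domains/PTMs projected from protein to genome coordinates and
   intersected with the distinct region only; RBP sites over distinct ∪
   introns minus common regions). NMD sensitivity is derived per isoform
   side with the 50-nt rule: a stop codon more than 50 nt upstream of the
   final exon–exon junction. The result is a fixed 23-column table (9
   identity/statistics columns + 14 feature columns covering the 12 classes).
3. **Knowledge-based statistics.** Over-representation of the
   differentially spliced gene list in gmt gene sets uses the hypergeometric
   upper tail P(X ≥ k) with Benjamini–Hochberg adjustment, testing only sets
   of effective size ≥ 20; pairwise feature dependency uses a two-sided
   Fisher exact test on the 2×2 presence/absence table with odds ratio
   (a·d)/(b·c) (Haldane 0.5 correction when a cell is zero).
4. **Outputs.** CSV tables, genome-track / PPI-network / enrichment-bar
   figures with JSON sidecar metadata, and a seeded synthetic-fixture
   generator that emulates every input dialect with planted, checkable
   structure.

## Worked example

```python
import tempfile
import splicescope as ss

spec = ss.FixtureSpec(seed=8, n_genes=15)          # one planted event per gene
_, truth, ann = ss.simulate_annotation(spec)

with tempfile.TemporaryDirectory() as tmp:
    tracks, _ = ss.simulate_feature_tracks(truth, spec, ann, tmp)
    db = ss.build_db(ann, tracks, f"{tmp}/features.sqlite")
    events = [ss.decode_event_id(i) for i in truth["event_id"]]
    table = ss.annotate_events(events, db, ann)
print(table.shape)
```

prints `(15, 23)` — 15 events, 23 columns. One feature-rich row
(`examples/02_annotate_features.py` prints it in full):

```
event_id             GENE0007|A3SS|chr1|+|71199:73196:73400
CONS                 CONS_GENE0007@73201-73221
MUT                  MUT_GENE0007@73186-73186
NMD                  inclusion:not_sensitive|exclusion:not_sensitive
DOMAIN               DOMAIN_GENE0007@57-125(GENE0007.T1)
DOMAIN_genomic       73196-73400
PPI                  inclusion:PARTNER_GENE0007_INC|shared:PARTNER_GENE0007_SH
LOCALIZATION         inclusion:nucleus
```

The alternative acceptor segment spans 73196–73399; the conservation
element, the variant in the −10 bp boundary window, the domain whose codons
project onto the segment, and the inclusion-isoform-specific interaction
partner are all reported against it, while features planted on common exons
stay silent. Running `examples/03_enrichment_and_dependency.py` on a
synthetic cohort with a +3 log-odds planted pathway prints:

```
SET_TARGET   overlap 24/30  p=3.12e-15  p_adj=6.55e-14
SET_019      overlap 10/30  p=0.0125    p_adj=0.131
```

— the planted set wins by thirteen orders of magnitude.

The `splicescope` command exposes the same workflow as subcommands
(`simulate`, `build-db`, `convert`, `annotate`, `enrich`, `depend`, `plot`);
each run writes a JSON log sufficient to re-run it.

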