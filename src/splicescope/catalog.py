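"""Transcript annotation and enumeration of AS events from exon chains.

Event classification works on *intron chains* (junction sets).  For a pair
of transcripts of the same gene, the introns unique to either transcript are
clustered by genomic overlap; each cluster is matched against a decision
table keyed on the number and anchoring of the differing introns:

=====================================  =========================================
pattern inside one cluster             classification
=====================================  =========================================
1 intron vs 0 (other side exonic)      RI
2 introns vs 1, shared outer anchors   SE (one cassette exon)
2 vs 2, shared anchors, disjoint exons MXE
1 vs 1 sharing the right coordinate    A5SS(+)/A3SS(-), or AF(+)/AL(-) when both
                                       varying exons are transcript-initial and
                                       disjoint (terminal position wins)
1 vs 1 sharing the left coordinate     A3SS(+)/A5SS(-), or AL(+)/AF(-) when both
                                       varying exons are transcript-final and
                                       disjoint
anything else                          unclassified ("complex"), reported but
                                       excluded from the seven-type output
=====================================  =========================================

An intron is represented by its junction pair ``(d, a)`` where ``d`` is the
last base of the left exon and ``a`` the first base of the right exon
(intronic bases are ``[d+1, a-1]``, 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .events import (
    ASEvent,
    GenomicInterval,
    ValidationError,
    decompose_regions,
    encode_event_id,
)


class IncompatiblePairError(ValueError):
    """Transcript pair differs in gene, chromosome, or strand."""


class GeneNotFoundError(KeyError):
    """Requested gene absent from the annotation."""


@dataclass(frozen=True)
class Transcript:
    """One annotated isoform: an ordered exon chain and optional CDS."""

    tx_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple
    cds: Optional[tuple] = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValidationError("exons: transcript must have >= 1 exon")
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"exons: overlapping/adjacent-disordered exons {a} and {b} in {self.tx_id}"
                )
        if self.cds is not None:
            cds = tuple(sorted(self.cds, key=lambda e: (e.start, e.end)))
            object.__setattr__(self, "cds", cds)
            for seg in cds:
                if not any(e.contains(seg) for e in exons):
                    raise ValidationError(
                        f"cds: segment {seg} outside exons of {self.tx_id}"
                    )

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Junction pairs (left exon end, right exon start)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def covers_exonic(self, start: int, end: int) -> bool:
        """True if [start, end] is fully contained in a single exon."""
        return any(e.start <= start and end <= e.end for e in self.exons)

    def exon_ending_at(self, pos: int) -> Optional[GenomicInterval]:
        for e in self.exons:
            if e.end == pos:
                return e
        return None

    def exon_starting_at(self, pos: int) -> Optional[GenomicInterval]:
        for e in self.exons:
            if e.start == pos:
                return e
        return None


@dataclass
class Annotation:
    """A gene annotation: transcripts indexed by id and by gene."""

    transcripts: Dict[str, Transcript] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_gene: Dict[str, List[str]] = {}
        for tx in self.transcripts.values():
            self._by_gene.setdefault(tx.gene, []).append(tx.tx_id)
        for ids in self._by_gene.values():
            ids.sort()

    @property
    def genes(self) -> List[str]:
        return sorted(self._by_gene)

    def gene_transcripts(self, gene: str) -> List[Transcript]:
        if gene not in self._by_gene:
            raise GeneNotFoundError(gene)
        return [self.transcripts[t] for t in self._by_gene[gene]]

    def __getitem__(self, tx_id: str) -> Transcript:
        return self.transcripts[tx_id]

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self.transcripts


def load_gtf(path: str) -> Annotation:
    """Read a GTF (Ensembl or RefSeq dialect) into an :class:`Annotation`.

    Uses :mod:`gffutils` with an in-memory database; tolerant of unsorted
    input.  Only ``exon`` and ``CDS`` features with ``transcript_id`` and
    ``gene_id`` attributes are consumed; ``gene_name`` is preferred over
    ``gene_id`` as the gene key when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    meta: Dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_ids = feat.attributes.get("transcript_id")
        gene_ids = feat.attributes.get("gene_name") or feat.attributes.get("gene_id")
        if not tx_ids or not gene_ids:
            continue
        tx_id = tx_ids[0]
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        meta.setdefault(tx_id, (gene_ids[0], feat.seqid, feat.strand))
        (exons if feat.featuretype == "exon" else cds).setdefault(tx_id, []).append(iv)
    transcripts = {}
    for tx_id, exon_list in exons.items():
        gene, chrom, strand = meta[tx_id]
        transcripts[tx_id] = Transcript(
            tx_id=tx_id,
            gene=gene,
            chrom=chrom,
            strand=strand,
            exons=tuple(exon_list),
            cds=tuple(cds[tx_id]) if tx_id in cds else None,
        )
    return Annotation(transcripts)


def _cluster_differing_introns(da: Sequence, db_: Sequence) -> List[Tuple[list, list]]:
    """Group differing introns from the two transcripts by genomic overlap."""
    tagged = [(d, a, 0) for d, a in da] + [(d, a, 1) for d, a in db_]
    tagged.sort()
    clusters: List[Tuple[list, list]] = []
    cur_a: list = []
    cur_b: list = []
    cur_end = None
    for d, a, side in tagged:
        if cur_end is not None and d + 1 > cur_end:  # no overlap of intronic spans
            clusters.append((cur_a, cur_b))
            cur_a, cur_b, cur_end = [], [], None
        (cur_a if side == 0 else cur_b).append((d, a))
        cur_end = a - 1 if cur_end is None else max(cur_end, a - 1)
    if cur_a or cur_b:
        clusters.append((cur_a, cur_b))
    return clusters


def _classify_cluster(
    ia: List[Tuple[int, int]],
    ib: List[Tuple[int, int]],
    tx_a: Transcript,
    tx_b: Transcript,
) -> Optional[ASEvent]:
    """Match one cluster of differing introns against the decision table.

    Returns ``None`` for unclassifiable ("complex") clusters.
    """
    strand = tx_a.strand
    gene, chrom = tx_a.gene, tx_a.chrom
    mk = lambda et, coords: ASEvent(
        gene=gene, event_type=et, chrom=chrom, strand=strand, coords=tuple(coords)
    )

    # RI: an intron on one side only, exonically covered on the other
    for one, other_tx in (((ia, ib), tx_b), ((ib, ia), tx_a)):
        side, empty = one
        if len(side) == 1 and not empty:
            d, a = side[0]
            if other_tx.covers_exonic(d, a) and a > d + 1:
                spliced = tx_a if other_tx is tx_b else tx_b
                up = spliced.exon_ending_at(d)
                down = spliced.exon_starting_at(a)
                if up is not None and down is not None:
                    return mk("RI", (up.start, d, a, down.end))
            return None

    # SE: one intron vs two sharing its anchors, with a single cassette exon
    for two, one, inc_tx in ((ia, ib, tx_a), (ib, ia, tx_b)):
        if len(two) == 2 and len(one) == 1:
            (d1, s), (e, a1) = sorted(two)
            d, a = one[0]
            if d1 == d and a1 == a and s <= e:
                exon = inc_tx.exon_starting_at(s)
                if exon is not None and exon.end == e:
                    return mk("SE", (d, s, e, a))
            return None

    if len(ia) == 2 and len(ib) == 2:
        (d1, s1), (e1, a1) = sorted(ia)
        (d2, s2), (e2, a2) = sorted(ib)
        if d1 == d2 and a1 == a2:
            x1 = tx_a.exon_starting_at(s1)
            x2 = tx_b.exon_starting_at(s2)
            if x1 is not None and x2 is not None and x1.end == e1 and x2.end == e2:
                if e1 < s2:
                    return mk("MXE", (d1, s1, e1, s2, e2, a1))
                if e2 < s1:
                    return mk("MXE", (d1, s2, e2, s1, e1, a1))
        return None

    if len(ia) == 1 and len(ib) == 1:
        (da_, aa), (db_, ab) = ia[0], ib[0]
        if aa == ab and da_ != db_:
            # varying left boundary, shared acceptor-side coordinate
            lo, hi = min(da_, db_), max(da_, db_)
            xa, xb = tx_a.exon_ending_at(da_), tx_b.exon_ending_at(db_)
            if xa is None or xb is None:
                return None
            terminal = (tx_a.exons[0] == xa) and (tx_b.exons[0] == xb)
            disjoint = xa.end < xb.start or xb.end < xa.start
            if terminal and disjoint:
                first, second = sorted([xa, xb], key=lambda e: e.start)
                et = "AF" if strand == "+" else "AL"
                return mk(et, (first.start, first.end, second.start, second.end, aa))
            et = "A5SS" if strand == "+" else "A3SS"
            return mk(et, (lo, hi, aa))
        if da_ == db_ and aa != ab:
            lo, hi = min(aa, ab), max(aa, ab)
            xa, xb = tx_a.exon_starting_at(aa), tx_b.exon_starting_at(ab)
            if xa is None or xb is None:
                return None
            terminal = (tx_a.exons[-1] == xa) and (tx_b.exons[-1] == xb)
            disjoint = xa.end < xb.start or xb.end < xa.start
            if terminal and disjoint:
                first, second = sorted([xa, xb], key=lambda e: e.start)
                et = "AL" if strand == "+" else "AF"
                return mk(et, (da_, first.start, first.end, second.start, second.end))
            et = "A3SS" if strand == "+" else "A5SS"
            return mk(et, (da_, lo, hi))
        return None

    return None


def classify_transcript_pair(
    tx_a: Transcript,
    tx_b: Transcript,
    unclassified: Optional[list] = None,
) -> List[ASEvent]:
    """Classify every local exon-chain difference between two isoforms.

    Returns the classifiable events (each one of the seven types).  Clusters
    of differing introns that match no pattern are appended to
    ``unclassified`` (as ``(introns_a, introns_b)`` tuples) when a list is
    supplied, so complex differences are reported rather than silently
    dropped.
    """
    if (tx_a.gene, tx_a.chrom, tx_a.strand) != (tx_b.gene, tx_b.chrom, tx_b.strand):
        raise IncompatiblePairError(
            f"{tx_a.tx_id} and {tx_b.tx_id} differ in gene/chrom/strand"
        )
    set_a, set_b = set(tx_a.introns), set(tx_b.introns)
    da = sorted(set_a - set_b)
    db_ = sorted(set_b - set_a)
    events: List[ASEvent] = []
    for ia, ib in _cluster_differing_introns(da, db_):
        ev = _classify_cluster(ia, ib, tx_a, tx_b)
        if ev is None:
            ev = _classify_cluster(ib, ia, tx_b, tx_a)
        if ev is not None:
            events.append(ev)
        elif unclassified is not None:
            unclassified.append((tuple(ia), tuple(ib)))
    return events


def enumerate_events(
    annotation: Annotation,
    gene: str,
    unclassified: Optional[list] = None,
) -> List[ASEvent]:
    """All distinct events implied by pairwise comparison of a gene's isoforms.

    The result equals the deduplicated union of
    :func:`classify_transcript_pair` over all transcript pairs, ordered by
    canonical ID (hence invariant to transcript input order).
    """
    txs = annotation.gene_transcripts(gene)
    seen: Dict[str, ASEvent] = {}
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for ev in classify_transcript_pair(txs[i], txs[j], unclassified):
                seen.setdefault(encode_event_id(ev), ev)
    return [seen[k] for k in sorted(seen)]


def map_transcripts_to_event(
    event: ASEvent, annotation: Annotation
) -> Tuple[List[str], List[str]]:
    """Partition a gene's isoforms into inclusion / exclusion sets.

    A transcript is *inclusion* when the event's inclusion-side distinct
    region is fully exonic in it; *exclusion* when it either splices the
    region out (an intron covers it) or, for dual-region events, carries the
    exclusion-side region instead.  Transcripts doing neither (e.g. ending
    before the locus) are not informative and belong to neither set.
    """
    regions = decompose_regions(event, 0)
    inc_region = regions.inclusion_side
    exc_region = regions.exclusion_side
    inclusion: List[str] = []
    exclusion: List[str] = []
    for tx in annotation.gene_transcripts(event.gene):
        if tx.chrom != event.chrom or tx.strand != event.strand:
            continue
        has_inc = tx.covers_exonic(inc_region.start, inc_region.end)
        has_exc = (
            exc_region is not None
            and tx.covers_exonic(exc_region.start, exc_region.end)
        )
        if has_inc and not has_exc:
            inclusion.append(tx.tx_id)
        elif has_exc and not has_inc:
            exclusion.append(tx.tx_id)
        elif not has_inc and not has_exc and exc_region is None:
            # single-region event: exclusion iff an intron spans the region
            for d, a in tx.introns:
                if d < inc_region.start and inc_region.end < a:
                    exclusion.append(tx.tx_id)
                    break
    return inclusion, exclusion
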