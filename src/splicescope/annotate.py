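"""Event annotation: class-specific region rules and the 23-column table.

Each of the 12 feature classes is consumed by exactly one region rule:

================  =========================================  ========
class             region queried                             level
================  =========================================  ========
CONS              distinct                                   genomic
REPEAT            distinct                                   genomic
MIRNA_BS          distinct                                   genomic
EXON_USAGE        distinct                                   genomic
MUT               distinct + splice-site boundary windows    genomic
SPLICE_SITE_VAR.  distinct + splice-site boundary windows    genomic
RBP_BS            (distinct + flanking introns) - common     genomic
DOMAIN            protein span projected to genome,          isoform
                  overlapped with distinct only
PTM               same as DOMAIN                             isoform
NMD               derived from CDS vs last junction (50-nt)  isoform
PPI               inclusion/exclusion isoform partition      isoform
LOCALIZATION      inclusion/exclusion isoform partition      isoform
================  =========================================  ========

The common-region subtraction for RBP_BS is an interval subtraction applied
*before* querying, so a binding site straddling the boundary is truncated
and kept iff the residual overlap is at least 1 bp.

The output row has exactly 23 fixed columns: 9 identity/statistics columns
followed by 14 feature columns covering the 12 classes (DOMAIN and PTM each
carry a protein-space and a genome-space column).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pandas as pd

from .catalog import Annotation, Transcript, map_transcripts_to_event
from .events import (
    ASEvent,
    EventRegions,
    GenomicInterval,
    decompose_regions,
    encode_event_id,
    subtract_intervals,
)
from .store import (
    FeatureDB,
    GENOMIC_CLASSES,
    PROTEIN_CLASSES,
    project_protein_to_genome,
)

#: fixed 23-column schema of the annotation table
ANNOTATION_COLUMNS = (
    "event_id", "gene", "event_type", "chrom", "strand", "coords",
    "p_value", "fdr", "dpsi",
    "CONS", "MUT", "REPEAT", "MIRNA_BS", "NMD", "RBP_BS", "EXON_USAGE",
    "DOMAIN", "DOMAIN_genomic", "PTM", "PTM_genomic",
    "PPI", "LOCALIZATION", "SPLICE_SITE_VARIANT",
)

#: the 12 feature-class groups behind the 14 feature columns
FEATURE_CLASS_GROUPS = (
    "CONS", "MUT", "REPEAT", "MIRNA_BS", "NMD", "RBP_BS", "EXON_USAGE",
    "DOMAIN", "PTM", "PPI", "LOCALIZATION", "SPLICE_SITE_VARIANT",
)

#: region selector per class (genomic classes only; see module docstring)
REGION_RULES: Dict[str, frozenset] = {
    "CONS": frozenset({"distinct"}),
    "REPEAT": frozenset({"distinct"}),
    "MIRNA_BS": frozenset({"distinct"}),
    "EXON_USAGE": frozenset({"distinct"}),
    "MUT": frozenset({"distinct", "boundaries"}),
    "SPLICE_SITE_VARIANT": frozenset({"distinct", "boundaries"}),
    "RBP_BS": frozenset({"distinct", "flanking_introns", "common-excluded"}),
}

#: threshold of the NMD positional rule: a stop codon more than this many
#: nucleotides upstream of the final exon-exon junction marks the transcript
#: as NMD-sensitive.
NMD_RULE_NT = 50


def _dedupe(items: List[str]) -> List[str]:
    return sorted(set(items))


def _digest_genomic(records) -> str:
    return ";".join(
        _dedupe([f"{r.name}@{r.interval.start}-{r.interval.end}" for r in records])
    )


def _rule_regions(regions: EventRegions, selector: frozenset) -> List[GenomicInterval]:
    """Materialise the query intervals for one class rule."""
    out: List[GenomicInterval] = []
    if "distinct" in selector:
        out.extend(regions.distinct)
    if "boundaries" in selector:
        out.extend(regions.boundaries)
    if "flanking_introns" in selector:
        out.extend(regions.flanking_introns)
    if "common-excluded" in selector:
        out = subtract_intervals(out, regions.common)
    return out


def transcript_nmd_sensitive(tx: Transcript) -> Optional[bool]:
    """Apply the 50-nt rule to one transcript.

    Returns ``None`` when the transcript has no CDS, ``True`` when the stop
    codon (last CDS base) lies more than :data:`NMD_RULE_NT` nucleotides
    upstream of the final exon-exon junction in mRNA coordinates.
    Single-exon transcripts are never sensitive.
    """
    if tx.cds is None:
        return None
    if len(tx.exons) < 2:
        return False
    exons = list(tx.exons) if tx.strand == "+" else list(reversed(tx.exons))
    # mRNA coordinate of the last base of the CDS
    cds_last_genomic = tx.cds[-1].end if tx.strand == "+" else tx.cds[0].start
    pos = 0
    stop_mrna = None
    for exon in exons:
        bases = (
            range(exon.start, exon.end + 1)
            if tx.strand == "+"
            else range(exon.end, exon.start - 1, -1)
        )
        for b in bases:
            pos += 1
            if b == cds_last_genomic:
                stop_mrna = pos
        if stop_mrna is not None:
            break
    if stop_mrna is None:  # CDS end not on an exon: malformed, treat as unknown
        return None
    last_junction_mrna = sum(e.width for e in exons[:-1])
    return (last_junction_mrna - stop_mrna) > NMD_RULE_NT


def call_nmd(event: ASEvent, annotation: Annotation) -> Dict[str, str]:
    """Per-side NMD sensitivity of an event.

    A side is ``"sensitive"`` when at least one of its isoforms with an
    annotated CDS satisfies the 50-nt rule, ``"not_sensitive"`` when at least
    one isoform has a CDS and none is sensitive, and ``"unknown"`` when no
    isoform on that side carries a CDS.
    """
    inclusion, exclusion = map_transcripts_to_event(event, annotation)
    out = {}
    for side, tx_ids in (("inclusion", inclusion), ("exclusion", exclusion)):
        flags = [
            transcript_nmd_sensitive(annotation[t])
            for t in tx_ids
            if annotation[t].cds is not None
        ]
        if not flags:
            out[side] = "unknown"
        elif any(flags):
            out[side] = "sensitive"
        else:
            out[side] = "not_sensitive"
    return out


def assign_isoform_ppi(
    event: ASEvent, db: FeatureDB, annotation: Annotation
) -> Tuple[List[str], List[str], List[str]]:
    """Partition interaction partners into inclusion-specific /
    exclusion-specific / shared.

    A partner is inclusion-specific iff its edges touch at least one
    inclusion isoform and no exclusion isoform (symmetrically for
    exclusion); every other partner (both sides, or only uninformative
    isoforms) is shared.
    """
    inclusion, exclusion = map_transcripts_to_event(event, annotation)
    all_tx = [tx.tx_id for tx in annotation.gene_transcripts(event.gene)]
    edges = db.query_isoform_features(all_tx, classes=("PPI",))
    partners: Dict[str, set] = {}
    for rec in edges:
        partners.setdefault(rec.partner or rec.name, set()).add(rec.isoform)
    inc_set, exc_set = set(inclusion), set(exclusion)
    inc_specific, exc_specific, shared = [], [], []
    for partner in sorted(partners):
        isoforms = partners[partner]
        hits_inc = bool(isoforms & inc_set)
        hits_exc = bool(isoforms & exc_set)
        if hits_inc and not hits_exc:
            inc_specific.append(partner)
        elif hits_exc and not hits_inc:
            exc_specific.append(partner)
        else:
            shared.append(partner)
    return inc_specific, exc_specific, shared


def annotate_event(
    event: ASEvent,
    db: FeatureDB,
    annotation: Optional[Annotation] = None,
    boundary_halfwidth: int = 10,
) -> Dict[str, object]:
    """Build the full 23-column annotation row for one event."""
    ann = annotation if annotation is not None else db.annotation
    regions = decompose_regions(event, boundary_halfwidth)
    st = event.stats
    row: Dict[str, object] = {
        "event_id": encode_event_id(event),
        "gene": event.gene,
        "event_type": event.event_type,
        "chrom": event.chrom,
        "strand": event.strand,
        "coords": ":".join(map(str, event.coords)),
        "p_value": st.p_value if st else None,
        "fdr": st.fdr if st else None,
        "dpsi": st.dpsi if st else None,
    }

    for cls, selector in REGION_RULES.items():
        hits = []
        for iv in _rule_regions(regions, selector):
            hits.extend(db.query_interval(iv.chrom, iv.start, iv.end, classes=(cls,)))
        row[cls] = _digest_genomic(hits)

    # DOMAIN / PTM: protein records of the gene's isoforms, projected to the
    # genome and overlapped with the distinct region(s) only
    gene_tx = [tx for tx in ann.gene_transcripts(event.gene)]
    prot_records = db.query_isoform_features(
        [tx.tx_id for tx in gene_tx], classes=PROTEIN_CLASSES
    )
    for cls in PROTEIN_CLASSES:
        prot_digest, genome_digest = [], []
        for rec in (r for r in prot_records if r.feature_class == cls):
            try:
                segments = project_protein_to_genome(
                    ann, rec.isoform, rec.aa_start, rec.aa_end
                )
            except (KeyError, ValueError):
                continue
            overlapping = [
                seg for seg in segments
                if any(seg.overlaps(d) for d in regions.distinct)
            ]
            if overlapping:
                prot_digest.append(f"{rec.name}@{rec.aa_start}-{rec.aa_end}({rec.isoform})")
                genome_digest.extend(f"{seg.start}-{seg.end}" for seg in overlapping)
        row[cls] = ";".join(_dedupe(prot_digest))
        row[f"{cls}_genomic"] = ";".join(_dedupe(genome_digest))

    nmd = call_nmd(event, ann)
    row["NMD"] = f"inclusion:{nmd['inclusion']}|exclusion:{nmd['exclusion']}"

    inc_p, exc_p, shared_p = assign_isoform_ppi(event, db, ann)
    ppi_parts = []
    if inc_p:
        ppi_parts.append("inclusion:" + ",".join(inc_p))
    if exc_p:
        ppi_parts.append("exclusion:" + ",".join(exc_p))
    if shared_p:
        ppi_parts.append("shared:" + ",".join(shared_p))
    row["PPI"] = "|".join(ppi_parts)

    inclusion, exclusion = map_transcripts_to_event(event, ann)
    loc_records = db.query_isoform_features(
        inclusion + exclusion, classes=("LOCALIZATION",)
    )
    loc_parts = []
    for side, side_set in (("inclusion", set(inclusion)), ("exclusion", set(exclusion))):
        comps = _dedupe([r.name for r in loc_records if r.isoform in side_set])
        if comps:
            loc_parts.append(f"{side}:" + ",".join(comps))
    row["LOCALIZATION"] = "|".join(loc_parts)

    return row


def assemble_table(rows: List[Dict[str, object]]) -> pd.DataFrame:
    """Stack annotation rows into the fixed 23-column table (input order)."""
    df = pd.DataFrame(list(rows), columns=list(ANNOTATION_COLUMNS))
    return df


def annotate_events(
    events: List[ASEvent],
    db: FeatureDB,
    annotation: Optional[Annotation] = None,
    boundary_halfwidth: int = 10,
) -> pd.DataFrame:
    """Annotate a list of events and assemble the table."""
    rows = [
        annotate_event(ev, db, annotation, boundary_halfwidth) for ev in events
    ]
    return assemble_table(rows)
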