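"""Seeded synthetic fixtures: annotation, DAS outputs, feature tracks, gene sets.

Every generator is a pure function of a :class:`FixtureSpec` (seed
included): identical specs give byte-identical output files.  Sub-generators
draw from independent RNG streams spawned from the master seed with fixed
spawn keys, so adding a generator never perturbs the output of an earlier
one.

The simulated genome is deliberately coordinate-only (no nucleotide
sequence): one short contig, one planted AS event per gene, two isoforms
realising the inclusion and exclusion forms, and an optional shared extra
exon so transcripts carry at least two junctions.  The truth table records
each planted event's canonical ID together with the geometry needed to
re-express it in every supported input dialect.

Feature tracks are planted deliberately *inside* the region each class rule
queries (expected to annotate) or deliberately *outside* it (decoys,
expected silent), including +/-1 bp edge cases at the splice-site boundary
windows; the per-event expectation is returned as the ledger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import Annotation, Transcript
from .converters import events_to_frame
from .enrich import GeneSet, write_gmt
from .events import (
    ASEvent,
    DASRecord,
    EVENT_TYPES,
    GenomicInterval,
    decompose_regions,
    encode_event_id,
)
from .store import genome_to_protein

TRACK_CLASSES = (
    "CONS", "MUT", "REPEAT", "MIRNA_BS", "RBP_BS", "EXON_USAGE",
    "DOMAIN", "PTM", "PPI", "LOCALIZATION", "SPLICE_SITE_VARIANT",
)

#: event types expressible in rMATS JC output
RMATS_TYPES = ("SE", "MXE", "RI", "A5SS", "A3SS")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a small but structurally complete cohort: 50 genes
    (one planted event each, all seven types represented), moderate feature
    densities, half the events differentially spliced with |dPSI| around
    0.3 — the scale of effect the field treats as clearly differential.
    """

    seed: int = 0
    n_genes: int = 50
    chrom: str = "chr1"
    gene_spacing: int = 10_000
    type_mix: Dict[str, float] = field(
        default_factory=lambda: {t: 1 / 7 for t in EVENT_TYPES}
    )
    feature_density: Dict[str, float] = field(
        default_factory=lambda: {c: 0.6 for c in TRACK_CLASSES}
    )
    decoy_density: float = 0.5
    frac_significant: float = 0.5
    dpsi_magnitude: float = 0.3
    boundary_halfwidth: int = 10
    # gene-set generator
    n_sets: int = 20
    set_size: int = 30
    target_logodds: float = 3.0
    base_rate: float = 0.15

    def __post_init__(self) -> None:
        total = sum(self.type_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type_mix proportions must sum to 1, got {total}")
        if any(d < 0 for d in self.feature_density.values()):
            raise ValueError("feature densities must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent RNG stream with a fixed spawn key."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def _make_cds(exons: Sequence[GenomicInterval], strand: str,
              early_stop: bool) -> Tuple[GenomicInterval, ...]:
    """CDS over the exon chain, trimmed 30 bp off each transcript end.

    With ``early_stop`` the CDS ends inside the second-to-last exon in
    transcript order, putting the stop codon upstream of the final junction
    (the NMD-sensitive configuration when the distance exceeds 50 nt).
    """
    exons = list(exons)
    tx_order = exons if strand == "+" else list(reversed(exons))
    first, last = tx_order[0], tx_order[-1]
    stop_exon = tx_order[-2] if early_stop and len(tx_order) >= 2 else last
    segs = []
    for e in exons:
        lo, hi = e.start, e.end
        if e == first:
            if strand == "+":
                lo = min(e.start + 30, e.end)
            else:
                hi = max(e.end - 30, e.start)
        in_tx_after_stop = (
            (e.start > stop_exon.end) if strand == "+" else (e.end < stop_exon.start)
        )
        if in_tx_after_stop:
            continue
        if e == stop_exon:
            if strand == "+":
                hi = max(e.end - 30, lo)
            else:
                lo = min(e.start + 30, hi)
        if lo <= hi:
            segs.append(GenomicInterval(e.chrom, lo, hi, strand))
    return tuple(segs)


def _plan_gene(
    idx: int, etype: str, strand: str, spec: FixtureSpec, rng: np.random.Generator
) -> dict:
    """Lay out one gene realising one planted event of the requested type.

    Returns a dict with transcripts, the canonical event, inclusion /
    exclusion transcript ids, and the auxiliary exon extents needed to
    render rMATS rows.
    """
    g = 1_000 + idx * spec.gene_spacing
    chrom = spec.chrom
    j = int(rng.integers(0, 80))
    iv = lambda s, e: GenomicInterval(chrom, s, e, strand)
    U = iv(g, g + 199)
    D = iv(g + 2_400, g + 2_599)
    E2 = iv(g + 3_000, g + 3_199)
    gene = f"GENE{idx:04d}"
    tx1_id, tx2_id = f"{gene}.T1", f"{gene}.T2"
    aux: dict = {}

    # map requested type to the genomic geometry that realises it on this
    # strand (left/right mirrored for the strand-asymmetric types)
    geometry = etype
    if strand == "-":
        geometry = {"A5SS": "A3SS", "A3SS": "A5SS", "AF": "AL", "AL": "AF"}.get(etype, etype)

    if geometry == "SE":
        s = g + 1_000 + j
        e = s + 150 + int(rng.integers(0, 60))
        inc, exc = [U, iv(s, e), D, E2], [U, D, E2]
        coords = (U.end, s, e, D.start)
        aux = {"upstream": [U.start, U.end], "downstream": [D.start, D.end]}
    elif geometry == "RI":
        inc = [iv(U.start, D.end), E2]  # retained form
        exc = [U, D, E2]
        coords = (U.start, U.end, D.start, D.end)
        aux = {"upstream": [U.start, U.end], "downstream": [D.start, D.end]}
    elif geometry == "MXE":
        x1 = iv(g + 700 + j, g + 850 + j)
        x2 = iv(g + 1_400 + j, g + 1_550 + j)
        inc, exc = [U, x1, D, E2], [U, x2, D, E2]
        coords = (U.end, x1.start, x1.end, x2.start, x2.end, D.start)
        aux = {"upstream": [U.start, U.end], "downstream": [D.start, D.end]}
    elif geometry == "A5SS":  # left-varying boundary
        d1, d2 = U.end, U.end + 150 + j
        inc = [iv(U.start, d2), D, E2]  # long form carries the segment
        exc = [U, D, E2]
        coords = (d1, d2, D.start)
        aux = {
            "long": [U.start, d2], "short": [U.start, d1],
            "flanking": [D.start, D.end],
        }
    elif geometry == "A3SS":  # right-varying boundary
        a_long = D.start - 150 - j
        inc = [U, iv(a_long, D.end), E2]
        exc = [U, D, E2]
        coords = (U.end, a_long, D.start)
        aux = {
            "long": [a_long, D.end], "short": [D.start, D.end],
            "flanking": [U.start, U.end],
        }
    elif geometry == "AF":  # alternative leftmost exons, shared right exon
        f1 = iv(g, g + 150)
        f2 = iv(g + 600 + j, g + 750 + j)
        inc, exc = [f1, D, E2], [f2, D, E2]
        coords = (f1.start, f1.end, f2.start, f2.end, D.start)
    else:  # AL geometry: alternative rightmost exons
        l1 = iv(g + 2_400, g + 2_550)
        l2 = iv(g + 3_000, g + 3_150)
        inc, exc = [U, l1], [U, l2]
        coords = (U.end, l1.start, l1.end, l2.start, l2.end)

    early1 = bool(rng.random() < 0.3)
    early2 = bool(rng.random() < 0.3)
    tx1 = Transcript(tx_id=tx1_id, gene=gene, chrom=chrom, strand=strand,
                     exons=tuple(inc), cds=_make_cds(inc, strand, early1))
    tx2 = Transcript(tx_id=tx2_id, gene=gene, chrom=chrom, strand=strand,
                     exons=tuple(exc), cds=_make_cds(exc, strand, early2))
    event = ASEvent(gene=gene, event_type=etype, chrom=chrom, strand=strand,
                    coords=coords)
    # the planted "inclusion" transcript is the one carrying the
    # inclusion-side distinct region; recompute to honour strand labeling
    regions = decompose_regions(event, 0)
    inc_region = regions.inclusion_side
    if tx1.covers_exonic(inc_region.start, inc_region.end):
        inc_tx, exc_tx = tx1, tx2
    else:
        inc_tx, exc_tx = tx2, tx1
    return {
        "gene": gene, "event": event, "tx1": tx1, "tx2": tx2,
        "inclusion_tx": inc_tx.tx_id, "exclusion_tx": exc_tx.tx_id,
        "aux": aux,
    }


def _gtf_line(chrom, source, feat, start, end, strand, attrs) -> str:
    a = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\t{source}\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{a}\n"


def simulate_annotation(spec: FixtureSpec) -> Tuple[str, pd.DataFrame, Annotation]:
    """Generate the GTF text, the planted-event truth table, and the parsed
    annotation object.

    Each gene's transcript pair embeds exactly one planted event; the truth
    table lists its canonical ID, type, and inclusion/exclusion transcript
    ids, plus the auxiliary geometry used to render rMATS rows.
    """
    rng = spec.rng(0)
    types = sorted(spec.type_mix)
    probs = np.array([spec.type_mix[t] for t in types])
    rows = []
    transcripts: Dict[str, Transcript] = {}
    gtf_parts: List[str] = []
    for i in range(spec.n_genes):
        etype = str(rng.choice(types, p=probs))
        strand = "+" if rng.random() < 0.5 else "-"
        plan = _plan_gene(i, etype, strand, spec, rng)
        ev: ASEvent = plan["event"]
        for tx in (plan["tx1"], plan["tx2"]):
            transcripts[tx.tx_id] = tx
            gtf_parts.append(_gtf_line(
                tx.chrom, "sim", "transcript", tx.start, tx.end, tx.strand,
                [("gene_id", tx.gene), ("transcript_id", tx.tx_id)],
            ))
            for e in tx.exons:
                gtf_parts.append(_gtf_line(
                    tx.chrom, "sim", "exon", e.start, e.end, tx.strand,
                    [("gene_id", tx.gene), ("transcript_id", tx.tx_id)],
                ))
            for c in tx.cds or ():
                gtf_parts.append(_gtf_line(
                    tx.chrom, "sim", "CDS", c.start, c.end, tx.strand,
                    [("gene_id", tx.gene), ("transcript_id", tx.tx_id)],
                ))
        rows.append({
            "gene": plan["gene"],
            "event_id": encode_event_id(ev),
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "coords": ":".join(map(str, ev.coords)),
            "inclusion_tx": plan["inclusion_tx"],
            "exclusion_tx": plan["exclusion_tx"],
            "aux": json.dumps(plan["aux"], sort_keys=True),
        })
    truth = pd.DataFrame(rows, columns=[
        "gene", "event_id", "event_type", "chrom", "strand", "coords",
        "inclusion_tx", "exclusion_tx", "aux",
    ])
    return "".join(gtf_parts), truth, Annotation(transcripts)


# -- DAS output rendering -------------------------------------------------


def _suppa_token(ev: ASEvent) -> str:
    c = ev.coords
    ch, s = ev.chrom, ev.strand
    if ev.event_type == "SE":
        body = f"SE:{ch}:{c[0]}-{c[1]}:{c[2]}-{c[3]}"
    elif ev.event_type == "MXE":
        body = f"MX:{ch}:{c[0]}-{c[1]}:{c[2]}-{c[5]}:{c[0]}-{c[3]}:{c[4]}-{c[5]}"
    elif ev.event_type == "RI":
        body = f"RI:{ch}:{c[0]}:{c[1]}-{c[2]}:{c[3]}"
    elif ev.event_type in ("A5SS", "A3SS"):
        left_varying = (ev.event_type == "A5SS") == (s == "+")
        tag = "A5" if ev.event_type == "A5SS" else "A3"
        if left_varying:
            body = f"{tag}:{ch}:{c[1]}-{c[2]}:{c[0]}-{c[2]}"
        else:
            body = f"{tag}:{ch}:{c[0]}-{c[1]}:{c[0]}-{c[2]}"
    else:  # AF / AL
        alt_left = (ev.event_type == "AF") == (s == "+")
        if alt_left:
            body = f"{ev.event_type}:{ch}:{c[0]}:{c[1]}-{c[4]}:{c[2]}:{c[3]}-{c[4]}"
        else:
            body = f"{ev.event_type}:{ch}:{c[0]}-{c[1]}:{c[2]}:{c[0]}-{c[3]}:{c[4]}"
    return f"{ev.gene};{body}:{s}"


def _rmats_row(ev: ASEvent, aux: dict, stats: DASRecord, idx: int) -> dict:
    c = ev.coords
    base = {
        "ID": idx, "GeneID": ev.gene, "geneSymbol": ev.gene,
        "chr": ev.chrom, "strand": ev.strand,
        "PValue": stats.p_value, "FDR": stats.fdr,
        "IncLevelDifference": stats.dpsi,
    }
    if ev.event_type == "SE":
        base.update({
            "exonStart_0base": c[1] - 1, "exonEnd": c[2],
            "upstreamES": aux["upstream"][0] - 1, "upstreamEE": c[0],
            "downstreamES": c[3] - 1, "downstreamEE": aux["downstream"][1],
        })
    elif ev.event_type == "MXE":
        base.update({
            "1stExonStart_0base": c[1] - 1, "1stExonEnd": c[2],
            "2ndExonStart_0base": c[3] - 1, "2ndExonEnd": c[4],
            "upstreamES": aux["upstream"][0] - 1, "upstreamEE": c[0],
            "downstreamES": c[5] - 1, "downstreamEE": aux["downstream"][1],
        })
    elif ev.event_type == "RI":
        base.update({
            "riExonStart_0base": c[0] - 1, "riExonEnd": c[3],
            "upstreamES": c[0] - 1, "upstreamEE": c[1],
            "downstreamES": c[2] - 1, "downstreamEE": c[3],
        })
    else:  # A5SS / A3SS
        base.update({
            "longExonStart_0base": aux["long"][0] - 1, "longExonEnd": aux["long"][1],
            "shortES": aux["short"][0] - 1, "shortEE": aux["short"][1],
            "flankingES": aux["flanking"][0] - 1, "flankingEE": aux["flanking"][1],
        })
    return base


def simulate_das_outputs(
    truth: pd.DataFrame, spec: FixtureSpec, out_dir: str
) -> Dict[str, str]:
    """Render the planted events in every supported dialect.

    Writes rMATS ``<TYPE>.MATS.JC.txt`` files (the five rMATS-expressible
    types), a SUPPA ``.dpsi`` file and the generic TSV (all seven types),
    with identical statistics per event across dialects.  Returns the
    mapping of dialect name to file path.
    """
    rng = spec.rng(1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(truth)
    significant = rng.random(n) < spec.frac_significant
    p_raw = np.where(
        significant,
        rng.uniform(1e-6, 0.049, n),
        rng.uniform(0.05, 1.0, n),
    )
    from .enrich import bh_adjust

    fdr = bh_adjust(list(p_raw)) if n else []
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    dpsi = np.where(
        significant,
        sign * np.clip(spec.dpsi_magnitude + rng.uniform(0, 0.2, n), 0, 1),
        sign * rng.uniform(0.0, 0.09, n),
    )

    from .events import decode_event_id

    events: List[ASEvent] = []
    for i, row in enumerate(truth.itertuples(index=False)):
        stats = DASRecord(p_value=float(p_raw[i]), fdr=float(fdr[i]),
                          dpsi=float(np.round(dpsi[i], 6)))
        events.append(decode_event_id(row.event_id, stats=stats))

    from .converters import _rmats_required

    paths: Dict[str, str] = {}
    # rMATS: one file per type (header always present, even with zero rows)
    for etype in RMATS_TYPES:
        rows = [
            _rmats_row(ev, json.loads(truth.iloc[i]["aux"]), ev.stats, i)
            for i, ev in enumerate(events) if ev.event_type == etype
        ]
        columns = ["ID"] + _rmats_required(etype)
        path = out / f"{etype}.MATS.JC.txt"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        paths[f"rmats_{etype}"] = str(path)
    # SUPPA .dpsi
    dpsi_df = pd.DataFrame({
        "event": [_suppa_token(ev) for ev in events],
        "cond1-cond2_dPSI": [ev.stats.dpsi for ev in events],
        "cond1-cond2_p-val": [ev.stats.p_value for ev in events],
    })
    suppa_path = out / "events.dpsi"
    dpsi_df.to_csv(suppa_path, sep="\t", index=False)
    paths["suppa"] = str(suppa_path)
    # generic TSV
    generic_path = out / "events_generic.tsv"
    events_to_frame(events).to_csv(generic_path, sep="\t", index=False)
    paths["generic"] = str(generic_path)
    return paths


# -- feature tracks -------------------------------------------------------


def _bed_line(iv: GenomicInterval, name: str, score: float = 0.0) -> str:
    return f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"


def _overlaps_any(chrom: str, pos_lo: int, pos_hi: int,
                  regions: Sequence[GenomicInterval]) -> bool:
    probe = GenomicInterval(chrom, pos_lo, pos_hi)
    return any(probe.overlaps(r) for r in regions)


def simulate_feature_tracks(
    truth: pd.DataFrame,
    spec: FixtureSpec,
    annotation: Annotation,
    out_dir: str,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Plant per-class features inside or outside each event's rule region.

    Returns (class -> track path, ledger).  The ledger has one row per
    event and one boolean column per track-backed class, recording whether
    the annotation run must populate that class column.  Decoy features
    (planted strictly outside the class's query region, including 1 bp
    beyond a boundary window) must stay silent.
    """
    from .annotate import REGION_RULES, _rule_regions
    from .events import decode_event_id

    rng = spec.rng(2)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w = spec.boundary_halfwidth

    bed: Dict[str, List[str]] = {c: [] for c in ("CONS", "REPEAT", "MIRNA_BS", "RBP_BS")}
    vcf: Dict[str, List[tuple]] = {c: [] for c in ("MUT", "SPLICE_SITE_VARIANT")}
    usage_rows: List[dict] = []
    domain_rows: List[dict] = []
    ptm_rows: List[dict] = []
    ppi_rows: List[dict] = []
    loc_rows: List[dict] = []
    ledger_rows: List[dict] = []

    for _, trow in truth.iterrows():
        ev = decode_event_id(trow["event_id"])
        regions = decompose_regions(ev, w)
        distinct = regions.distinct[0]
        expected = {c: False for c in TRACK_CLASSES}
        planted = {c: bool(rng.random() < spec.feature_density.get(c, 0.0))
                   for c in TRACK_CLASSES}
        decoy = {c: bool(rng.random() < spec.decoy_density) for c in TRACK_CLASSES}

        # distinct-region classes: plant a sub-interval of the distinct region
        mid = (distinct.start + distinct.end) // 2
        for cls in ("CONS", "REPEAT", "MIRNA_BS"):
            if planted[cls]:
                lo = int(rng.integers(distinct.start, mid + 1))
                hi = min(lo + 20, distinct.end)
                bed[cls].append(_bed_line(
                    GenomicInterval(ev.chrom, lo, hi, ev.strand),
                    f"{cls}_{ev.gene}", float(np.round(rng.random(), 3)),
                ))
                expected[cls] = True
            if decoy[cls]:
                # strictly outside the distinct region(s): far downstream
                pos = ev.coords[-1] + 500
                bed[cls].append(_bed_line(
                    GenomicInterval(ev.chrom, pos, pos + 15, ev.strand),
                    f"{cls}_decoy_{ev.gene}",
                ))
        if planted["EXON_USAGE"]:
            usage_rows.append({
                "chrom": ev.chrom, "start": distinct.start, "end": distinct.end,
                "name": f"usage_{ev.gene}",
                "s1": float(np.round(rng.random(), 3)),
                "s2": float(np.round(rng.random(), 3)),
                "s3": float(np.round(rng.random(), 3)),
            })
            expected["EXON_USAGE"] = True

        # boundary-window classes: half the plants sit exactly on the window
        # edge; decoys sit exactly 1 bp beyond it (and off every rule region)
        for cls in ("MUT", "SPLICE_SITE_VARIANT"):
            rule_region = _rule_regions(regions, REGION_RULES[cls])
            if planted[cls]:
                center = distinct.start if cls == "MUT" else distinct.end
                offset = w if rng.random() < 0.5 else int(rng.integers(0, w + 1))
                pos = center - offset if cls == "MUT" else center + offset
                vcf[cls].append((ev.chrom, pos, f"{cls}_{ev.gene}"))
                expected[cls] = True
            if decoy[cls]:
                center = distinct.start if cls == "MUT" else distinct.end
                pos = center - w - 1 if cls == "MUT" else center + w + 1
                if pos >= 1 and not _overlaps_any(ev.chrom, pos, pos, rule_region):
                    vcf[cls].append((ev.chrom, pos, f"{cls}_decoy_{ev.gene}"))

        # RBP: inside a flanking intron (or the distinct region when the
        # event has none); decoy inside a common exon
        rbp_region = _rule_regions(regions, REGION_RULES["RBP_BS"])
        if planted["RBP_BS"]:
            host = (regions.flanking_introns[0]
                    if regions.flanking_introns else distinct)
            lo = (host.start + host.end) // 2
            hi = min(lo + 15, host.end)
            bed["RBP_BS"].append(_bed_line(
                GenomicInterval(ev.chrom, lo, hi, ev.strand), f"RBP_{ev.gene}"
            ))
            expected["RBP_BS"] = True
        if decoy["RBP_BS"]:
            inc_tx = annotation[trow["inclusion_tx"]]
            for exon in inc_tx.exons:
                lo, hi = exon.start + 20, exon.start + 35
                if hi <= exon.end and not _overlaps_any(ev.chrom, lo, hi, rbp_region):
                    bed["RBP_BS"].append(_bed_line(
                        GenomicInterval(ev.chrom, lo, hi, ev.strand),
                        f"RBP_decoy_{ev.gene}",
                    ))
                    break

        # protein-level classes on the inclusion isoform over the distinct
        # region; decoys over a common exon interior only
        inc_tx = annotation[trow["inclusion_tx"]]
        for cls, rows_list in (("DOMAIN", domain_rows), ("PTM", ptm_rows)):
            if planted[cls] and inc_tx.cds is not None:
                span = genome_to_protein(
                    annotation, inc_tx.tx_id, distinct.start, distinct.end
                )
                if span is not None:
                    aa_lo, aa_hi = span
                    if cls == "PTM":
                        aa_hi = aa_lo
                    rows_list.append({
                        "tx_id": inc_tx.tx_id, "aa_start": aa_lo, "aa_end": aa_hi,
                        "name": f"{cls}_{ev.gene}",
                    })
                    expected[cls] = True
            if decoy[cls] and inc_tx.cds is not None:
                for exon in inc_tx.exons:
                    probe = GenomicInterval(ev.chrom, exon.start + 40, exon.start + 60)
                    if (probe.end <= exon.end
                            and not _overlaps_any(ev.chrom, probe.start - 2,
                                                  probe.end + 2, regions.distinct)):
                        span = genome_to_protein(
                            annotation, inc_tx.tx_id, probe.start, probe.end
                        )
                        if span is not None:
                            rows_list.append({
                                "tx_id": inc_tx.tx_id,
                                "aa_start": span[0], "aa_end": span[1],
                                "name": f"{cls}_decoy_{ev.gene}",
                            })
                        break

        if planted["PPI"]:
            ppi_rows.append({"tx_id": trow["inclusion_tx"],
                             "partner": f"PARTNER_{ev.gene}_INC"})
            if rng.random() < 0.5:  # an additional shared partner
                ppi_rows.append({"tx_id": trow["inclusion_tx"],
                                 "partner": f"PARTNER_{ev.gene}_SH"})
                ppi_rows.append({"tx_id": trow["exclusion_tx"],
                                 "partner": f"PARTNER_{ev.gene}_SH"})
            expected["PPI"] = True
        if planted["LOCALIZATION"]:
            compartment = str(rng.choice(["nucleus", "cytosol", "membrane"]))
            loc_rows.append({"tx_id": trow["inclusion_tx"], "compartment": compartment})
            expected["LOCALIZATION"] = True

        ledger_rows.append({"event_id": trow["event_id"], **expected})

    paths: Dict[str, str] = {}
    for cls, lines in bed.items():
        path = out / f"{cls.lower()}.bed"
        path.write_text("".join(lines))
        paths[cls] = str(path)
    contig_end = 2_000 + spec.n_genes * spec.gene_spacing
    for cls, recs in vcf.items():
        path = out / f"{cls.lower()}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={spec.chrom},length={contig_end}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos, name in sorted(recs, key=lambda r: (r[0], r[1], r[2])):
                fh.write(f"{chrom}\t{pos}\t{name}\tA\tG\t.\t.\t.\n")
        paths[cls] = str(path)
    for cls, rows_list, cols in (
        ("EXON_USAGE", usage_rows, ["chrom", "start", "end", "name", "s1", "s2", "s3"]),
        ("DOMAIN", domain_rows, ["tx_id", "aa_start", "aa_end", "name"]),
        ("PTM", ptm_rows, ["tx_id", "aa_start", "aa_end", "name"]),
        ("PPI", ppi_rows, ["tx_id", "partner"]),
        ("LOCALIZATION", loc_rows, ["tx_id", "compartment"]),
    ):
        path = out / f"{cls.lower()}.tsv"
        pd.DataFrame(rows_list, columns=cols).to_csv(path, sep="\t", index=False)
        paths[cls] = str(path)

    ledger = pd.DataFrame(ledger_rows, columns=["event_id", *TRACK_CLASSES])
    return paths, ledger


# -- gene sets ------------------------------------------------------------


def simulate_gene_sets(
    spec: FixtureSpec,
    universe: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[GeneSet], str, List[str]]:
    """Decoy gene sets plus one planted target set and a query gene list.

    Decoy sets are uniform draws from the universe.  The query list includes
    each universe gene with probability ``sigmoid(logit(base_rate) +
    target_logodds * [gene in target set])``, so ``target_logodds = 0``
    makes the target statistically indistinguishable from the decoys.
    """
    if len(universe) < 2 * spec.set_size:
        raise ValueError(
            f"universe ({len(universe)}) must hold at least twice the set size "
            f"({spec.set_size})"
        )
    rng = rng if rng is not None else spec.rng(3)
    universe = sorted(universe)
    sets: List[GeneSet] = []
    for i in range(spec.n_sets):
        members = rng.choice(universe, size=spec.set_size, replace=False)
        sets.append(GeneSet(name=f"SET_{i:03d}", genes=frozenset(map(str, members)),
                            source="decoy"))
    target_members = rng.choice(universe, size=spec.set_size, replace=False)
    target = GeneSet(name="SET_TARGET", genes=frozenset(map(str, target_members)),
                     source="target")
    sets.append(target)
    base_logit = float(np.log(spec.base_rate / (1 - spec.base_rate)))
    query: List[str] = []
    for gene in universe:
        logit = base_logit + (spec.target_logodds if gene in target.genes else 0.0)
        p = 1.0 / (1.0 + np.exp(-logit))
        if rng.random() < p:
            query.append(gene)
    if not query:  # guarantee a non-empty query
        query.append(str(rng.choice(universe)))
    return sets, target.name, query


def write_fixture_tree(spec: FixtureSpec, out_dir: str) -> Dict[str, str]:
    """Materialise the complete fixture tree (GTF, truth, DAS files, tracks,
    ledger, gmt) under ``out_dir``; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtf_text, truth, annotation = simulate_annotation(spec)
    paths = {"gtf": str(out / "annotation.gtf"), "truth": str(out / "truth.tsv")}
    (out / "annotation.gtf").write_text(gtf_text)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths.update(simulate_das_outputs(truth, spec, str(out / "das")))
    track_paths, ledger = simulate_feature_tracks(truth, spec, annotation,
                                                  str(out / "tracks"))
    paths.update({f"track_{k}": v for k, v in track_paths.items()})
    ledger_path = out / "ledger.tsv"
    ledger.to_csv(ledger_path, sep="\t", index=False)
    paths["ledger"] = str(ledger_path)
    universe = [f"G{i:04d}" for i in range(max(200, 4 * spec.set_size))]
    sets, target, query = simulate_gene_sets(spec, universe)
    gmt_path = out / "gene_sets.gmt"
    write_gmt(sets, str(gmt_path))
    paths["gmt"] = str(gmt_path)
    (out / "query_genes.txt").write_text("\n".join(query) + "\n")
    paths["query"] = str(out / "query_genes.txt")
    (out / "universe.txt").write_text("\n".join(universe) + "\n")
    paths["universe"] = str(out / "universe.txt")
    return paths
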