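"""Converters from caller-specific differential-splicing outputs to canonical events.

Three dialects are supported, plus a generic TSV so any other caller can be
funneled in:

* rMATS ``*.MATS.JC.txt`` — one file per event type; 0-based exon starts
  (``*ES`` / ``*_0base`` columns) and 1-based-equivalent ends.  Normalisation
  adds 1 to every 0-based start.
* SUPPA ``.dpsi`` / ``.ioe`` — events encoded as
  ``<gene>;<TYPE>:<chrom>:<j1>-<j2>:...:<strand>`` with 1-based junction
  coordinates.  Because the canonical coordinate tuple is exactly the sorted
  set of distinct coordinates in the SUPPA string, parsing is
  order-insensitive.
* spliceR-style isoform-pair tables — resolved in two steps: isoform ids ->
  exon chains via the annotation, then exon chains -> events via
  :func:`~splicescope.catalog.classify_transcript_pair`.

Rows whose statistics fail to parse keep their event with absent stats;
statistical filtering (e.g. p < 0.05, |dPSI| > 0.1) is the caller's choice,
exposed as CLI flags, never hard-coded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .catalog import Annotation, classify_transcript_pair
from .events import (
    ASEvent,
    COORD_ARITY,
    DASRecord,
    EVENT_TYPES,
    ValidationError,
    encode_event_id,
)


class SchemaError(ValueError):
    """Input file is missing a required column."""


@dataclass
class ConversionReport:
    """Row-level accounting for one conversion run.

    Invariant: ``n_input == n_converted + n_duplicates + n_failed``.
    A *converted* row parsed cleanly and contributed at least one new event
    (or legitimately zero, e.g. an identical isoform pair); a *duplicate*
    row's events all collapsed onto already-emitted canonical IDs; a
    *failed* row could not be parsed (reason recorded).
    """

    n_input: int = 0
    n_converted: int = 0
    n_duplicates: int = 0
    n_failed: int = 0
    failures: List[Tuple[int, str]] = field(default_factory=list)

    def fail(self, row: int, reason: str) -> None:
        self.n_failed += 1
        self.failures.append((row, reason))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_converted": self.n_converted,
            "n_duplicates": self.n_duplicates,
            "n_failed": self.n_failed,
            "failures": [{"row": r, "reason": m} for r, m in self.failures],
        }


def _num(value) -> Optional[float]:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def _stats(p, fdr, dpsi) -> Optional[DASRecord]:
    p, fdr, dpsi = _num(p), _num(fdr), _num(dpsi)
    if p is None and fdr is None and dpsi is None:
        return None
    try:
        return DASRecord(p_value=p, fdr=fdr, dpsi=dpsi)
    except ValidationError:
        return None


#: rMATS JC coordinate columns per event type, in canonical order, with the
#: 0-based-start flag that triggers the +1 normalisation.
_RMATS_COORDS: Dict[str, List[Tuple[str, bool]]] = {
    "SE": [
        ("upstreamEE", False),
        ("exonStart_0base", True),
        ("exonEnd", False),
        ("downstreamES", True),
    ],
    "MXE": [
        ("upstreamEE", False),
        ("1stExonStart_0base", True),
        ("1stExonEnd", False),
        ("2ndExonStart_0base", True),
        ("2ndExonEnd", False),
        ("downstreamES", True),
    ],
    "RI": [
        ("upstreamES", True),
        ("upstreamEE", False),
        ("downstreamES", True),
        ("downstreamEE", False),
    ],
}


def _rmats_coords(event_type: str, strand: str, row) -> Tuple[int, ...]:
    conv = lambda col, zero: int(row[col]) + (1 if zero else 0)
    if event_type in _RMATS_COORDS:
        return tuple(conv(c, z) for c, z in _RMATS_COORDS[event_type])
    if event_type in ("A5SS", "A3SS"):
        long_s = conv("longExonStart_0base", True)
        long_e = conv("longExonEnd", False)
        short_s = conv("shortES", True)
        short_e = conv("shortEE", False)
        flank_s = conv("flankingES", True)
        flank_e = conv("flankingEE", False)
        left_varying = (event_type == "A5SS") == (strand == "+")
        if left_varying:
            # flanking exon right of the varying donors/acceptors
            return (short_e, long_e, flank_s)
        return (flank_e, long_s, short_s)
    raise SchemaError(f"rMATS converter does not support event type {event_type!r}")


def _rmats_required(event_type: str) -> List[str]:
    base = ["GeneID", "geneSymbol", "chr", "strand", "PValue", "FDR", "IncLevelDifference"]
    if event_type in _RMATS_COORDS:
        return base + [c for c, _ in _RMATS_COORDS[event_type]]
    return base + [
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ]


def parse_rmats(path: str, event_type: str) -> Tuple[List[ASEvent], ConversionReport]:
    """Parse an rMATS ``<TYPE>.MATS.JC.txt`` file (SE/MXE/RI/A5SS/A3SS)."""
    if event_type not in ("SE", "MXE", "RI", "A5SS", "A3SS"):
        raise SchemaError(f"rMATS emits SE/MXE/RI/A5SS/A3SS only, got {event_type!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _rmats_required(event_type):
        if col not in df.columns:
            raise SchemaError(f"missing required rMATS column {col!r} in {path}")
    events: List[ASEvent] = []
    seen: set = set()
    report = ConversionReport(n_input=len(df))
    for idx, row in df.iterrows():
        gene = str(row["geneSymbol"]).strip('"') or str(row["GeneID"]).strip('"')
        chrom, strand = str(row["chr"]), str(row["strand"])
        try:
            coords = _rmats_coords(event_type, strand, row)
            ev = ASEvent(
                gene=gene,
                event_type=event_type,
                chrom=chrom,
                strand=strand,
                coords=coords,
                source="rmats",
                stats=_stats(row["PValue"], row["FDR"], row["IncLevelDifference"]),
            )
        except (ValueError, KeyError) as exc:
            report.fail(int(idx), str(exc))
            continue
        key = encode_event_id(ev)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        events.append(ev)
        report.n_converted += 1
    return events, report


def parse_suppa_event_id(token: str) -> ASEvent:
    """Parse one SUPPA event string ``<gene>;<TYPE>:<chrom>:...:<strand>``.

    The canonical coordinate tuple is the ascending sorted set of distinct
    coordinates in the string, so any junction ordering a SUPPA version
    emits maps to the same canonical event.
    """
    if ";" not in token:
        raise ValueError(f"missing ';' gene separator in {token!r}")
    gene, rest = token.split(";", 1)
    fields = rest.split(":")
    if len(fields) < 4:
        raise ValueError(f"too few ':' fields in {token!r}")
    etype = {"MX": "MXE", "A5": "A5SS", "A3": "A3SS"}.get(fields[0], fields[0])
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event type token {fields[0]!r} in {token!r}")
    chrom, strand = fields[1], fields[-1]
    values = set()
    for part in fields[2:-1]:
        for coord in part.split("-"):
            values.add(int(coord))
    coords = tuple(sorted(values))
    if len(coords) != COORD_ARITY[etype]:
        raise ValueError(
            f"{etype} event needs {COORD_ARITY[etype]} distinct coordinates, "
            f"got {len(coords)} in {token!r}"
        )
    return ASEvent(
        gene=gene, event_type=etype, chrom=chrom, strand=strand,
        coords=coords, source="suppa",
    )


def parse_suppa(path: str) -> Tuple[List[ASEvent], ConversionReport]:
    """Parse a SUPPA ``.dpsi`` (diffSplice) or ``.ioe`` file.

    ``.dpsi``: first column holds the event string; a ``*_dPSI`` column and a
    ``*_p-val`` column hold the statistics.  ``.ioe``: the ``event_id``
    column holds the event string and no statistics are attached.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "event_id" in df.columns:  # .ioe
        tokens = df["event_id"]
        dpsi_col = pval_col = None
    else:  # .dpsi: event string in the first column, stats in the rest
        tokens = df[df.columns[0]]
        dpsi_col = next((c for c in df.columns if "dpsi" in c.lower()), None)
        pval_col = next((c for c in df.columns if "p-val" in c.lower() or "pval" in c.lower()), None)
    events: List[ASEvent] = []
    seen: set = set()
    report = ConversionReport(n_input=len(df))
    for pos, (idx, row) in enumerate(df.iterrows()):
        token = str(tokens.iloc[pos])
        try:
            ev = parse_suppa_event_id(token)
        except ValueError as exc:
            report.fail(pos, str(exc))
            continue
        stats = None
        if dpsi_col or pval_col:
            stats = _stats(
                row[pval_col] if pval_col else None,
                None,
                row[dpsi_col] if dpsi_col else None,
            )
        ev = ASEvent(
            gene=ev.gene, event_type=ev.event_type, chrom=ev.chrom,
            strand=ev.strand, coords=ev.coords, source="suppa", stats=stats,
        )
        key = encode_event_id(ev)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        events.append(ev)
        report.n_converted += 1
    return events, report


def parse_generic(path: str) -> Tuple[List[ASEvent], ConversionReport]:
    """Parse the package's generic TSV dialect.

    Columns: ``gene, event_type, chrom, strand, coords, p_value, fdr, dpsi``
    with ``coords`` colon-joined 1-based ascending integers.  This is the
    entry point for any other differential-splicing caller.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene", "event_type", "chrom", "strand", "coords"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    events: List[ASEvent] = []
    seen: set = set()
    report = ConversionReport(n_input=len(df))
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            coords = tuple(int(tok) for tok in str(row["coords"]).split(":"))
            ev = ASEvent(
                gene=str(row["gene"]),
                event_type=str(row["event_type"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                coords=coords,
                source="generic",
                stats=_stats(row.get("p_value"), row.get("fdr"), row.get("dpsi")),
            )
        except (ValueError, ValidationError) as exc:
            report.fail(pos, str(exc))
            continue
        key = encode_event_id(ev)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        events.append(ev)
        report.n_converted += 1
    return events, report


def parse_splicer(
    path: str, annotation: Annotation
) -> Tuple[List[ASEvent], ConversionReport]:
    """Parse a spliceR-style isoform-pair table.

    Columns: ``tx_a, tx_b`` (isoform ids resolvable in ``annotation``) plus
    optional ``p_value, fdr, dpsi``.  Each pair passes through the two-step
    conversion: isoform ids -> exon chains, exon chains -> canonical events;
    every event emitted from one row carries that row's statistics.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tx_a", "tx_b"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    events: List[ASEvent] = []
    seen: set = set()
    report = ConversionReport(n_input=len(df))
    for pos, (_, row) in enumerate(df.iterrows()):
        a, b = str(row["tx_a"]), str(row["tx_b"])
        missing = [t for t in (a, b) if t not in annotation]
        if missing:
            report.fail(pos, f"unknown isoform {missing[0]!r}")
            continue
        stats = _stats(row.get("p_value"), row.get("fdr"), row.get("dpsi"))
        try:
            found = classify_transcript_pair(annotation[a], annotation[b])
        except ValueError as exc:
            report.fail(pos, str(exc))
            continue
        new = 0
        for ev in found:
            ev = ASEvent(
                gene=ev.gene, event_type=ev.event_type, chrom=ev.chrom,
                strand=ev.strand, coords=ev.coords, source="splicer", stats=stats,
            )
            key = encode_event_id(ev)
            if key in seen:
                continue
            seen.add(key)
            events.append(ev)
            new += 1
        if found and new == 0:
            report.n_duplicates += 1
        else:
            report.n_converted += 1  # includes converted-empty identical pairs
    return events, report


def filter_events(
    events: List[ASEvent],
    max_p: Optional[float] = None,
    min_abs_dpsi: Optional[float] = None,
) -> List[ASEvent]:
    """Keep events passing the caller-chosen significance thresholds.

    Events without the relevant statistic are dropped when a threshold on it
    is requested.
    """
    out = []
    for ev in events:
        if max_p is not None:
            if ev.stats is None or ev.stats.p_value is None or ev.stats.p_value >= max_p:
                continue
        if min_abs_dpsi is not None:
            if ev.stats is None or ev.stats.dpsi is None or abs(ev.stats.dpsi) <= min_abs_dpsi:
                continue
        out.append(ev)
    return out


def events_to_frame(events: List[ASEvent]) -> pd.DataFrame:
    """Tabulate events as a TSV-ready frame (canonical ID + statistics)."""
    rows = []
    for ev in events:
        st = ev.stats or DASRecord()
        rows.append(
            {
                "event_id": encode_event_id(ev),
                "gene": ev.gene,
                "event_type": ev.event_type,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "coords": ":".join(map(str, ev.coords)),
                "p_value": st.p_value,
                "fdr": st.fdr,
                "dpsi": st.dpsi,
                "source": ev.source,
            }
        )
    columns = [
        "event_id", "gene", "event_type", "chrom", "strand",
        "coords", "p_value", "fdr", "dpsi", "source",
    ]
    return pd.DataFrame(rows, columns=columns)
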