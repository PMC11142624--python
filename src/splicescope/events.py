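"""Core alternative-splicing event model.

An AS event is a local difference between two isoform structures of one gene,
classified into one of seven types:

==========  =============================================================
code        meaning
==========  =============================================================
``SE``      skipped (cassette) exon
``MXE``     mutually exclusive exons
``RI``      retained intron
``A5SS``    alternative 5' (donor) splice site
``A3SS``    alternative 3' (acceptor) splice site
``AF``      alternative first exon
``AL``      alternative last exon
==========  =============================================================

Every event is identified by a canonical ID string::

    <gene>|<type>|<chrom>|<strand>|<c1>:<c2>:...:<cn>

where the coordinates are the strictly ascending, 1-based inclusive genomic
splice coordinates that determine the event.  The coordinate arity is fixed
per type (SE 4, RI 4, MXE 6, A5SS/A3SS 3, AF/AL 5) and equals the number of
distinct coordinates carried by the corresponding SUPPA event string, so the
same event expressed by any supported caller maps to one ID (one-to-one
AS-key mapping).

All coordinates everywhere in the public API are 1-based inclusive, matching
GTF and VCF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

EVENT_TYPES = ("SE", "MXE", "RI", "A5SS", "A3SS", "AF", "AL")

#: fixed number of canonical coordinates per event type
COORD_ARITY = {"SE": 4, "MXE": 6, "RI": 4, "A5SS": 3, "A3SS": 3, "AF": 5, "AL": 5}

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An object violates a domain invariant; the message names the field."""


class ParseError(ValueError):
    """A string does not match the canonical event-ID grammar."""


class DegenerateEventError(ValueError):
    """Event geometry collapses to a zero-length distinct region."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom: must be non-empty")
        if self.start < 1:
            raise ValidationError(f"start: must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(f"end: must be >= start ({self.start}), got {self.end}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand: must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Inclusive overlap: a single shared base counts."""
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) <= min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class DASRecord:
    """Differential-splicing statistics attached to an event.

    ``dpsi`` is the between-condition difference in percent-spliced-in
    (rMATS ``IncLevelDifference``), in [-1, 1].
    """

    p_value: Optional[float] = None
    fdr: Optional[float] = None
    dpsi: Optional[float] = None

    def __post_init__(self) -> None:
        for name, lo, hi in (("p_value", 0.0, 1.0), ("fdr", 0.0, 1.0), ("dpsi", -1.0, 1.0)):
            val = getattr(self, name)
            if val is not None and not (lo <= val <= hi):
                raise ValidationError(f"{name}: must be in [{lo}, {hi}], got {val}")


@dataclass(frozen=True)
class ASEvent:
    """One canonical alternative-splicing event.

    ``coords`` is the strictly ascending tuple of defining genomic
    coordinates; its arity is fixed by ``event_type`` (see
    :data:`COORD_ARITY`).  ``source`` and ``stats`` are provenance /
    statistics riders and do not take part in equality: two events are the
    same event iff their canonical IDs are equal.
    """

    gene: str
    event_type: str
    chrom: str
    strand: str
    coords: tuple
    source: str = field(default="catalog", compare=False)
    stats: Optional[DASRecord] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.gene or any(ch in self.gene for ch in "|:"):
            raise ValidationError(f"gene: must be non-empty without '|' or ':', got {self.gene!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"event_type: must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )
        if not self.chrom or "|" in self.chrom or ":" in self.chrom:
            raise ValidationError(f"chrom: must be non-empty without '|' or ':', got {self.chrom!r}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand: must be one of {STRANDS}, got {self.strand!r}")
        coords = tuple(int(c) for c in self.coords)
        object.__setattr__(self, "coords", coords)
        arity = COORD_ARITY[self.event_type]
        if len(coords) != arity:
            raise ValidationError(
                f"coords: {self.event_type} requires {arity} coordinates, got {len(coords)}"
            )
        if coords[0] < 1:
            raise ValidationError(f"coords: positions must be >= 1, got {coords[0]}")
        for a, b in zip(coords, coords[1:]):
            if b <= a:
                raise ValidationError(
                    f"coords: must be strictly ascending, got {a} followed by {b}"
                )

    @property
    def event_id(self) -> str:
        return encode_event_id(self)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.coords[0], self.coords[-1], self.strand)


@dataclass(frozen=True)
class EventRegions:
    """Region decomposition of an event.

    ``distinct``
        the region(s) whose usage differs between the two isoform forms
        (skipped exon, retained intron, alternative segment, alternative
        terminal exons); ``distinct_labels`` tags each one — ``"distinct"``
        for single-region types, ``"inclusion-side"`` / ``"exclusion-side"``
        for MXE/AF/AL (inclusion-side = nearer the transcript 5' end).
    ``common``
        flanking constitutive anchors/exons shared by both forms.
    ``boundaries``
        the +/-w bp window centred on each splice-site coordinate of each
        distinct region (width 2w+1).
    ``flanking_introns``
        intronic gaps adjoining the distinct region(s).
    """

    distinct: tuple
    distinct_labels: tuple
    common: tuple
    boundaries: tuple
    flanking_introns: tuple

    @property
    def inclusion_side(self) -> GenomicInterval:
        for iv, lab in zip(self.distinct, self.distinct_labels):
            if lab in ("distinct", "inclusion-side"):
                return iv
        raise ValueError("no inclusion-side region")  # pragma: no cover

    @property
    def exclusion_side(self) -> Optional[GenomicInterval]:
        for iv, lab in zip(self.distinct, self.distinct_labels):
            if lab == "exclusion-side":
                return iv
        return None


_ID_RE = re.compile(
    r"^(?P<gene>[^|:]+)\|(?P<type>[^|:]+)\|(?P<chrom>[^|:]+)\|(?P<strand>[^|:]+)\|(?P<coords>[0-9:]+)$"
)


def encode_event_id(event: ASEvent) -> str:
    """Render the canonical ID string for a valid event (deterministic,
    one-to-one on valid events)."""
    coords = ":".join(str(c) for c in event.coords)
    return f"{event.gene}|{event.event_type}|{event.chrom}|{event.strand}|{coords}"


def decode_event_id(event_id: str, stats: Optional[DASRecord] = None,
                    source: str = "catalog") -> ASEvent:
    """Parse a canonical ID back into an :class:`ASEvent`.

    Inverse of :func:`encode_event_id` on its image.  Raises
    :class:`ParseError` naming the offending position for malformed input.
    """
    m = _ID_RE.match(event_id)
    if m is None:
        fields = event_id.split("|")
        if len(fields) != 5:
            raise ParseError(
                f"expected 5 '|'-separated fields, got {len(fields)}: {event_id!r}"
            )
        raise ParseError(f"malformed canonical ID: {event_id!r}")
    etype = m.group("type")
    if etype not in EVENT_TYPES:
        raise ParseError(f"unknown event type {etype!r} at field 2 of {event_id!r}")
    try:
        coords = tuple(int(tok) for tok in m.group("coords").split(":"))
    except ValueError as exc:  # pragma: no cover - regex restricts to digits/colon
        raise ParseError(f"non-integer coordinate in {event_id!r}") from exc
    if len(coords) != COORD_ARITY[etype]:
        raise ParseError(
            f"{etype} requires {COORD_ARITY[etype]} coordinates, "
            f"got {len(coords)} in field 5 of {event_id!r}"
        )
    try:
        return ASEvent(
            gene=m.group("gene"),
            event_type=etype,
            chrom=m.group("chrom"),
            strand=m.group("strand"),
            coords=coords,
            stats=stats,
            source=source,
        )
    except ValidationError as exc:
        raise ParseError(f"invalid event in {event_id!r}: {exc}") from exc


def _window(chrom: str, center: int, w: int, strand: str) -> GenomicInterval:
    if center - w < 1:
        raise ValidationError(
            f"boundary window around {center} with half-width {w} extends below position 1"
        )
    return GenomicInterval(chrom, center - w, center + w, strand)


def decompose_regions(event: ASEvent, boundary_halfwidth: int = 10) -> EventRegions:
    """Decompose an event into distinct / common / boundary / intron regions.

    Geometry per type (coords ``c1..cn``, ascending):

    * SE — distinct = skipped exon ``[c2, c3]``; common anchors at ``c1``
      (upstream exon end) and ``c4`` (downstream exon start); flanking
      introns ``[c1+1, c2-1]`` and ``[c3+1, c4-1]``.
    * RI — distinct = retained intron ``[c2+1, c3-1]``; common = upstream
      exon ``[c1, c2]`` and downstream exon ``[c3, c4]``.
    * MXE — distinct = the two exclusive exons ``[c2, c3]`` and ``[c4, c5]``.
    * A5SS/A3SS — distinct = the alternative segment between the proximal and
      distal alternative splice sites; which end of the coordinate triple
      varies depends on type x strand (A5SS(+) and A3SS(-) vary on the left).
    * AF/AL — distinct = the two alternative terminal exons; the remaining
      coordinate anchors the shared flanking exon.

    Boundary windows are centred on the start and end of every distinct
    region and have width ``2 * boundary_halfwidth + 1``.  Empty flanking
    introns (adjacent features) are omitted rather than reported as
    zero-width; a zero-length *distinct* region raises
    :class:`DegenerateEventError`.
    """
    w = boundary_halfwidth
    if w < 0:
        raise ValidationError(f"boundary_halfwidth: must be >= 0, got {w}")
    c = event.coords
    chrom, strand = event.chrom, event.strand
    iv = lambda s, e: GenomicInterval(chrom, s, e, strand)

    distinct: list = []
    labels: list = []
    common: list = []
    introns: list = []

    et = event.event_type
    if et == "SE":
        distinct = [iv(c[1], c[2])]
        labels = ["distinct"]
        common = [iv(c[0], c[0]), iv(c[3], c[3])]
        intron_spans = [(c[0] + 1, c[1] - 1), (c[2] + 1, c[3] - 1)]
    elif et == "RI":
        if c[2] == c[1] + 1:
            raise DegenerateEventError(
                f"retained intron between {c[1]} and {c[2]} is empty"
            )
        distinct = [iv(c[1] + 1, c[2] - 1)]
        labels = ["distinct"]
        common = [iv(c[0], c[1]), iv(c[2], c[3])]
        intron_spans = []
    elif et == "MXE":
        first, second = iv(c[1], c[2]), iv(c[3], c[4])
        if strand == "+":
            distinct, labels = [first, second], ["inclusion-side", "exclusion-side"]
        else:
            distinct, labels = [first, second], ["exclusion-side", "inclusion-side"]
        common = [iv(c[0], c[0]), iv(c[5], c[5])]
        intron_spans = [(c[0] + 1, c[1] - 1), (c[2] + 1, c[3] - 1), (c[4] + 1, c[5] - 1)]
    elif et in ("A5SS", "A3SS"):
        # left-varying: segment adjoins the left flanking anchor; A5SS(+) and
        # A3SS(-) vary the left boundary, A5SS(-)/A3SS(+) the right one.
        left_varying = (et == "A5SS") == (strand == "+")
        if left_varying:
            distinct = [iv(c[0] + 1, c[1])]
            common = [iv(c[0], c[0]), iv(c[2], c[2])]
            intron_spans = [(c[1] + 1, c[2] - 1)]
        else:
            distinct = [iv(c[1], c[2] - 1)]
            common = [iv(c[0], c[0]), iv(c[2], c[2])]
            intron_spans = [(c[0] + 1, c[1] - 1)]
        labels = ["distinct"]
    elif et in ("AF", "AL"):
        # alternative terminal exons sit at the genomic left iff
        # (AF and +) or (AL and -); the odd coordinate anchors the shared exon.
        alt_left = (et == "AF") == (strand == "+")
        if alt_left:
            e1, e2 = iv(c[0], c[1]), iv(c[2], c[3])
            anchor = iv(c[4], c[4])
            intron_spans = [(c[1] + 1, c[2] - 1), (c[3] + 1, c[4] - 1)]
        else:
            e1, e2 = iv(c[1], c[2]), iv(c[3], c[4])
            anchor = iv(c[0], c[0])
            intron_spans = [(c[0] + 1, c[1] - 1), (c[2] + 1, c[3] - 1)]
        # inclusion-side = the exon encountered first in transcript order,
        # which for both AF and AL is the genomically left one on '+'
        if strand == "+":
            distinct, labels = [e1, e2], ["inclusion-side", "exclusion-side"]
        else:
            distinct, labels = [e1, e2], ["exclusion-side", "inclusion-side"]
        common = [anchor]
    else:  # pragma: no cover
        raise ValidationError(f"event_type: unknown {et!r}")

    for s, e in intron_spans:
        if s <= e:
            introns.append(iv(s, e))

    boundaries = []
    for region in distinct:
        boundaries.append(_window(chrom, region.start, w, strand))
        boundaries.append(_window(chrom, region.end, w, strand))

    return EventRegions(
        distinct=tuple(distinct),
        distinct_labels=tuple(labels),
        common=tuple(common),
        boundaries=tuple(boundaries),
        flanking_introns=tuple(introns),
    )


def subtract_intervals(regions, remove):
    """Subtract ``remove`` intervals from ``regions``; keep residuals >= 1 bp.

    Both arguments are iterables of :class:`GenomicInterval`; strand is
    carried from the source region.
    """
    out = []
    for region in regions:
        pieces = [(region.start, region.end)]
        for r in remove:
            if r.chrom != region.chrom:
                continue
            nxt = []
            for s, e in pieces:
                if r.end < s or r.start > e:
                    nxt.append((s, e))
                    continue
                if s < r.start:
                    nxt.append((s, r.start - 1))
                if r.end < e:
                    nxt.append((r.end + 1, e))
            pieces = nxt
        out.extend(
            GenomicInterval(region.chrom, s, e, region.strand) for s, e in pieces if s <= e
        )
    return out
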