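"""Single-file feature database over standard genomic/proteomic tracks.

The store is an embedded SQLite file holding the 12 feature classes at three
key levels:

* genomic classes (``CONS, MUT, REPEAT, MIRNA_BS, RBP_BS, EXON_USAGE,
  SPLICE_SITE_VARIANT``) — keyed by a 1-based inclusive interval; ingested
  from BED (CONS/REPEAT/MIRNA_BS/RBP_BS), VCF sites (MUT/SPLICE_SITE_VARIANT)
  or TSV (EXON_USAGE, payload = sample -> PSI mapping);
* protein classes (``DOMAIN, PTM``) — keyed by isoform id + amino-acid span,
  from TSV; reach genomic space through :func:`project_protein_to_genome`;
* isoform classes (``PPI, LOCALIZATION``) — keyed by isoform id, from TSV.

``NMD`` is the 12th class; it is derived from transcript structure at
annotation time rather than stored (see :mod:`splicescope.annotate`).

All tables carry UNIQUE constraints with ``INSERT OR IGNORE`` so rebuilding
from identical inputs is idempotent and duplicate records collapse.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .catalog import Annotation, Transcript, load_gtf
from .events import GenomicInterval, ValidationError

GENOMIC_CLASSES = (
    "CONS", "MUT", "REPEAT", "MIRNA_BS", "RBP_BS", "EXON_USAGE", "SPLICE_SITE_VARIANT",
)
PROTEIN_CLASSES = ("DOMAIN", "PTM")
ISOFORM_CLASSES = ("PPI", "LOCALIZATION")
DERIVED_CLASSES = ("NMD",)
FEATURE_CLASSES = GENOMIC_CLASSES + PROTEIN_CLASSES + ISOFORM_CLASSES + DERIVED_CLASSES

_BED_CLASSES = {"CONS", "REPEAT", "MIRNA_BS", "RBP_BS"}
_VCF_CLASSES = {"MUT", "SPLICE_SITE_VARIANT"}


class BuildError(ValueError):
    """A track could not be ingested; the message names class and path."""


@dataclass(frozen=True)
class FeatureRecord:
    """One feature observation at genomic, protein, or isoform level."""

    feature_class: str
    interval: Optional[GenomicInterval] = None
    isoform: Optional[str] = None
    aa_start: Optional[int] = None
    aa_end: Optional[int] = None
    partner: Optional[str] = None
    name: str = ""
    source: str = ""
    score: Optional[float] = None
    payload: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"feature_class: unknown {self.feature_class!r}")
        genomic = self.interval is not None
        protein = self.isoform is not None and self.aa_start is not None
        iso = self.isoform is not None and self.aa_start is None
        if self.feature_class in GENOMIC_CLASSES and not genomic:
            raise ValidationError(f"{self.feature_class}: requires a genomic interval key")
        if self.feature_class in PROTEIN_CLASSES and not protein:
            raise ValidationError(f"{self.feature_class}: requires isoform + aa span key")
        if self.feature_class in ISOFORM_CLASSES and not iso:
            raise ValidationError(f"{self.feature_class}: requires an isoform key")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS genomic (
    class TEXT, chrom TEXT, start INTEGER, end INTEGER, strand TEXT,
    name TEXT, source TEXT, score REAL, payload TEXT,
    UNIQUE(class, chrom, start, end, strand, name, source, score, payload)
);
CREATE INDEX IF NOT EXISTS idx_genomic ON genomic(class, chrom, start, end);
CREATE TABLE IF NOT EXISTS protein (
    class TEXT, tx_id TEXT, aa_start INTEGER, aa_end INTEGER,
    name TEXT, source TEXT, payload TEXT,
    UNIQUE(class, tx_id, aa_start, aa_end, name, source, payload)
);
CREATE TABLE IF NOT EXISTS isoform (
    class TEXT, tx_id TEXT, partner TEXT, name TEXT, source TEXT, payload TEXT,
    UNIQUE(class, tx_id, partner, name, source, payload)
);
CREATE TABLE IF NOT EXISTS transcripts (
    tx_id TEXT PRIMARY KEY, gene TEXT, chrom TEXT, strand TEXT,
    exons TEXT, cds TEXT
);
"""


class FeatureDB:
    """Handle over a built feature database file."""

    def __init__(self, path):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._annotation: Optional[Annotation] = None

    def close(self) -> None:
        self._conn.close()

    # -- queries ---------------------------------------------------------

    def query_interval(
        self, chrom: str, start: int, end: int, classes: Optional[Sequence[str]] = None
    ) -> List[FeatureRecord]:
        """All genomic records overlapping ``[start, end]`` (1-based inclusive:
        a single shared base counts)."""
        if start > end:
            raise ValidationError(f"start ({start}) must be <= end ({end})")
        classes = tuple(classes) if classes is not None else GENOMIC_CLASSES
        for cls in classes:
            if cls not in GENOMIC_CLASSES:
                raise ValidationError(f"class {cls!r} is not a genomic feature class")
        qmarks = ",".join("?" for _ in classes)
        rows = self._conn.execute(
            f"SELECT class, chrom, start, end, strand, name, source, score, payload "
            f"FROM genomic WHERE class IN ({qmarks}) AND chrom = ? "
            f"AND start <= ? AND end >= ? "
            f"ORDER BY class, chrom, start, end, name",
            (*classes, chrom, end, start),
        ).fetchall()
        return [
            FeatureRecord(
                feature_class=c,
                interval=GenomicInterval(ch, s, e, st or "+"),
                name=n, source=src, score=sc,
                payload=json.loads(pl) if pl else {},
            )
            for c, ch, s, e, st, n, src, sc, pl in rows
        ]

    def query_isoform_features(
        self, isoform_ids: Iterable[str], classes: Optional[Sequence[str]] = None
    ) -> List[FeatureRecord]:
        """Exact-match retrieval of isoform-keyed records (PPI, LOCALIZATION,
        DOMAIN, PTM)."""
        ids = sorted(set(isoform_ids))
        classes = tuple(classes) if classes is not None else PROTEIN_CLASSES + ISOFORM_CLASSES
        for cls in classes:
            if cls not in PROTEIN_CLASSES + ISOFORM_CLASSES:
                raise ValidationError(f"class {cls!r} is not isoform/protein keyed")
        if not ids:
            return []
        out: List[FeatureRecord] = []
        idq = ",".join("?" for _ in ids)
        iso_classes = [c for c in classes if c in ISOFORM_CLASSES]
        if iso_classes:
            cq = ",".join("?" for _ in iso_classes)
            rows = self._conn.execute(
                f"SELECT class, tx_id, partner, name, source, payload FROM isoform "
                f"WHERE class IN ({cq}) AND tx_id IN ({idq}) "
                f"ORDER BY class, tx_id, partner, name",
                (*iso_classes, *ids),
            ).fetchall()
            out += [
                FeatureRecord(feature_class=c, isoform=t, partner=p or None, name=n,
                              source=src, payload=json.loads(pl) if pl else {})
                for c, t, p, n, src, pl in rows
            ]
        prot_classes = [c for c in classes if c in PROTEIN_CLASSES]
        if prot_classes:
            cq = ",".join("?" for _ in prot_classes)
            rows = self._conn.execute(
                f"SELECT class, tx_id, aa_start, aa_end, name, source, payload "
                f"FROM protein WHERE class IN ({cq}) AND tx_id IN ({idq}) "
                f"ORDER BY class, tx_id, aa_start, aa_end, name",
                (*prot_classes, *ids),
            ).fetchall()
            out += [
                FeatureRecord(feature_class=c, isoform=t, aa_start=s, aa_end=e,
                              name=n, source=src, payload=json.loads(pl) if pl else {})
                for c, t, s, e, n, src, pl in rows
            ]
        return out

    def counts(self) -> Dict[str, int]:
        out = {cls: 0 for cls in FEATURE_CLASSES if cls not in DERIVED_CLASSES}
        for table, col in (("genomic", "class"), ("protein", "class"), ("isoform", "class")):
            for cls, n in self._conn.execute(
                f"SELECT {col}, COUNT(*) FROM {table} GROUP BY {col}"
            ):
                out[cls] = n
        return out

    @property
    def annotation(self) -> Annotation:
        """The gene model stored at build time."""
        if self._annotation is None:
            txs = {}
            for tx_id, gene, chrom, strand, exons, cds in self._conn.execute(
                "SELECT tx_id, gene, chrom, strand, exons, cds FROM transcripts"
            ):
                txs[tx_id] = Transcript(
                    tx_id=tx_id, gene=gene, chrom=chrom, strand=strand,
                    exons=tuple(GenomicInterval(chrom, s, e, strand)
                                for s, e in json.loads(exons)),
                    cds=tuple(GenomicInterval(chrom, s, e, strand)
                              for s, e in json.loads(cds)) if cds else None,
                )
            self._annotation = Annotation(txs)
        return self._annotation

    @property
    def meta(self) -> Dict[str, str]:
        return dict(self._conn.execute("SELECT key, value FROM meta"))


# -- track readers -------------------------------------------------------


def _read_bed(path: str, cls: str) -> Iterable[tuple]:
    """BED 3/6 columns; 0-based half-open converted to 1-based inclusive."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BuildError(f"{cls}: BED line with <3 columns in {path}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
            name = parts[3] if len(parts) > 3 else cls
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            yield (cls, chrom, start, end, strand, name, "bed", score, "")


def _read_vcf(path: str, cls: str) -> Iterable[tuple]:
    """VCF v4.x site records (CHROM/POS/REF/ALT); genotypes ignored."""
    import pysam

    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref = rec.ref or ""
            alts = ",".join(a for a in (rec.alts or ()) if a)
            name = rec.id or f"{ref}>{alts}"
            end = rec.pos + max(len(ref), 1) - 1
            payload = json.dumps({"ref": ref, "alt": alts}, sort_keys=True)
            yield (cls, rec.chrom, rec.pos, end, "+", name, "vcf", None, payload)


def _read_exon_usage(path: str) -> Iterable[tuple]:
    """TSV: chrom, start, end, name, then one PSI column per sample."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise BuildError(f"EXON_USAGE: missing column {col!r} in {path}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end", "name")]
    for _, row in df.iterrows():
        psi = {s: float(row[s]) for s in samples}
        name = str(row["name"]) if "name" in df.columns else "exon_usage"
        yield (
            "EXON_USAGE", str(row["chrom"]), int(row["start"]), int(row["end"]), "+",
            name, "tsv", None, json.dumps(psi, sort_keys=True),
        )


def _read_protein_tsv(path: str, cls: str) -> Iterable[tuple]:
    """TSV: tx_id, aa_start, aa_end, name (protein coordinates, 1-based)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tx_id", "aa_start", "aa_end", "name"):
        if col not in df.columns:
            raise BuildError(f"{cls}: missing column {col!r} in {path}")
    for _, row in df.iterrows():
        yield (cls, str(row["tx_id"]), int(row["aa_start"]), int(row["aa_end"]),
               str(row["name"]), "tsv", "")


def _read_isoform_tsv(path: str, cls: str) -> Iterable[tuple]:
    """TSV: PPI = tx_id, partner; LOCALIZATION = tx_id, compartment."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "tx_id" not in df.columns:
        raise BuildError(f"{cls}: missing column 'tx_id' in {path}")
    value_col = "partner" if cls == "PPI" else "compartment"
    if value_col not in df.columns:
        raise BuildError(f"{cls}: missing column {value_col!r} in {path}")
    for _, row in df.iterrows():
        val = str(row[value_col])
        partner = val if cls == "PPI" else ""
        yield (cls, str(row["tx_id"]), partner, val, "tsv", "")


def build_db(
    annotation: Union[str, Annotation],
    tracks: Optional[Dict[str, str]] = None,
    out_path: str = "features.sqlite",
    genome_label: str = "custom",
) -> FeatureDB:
    """Build the feature database from a gene model plus per-class tracks.

    ``tracks`` maps feature-class code -> file path; the file format is fixed
    per class (see module docstring).  Building is idempotent: identical
    inputs yield a database giving identical query answers.  Protein records
    whose isoform lacks a CDS are skipped and counted as warnings in the
    build report (``meta['n_skipped_no_cds']``).
    """
    tracks = dict(tracks or {})
    ann = load_gtf(annotation) if isinstance(annotation, str) else annotation
    conn = sqlite3.connect(out_path)
    conn.executescript(_SCHEMA)
    for tbl in ("genomic", "protein", "isoform", "transcripts", "meta"):
        conn.execute(f"DELETE FROM {tbl}")

    for tx in ann.transcripts.values():
        conn.execute(
            "INSERT OR REPLACE INTO transcripts VALUES (?,?,?,?,?,?)",
            (
                tx.tx_id, tx.gene, tx.chrom, tx.strand,
                json.dumps([[e.start, e.end] for e in tx.exons]),
                json.dumps([[e.start, e.end] for e in tx.cds]) if tx.cds else None,
            ),
        )

    n_skipped = 0
    for cls, path in sorted(tracks.items()):
        if cls not in FEATURE_CLASSES or cls in DERIVED_CLASSES:
            raise BuildError(f"unknown or derived feature class {cls!r} for track {path}")
        try:
            if cls in _BED_CLASSES:
                rows = list(_read_bed(path, cls))
            elif cls in _VCF_CLASSES:
                rows = list(_read_vcf(path, cls))
            elif cls == "EXON_USAGE":
                rows = list(_read_exon_usage(path))
            elif cls in PROTEIN_CLASSES:
                rows = list(_read_protein_tsv(path, cls))
            else:
                rows = list(_read_isoform_tsv(path, cls))
        except BuildError:
            raise
        except Exception as exc:
            raise BuildError(f"{cls}: cannot read track {path}: {exc}") from exc
        if cls in PROTEIN_CLASSES:
            kept = []
            for row in rows:
                tx_id = row[1]
                if tx_id not in ann or ann[tx_id].cds is None:
                    n_skipped += 1
                    continue
                kept.append(row)
            conn.executemany(
                "INSERT OR IGNORE INTO protein VALUES (?,?,?,?,?,?,?)", kept
            )
        elif cls in ISOFORM_CLASSES:
            conn.executemany("INSERT OR IGNORE INTO isoform VALUES (?,?,?,?,?,?)", rows)
        else:
            conn.executemany("INSERT OR IGNORE INTO genomic VALUES (?,?,?,?,?,?,?,?,?)", rows)

    import datetime

    meta = {
        "genome": genome_label,
        "annotation_source": str(annotation) if isinstance(annotation, str) else "in-memory",
        "built": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_transcripts": str(len(ann.transcripts)),
        "n_skipped_no_cds": str(n_skipped),
    }
    conn.executemany("INSERT OR REPLACE INTO meta VALUES (?,?)", meta.items())
    conn.commit()
    conn.close()
    return FeatureDB(out_path)


# -- protein -> genome projection ----------------------------------------


class NoCDSError(ValueError):
    pass


class AARangeError(ValueError):
    pass


def project_protein_to_genome(
    annotation: Annotation, tx_id: str, aa_start: int, aa_end: int
) -> List[GenomicInterval]:
    """Genomic segments covering codons ``aa_start..aa_end`` of an isoform.

    The CDS is walked in translation order (reversed genomic order on the
    minus strand); returned segments are in ascending genomic order and
    their lengths sum to ``3 * (aa_end - aa_start + 1)``.
    """
    if tx_id not in annotation:
        raise KeyError(tx_id)
    tx = annotation[tx_id]
    if tx.cds is None:
        raise NoCDSError(f"{tx_id} has no annotated CDS")
    cds_len = sum(seg.width for seg in tx.cds)
    if not (1 <= aa_start <= aa_end):
        raise AARangeError(f"invalid amino-acid range {aa_start}..{aa_end}")
    if aa_end * 3 > cds_len:
        raise AARangeError(
            f"aa range {aa_start}..{aa_end} exceeds coding length "
            f"({cds_len // 3} aa) of {tx_id}"
        )
    nt_lo, nt_hi = (aa_start - 1) * 3 + 1, aa_end * 3  # 1-based CDS nt coords
    segments = list(tx.cds) if tx.strand == "+" else list(reversed(tx.cds))
    out: List[GenomicInterval] = []
    offset = 0  # CDS nts consumed so far
    for seg in segments:
        seg_lo, seg_hi = offset + 1, offset + seg.width
        lo, hi = max(nt_lo, seg_lo), min(nt_hi, seg_hi)
        if lo <= hi:
            if tx.strand == "+":
                gs = seg.start + (lo - seg_lo)
                ge = seg.start + (hi - seg_lo)
            else:
                ge = seg.end - (lo - seg_lo)
                gs = seg.end - (hi - seg_lo)
            out.append(GenomicInterval(tx.chrom, gs, ge, tx.strand))
        offset += seg.width
    return sorted(out, key=lambda r: r.start)


def genome_to_protein(
    annotation: Annotation, tx_id: str, start: int, end: int
) -> Optional[Tuple[int, int]]:
    """Amino-acid span of an isoform covered by genomic ``[start, end]``.

    Returns ``None`` if the interval does not intersect the CDS.  Used by the
    fixture generator to plant protein-level features over known exons.
    """
    tx = annotation[tx_id]
    if tx.cds is None:
        raise NoCDSError(f"{tx_id} has no annotated CDS")
    segments = list(tx.cds) if tx.strand == "+" else list(reversed(tx.cds))
    offset = 0
    nts: List[int] = []
    for seg in segments:
        positions = (
            range(seg.start, seg.end + 1)
            if tx.strand == "+"
            else range(seg.end, seg.start - 1, -1)
        )
        for pos in positions:
            offset += 1
            if start <= pos <= end:
                nts.append(offset)
    if not nts:
        return None
    n_complete = sum(seg.width for seg in tx.cds) // 3  # drop a partial codon
    aa_lo = (min(nts) - 1) // 3 + 1
    aa_hi = min((max(nts) - 1) // 3 + 1, n_complete)
    if aa_lo > aa_hi:
        return None
    return aa_lo, aa_hi
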