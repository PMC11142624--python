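"""Region-rule engine, NMD calling, isoform PPI, and the 23-column table."""

import numpy as np
import pandas as pd
import pytest

from splicescope import (
    ANNOTATION_COLUMNS,
    Annotation,
    FEATURE_CLASS_GROUPS,
    Transcript,
    annotate_event,
    annotate_events,
    assemble_table,
    assign_isoform_ppi,
    build_db,
    call_nmd,
    decode_event_id,
)
from splicescope.annotate import REGION_RULES, transcript_nmd_sensitive
from splicescope.events import GenomicInterval
from splicescope.simulate import TRACK_CLASSES


def mk_tx(tx_id, exons, strand="+", cds=None, gene="G", chrom="chr1"):
    return Transcript(
        tx_id=tx_id, gene=gene, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        cds=tuple(GenomicInterval(chrom, s, e, strand) for s, e in cds) if cds else None,
    )


@pytest.fixture()
def se_locus():
    """An SE gene: upstream (900-1000), cassette (1200-1300), downstream
    (1500-1600), tail exon (1900-2000)."""
    inc = mk_tx("TI", [(900, 1000), (1200, 1300), (1500, 1600), (1900, 2000)],
                cds=[(930, 1000), (1200, 1300), (1500, 1600), (1900, 1970)])
    exc = mk_tx("TE", [(900, 1000), (1500, 1600), (1900, 2000)],
                cds=[(930, 1000), (1500, 1600), (1900, 1970)])
    ann = Annotation({"TI": inc, "TE": exc})
    event = decode_event_id("G|SE|chr1|+|1000:1200:1300:1500")
    return ann, event


def write_vcf(path, positions):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, pos in enumerate(positions):
            fh.write(f"chr1\t{pos}\tv{i}\tA\tG\t.\t.\t.\n")
    return str(path)


def write_bed(path, rows):
    with open(path, "w") as fh:
        for s1, e1, name in rows:  # 1-based inclusive input
            fh.write(f"chr1\t{s1 - 1}\t{e1}\t{name}\t0\t+\n")
    return str(path)


class TestRegionRules:
    def test_every_class_has_exactly_one_rule(self):
        genomic = set(REGION_RULES)
        assert genomic == {"CONS", "REPEAT", "MIRNA_BS", "EXON_USAGE",
                           "MUT", "SPLICE_SITE_VARIANT", "RBP_BS"}
        # the remaining five classes are handled by dedicated code paths
        assert set(FEATURE_CLASS_GROUPS) - genomic == {
            "DOMAIN", "PTM", "NMD", "PPI", "LOCALIZATION"}

    def test_mutation_boundary_window(self, se_locus, tmp_path):
        ann, event = se_locus
        # acceptor -5 bp (within w=10) in; 50 bp into the intron out
        vcf = write_vcf(tmp_path / "m.vcf", [1195, 1350])
        db = build_db(ann, {"MUT": vcf}, str(tmp_path / "db.sqlite"))
        row = annotate_event(event, db, ann, boundary_halfwidth=10)
        assert "v0" in row["MUT"] and "v1" not in row["MUT"]

    def test_boundary_edge_exact(self, se_locus, tmp_path):
        ann, event = se_locus
        # window around 1200 with w=10 spans [1190, 1210]
        vcf = write_vcf(tmp_path / "m.vcf", [1190, 1189])
        db = build_db(ann, {"SPLICE_SITE_VARIANT": vcf}, str(tmp_path / "db.sqlite"))
        row = annotate_event(event, db, ann, boundary_halfwidth=10)
        assert "v0" in row["SPLICE_SITE_VARIANT"]
        assert "v1" not in row["SPLICE_SITE_VARIANT"]

    def test_domain_on_common_exon_stays_silent(self, se_locus, tmp_path):
        ann, event = se_locus
        # aa 1..10 of TI start at genomic 930 (+30 codons = up to 959): common only
        dom = tmp_path / "dom.tsv"
        pd.DataFrame([
            {"tx_id": "TI", "aa_start": 1, "aa_end": 8, "name": "COMMON_DOM"},
        ]).to_csv(dom, sep="\t", index=False)
        db = build_db(ann, {"DOMAIN": str(dom)}, str(tmp_path / "db.sqlite"))
        row = annotate_event(event, db, ann)
        assert row["DOMAIN"] == "" and row["DOMAIN_genomic"] == ""

    def test_domain_over_cassette_populates_both_columns(self, se_locus, tmp_path):
        ann, event = se_locus
        # TI CDS: 71 nt then cassette begins at nt 72 -> aa 24 onward
        dom = tmp_path / "dom.tsv"
        pd.DataFrame([
            {"tx_id": "TI", "aa_start": 25, "aa_end": 40, "name": "CASSETTE_DOM"},
        ]).to_csv(dom, sep="\t", index=False)
        db = build_db(ann, {"DOMAIN": str(dom)}, str(tmp_path / "db.sqlite"))
        row = annotate_event(event, db, ann)
        assert "CASSETTE_DOM" in row["DOMAIN"]
        assert row["DOMAIN_genomic"] != ""

    def test_rbp_intron_in_common_exon_out(self, se_locus, tmp_path):
        ann, event = se_locus
        bed = write_bed(tmp_path / "rbp.bed", [
            (1100, 1120, "IN_INTRON"),
            (1540, 1560, "IN_COMMON_EXON"),
        ])
        db = build_db(ann, {"RBP_BS": bed}, str(tmp_path / "db.sqlite"))
        row = annotate_event(event, db, ann)
        assert "IN_INTRON" in row["RBP_BS"]
        assert "IN_COMMON_EXON" not in row["RBP_BS"]

    def test_annotation_monotone_in_database(self, se_locus, tmp_path):
        ann, event = se_locus
        bed1 = write_bed(tmp_path / "c1.bed", [(1220, 1240, "A")])
        bed2 = write_bed(tmp_path / "c2.bed", [(1220, 1240, "A"), (1250, 1260, "B")])
        db1 = build_db(ann, {"CONS": bed1}, str(tmp_path / "d1.sqlite"))
        db2 = build_db(ann, {"CONS": bed2}, str(tmp_path / "d2.sqlite"))
        r1 = annotate_event(event, db1, ann)
        r2 = annotate_event(event, db2, ann)
        for col in ANNOTATION_COLUMNS:
            if r1[col] not in ("", None):
                assert r2[col] not in ("", None)


class TestNMD:
    def test_stop_distance_threshold(self):
        # exons: 200 + 100 + 200 nt; final junction at mRNA position 300
        def tx_with_stop(stop_genomic):
            return mk_tx("T", [(1, 200), (301, 400), (501, 700)],
                         cds=[(31, 200), (301, stop_genomic)])
        # stop 60 nt upstream of the junction -> sensitive
        assert transcript_nmd_sensitive(tx_with_stop(340)) is True
        # stop 20 nt upstream -> not sensitive
        assert transcript_nmd_sensitive(tx_with_stop(380)) is False
        # exactly 50 -> not sensitive; 51 -> sensitive
        assert transcript_nmd_sensitive(tx_with_stop(350)) is False
        assert transcript_nmd_sensitive(tx_with_stop(349)) is True

    def test_stop_in_last_exon_not_sensitive(self):
        t = mk_tx("T", [(1, 200), (301, 400)], cds=[(31, 200), (301, 390)])
        assert transcript_nmd_sensitive(t) is False

    def test_no_cds_unknown(self, se_locus):
        ann, event = se_locus
        stripped = Annotation({
            t.tx_id: mk_tx(t.tx_id, [(e.start, e.end) for e in t.exons])
            for t in ann.transcripts.values()
        })
        flags = call_nmd(event, stripped)
        assert flags == {"inclusion": "unknown", "exclusion": "unknown"}

    def test_event_side_flags(self, se_locus):
        ann, event = se_locus
        flags = call_nmd(event, ann)
        assert set(flags) == {"inclusion", "exclusion"}
        assert all(v in ("sensitive", "not_sensitive", "unknown")
                   for v in flags.values())

    def test_matches_transcript_walk_oracle_randomized(self):
        """The arithmetic rule agrees with a literal walk along the mRNA."""
        rng = np.random.default_rng(41)
        checked = 0
        for _ in range(400):
            n_exons = int(rng.integers(2, 6))
            pos = 100
            exons = []
            for _ in range(n_exons):
                w = int(rng.integers(30, 250))
                exons.append((pos, pos + w - 1))
                pos += w + int(rng.integers(50, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            # random CDS end inside the exon body
            total = sum(e - s + 1 for s, e in exons)
            cds_end_mrna = int(rng.integers(10, total + 1))
            # map mRNA coord -> genomic to build the CDS
            order = exons if strand == "+" else exons[::-1]
            mrna = []
            for s, e in order:
                rangepos = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
                mrna.extend(rangepos)
            cds_start_g, cds_end_g = mrna[0], mrna[cds_end_mrna - 1]
            lo, hi = sorted((cds_start_g, cds_end_g))
            cds = [(max(s, lo), min(e, hi)) for s, e in exons
                   if not (e < lo or s > hi)]
            t = mk_tx("T", exons, strand=strand, cds=cds)
            got = transcript_nmd_sensitive(t)
            # oracle: positional walk on the explicit mRNA base list
            stop_idx = mrna.index(cds_end_g) + 1
            junction_idx = len(mrna) - (order[-1][1] - order[-1][0] + 1)
            want = (junction_idx - stop_idx) > 50
            assert got == want
            checked += 1
        assert checked == 400


class TestPPI:
    def build_db_with_ppi(self, ann, tmp_path, rows):
        path = tmp_path / "ppi.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return build_db(ann, {"PPI": str(path)}, str(tmp_path / "db.sqlite"))

    def test_partition(self, se_locus, tmp_path):
        ann, event = se_locus
        db = self.build_db_with_ppi(ann, tmp_path, [
            {"tx_id": "TI", "partner": "ONLY_INC"},
            {"tx_id": "TE", "partner": "ONLY_EXC"},
            {"tx_id": "TI", "partner": "BOTH"},
            {"tx_id": "TE", "partner": "BOTH"},
        ])
        inc, exc, shared = assign_isoform_ppi(event, db, ann)
        assert inc == ["ONLY_INC"] and exc == ["ONLY_EXC"] and shared == ["BOTH"]

    def test_no_records_all_empty(self, se_locus, tmp_path):
        ann, event = se_locus
        db = build_db(ann, {}, str(tmp_path / "db.sqlite"))
        assert assign_isoform_ppi(event, db, ann) == ([], [], [])


class TestTable:
    def test_header_only_table_has_23_columns(self):
        table = assemble_table([])
        assert len(table.columns) == 23
        assert list(table.columns) == list(ANNOTATION_COLUMNS)

    def test_schema_stable_across_rows(self, se_locus, tmp_path):
        ann, event = se_locus
        db = build_db(ann, {}, str(tmp_path / "db.sqlite"))
        table = annotate_events([event, event], db, ann)
        assert table.shape == (2, 23)
        assert list(table.columns) == list(ANNOTATION_COLUMNS)

    def test_twelve_class_groups(self):
        assert len(FEATURE_CLASS_GROUPS) == 12
        feature_cols = [c for c in ANNOTATION_COLUMNS if c in FEATURE_CLASS_GROUPS
                        or c.endswith("_genomic")]
        assert len(feature_cols) == 14  # 12 groups; DOMAIN/PTM carry 2 columns


class TestLedgerEndToEnd:
    def test_populated_columns_match_fixture_ledger(self, sim_bundle):
        """Planted tracks populate exactly the class columns the fixture
        ledger predicts, including boundary edge cases and decoys."""
        spec = sim_bundle["spec"]
        truth, ledger = sim_bundle["truth"], sim_bundle["ledger"]
        db, ann = sim_bundle["db"], sim_bundle["annotation"]
        events = [decode_event_id(i) for i in truth["event_id"]]
        table = annotate_events(events, db, ann,
                                boundary_halfwidth=spec.boundary_halfwidth)
        for i, row in table.iterrows():
            assert ledger.iloc[i]["event_id"] == row["event_id"]
            for cls in TRACK_CLASSES:
                populated = bool(str(row[cls] or "")) and str(row[cls]) != "nan"
                assert populated == bool(ledger.iloc[i][cls]), (
                    f"{row['event_id']} {cls}")
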