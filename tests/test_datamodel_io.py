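"""Container invariants and file-format round trips."""

import numpy as np
import pandas as pd
import pytest

from xscnd import io as xio
from xscnd.datamodel import (
    GenomicInterval,
    IntensityMatrix,
    MismatchTable,
    ParseError,
    ProbeSet,
    ScalingFactors,
    ValidationError,
)

from conftest import make_matrix

SEQ_A = "ACGTACGTACGTACGTACGTACGTA"
SEQ_B = "TTGCATTGCATTGCATTGCATTGCA"


class TestProbeAnnotation:
    def test_two_row_file_yields_one_probeset(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "probeset_id\tprobe_index\tsequence\n"
            f"ps1\t1\t{SEQ_A}\nps1\t2\t{SEQ_B}\n"
        )
        sets = xio.read_probe_annotation(p)
        assert len(sets) == 1 and sets[0].n_probes == 2
        assert sets[0].sequences() == {1: SEQ_A, 2: SEQ_B}

    def test_short_sequence_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "probeset_id\tprobe_index\tsequence\n" f"ps1\t1\t{SEQ_A[:24]}\n"
        )
        with pytest.raises(ParseError, match=":2"):
            xio.read_probe_annotation(p)

    def test_duplicate_probe_index_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "probeset_id\tprobe_index\tsequence\n"
            f"ps1\t1\t{SEQ_A}\nps1\t1\t{SEQ_B}\n"
        )
        with pytest.raises(ParseError, match="duplicate"):
            xio.read_probe_annotation(p)

    def test_round_trip_with_coordinates(self, tmp_path):
        sets = [
            ProbeSet("ps1", [(1, SEQ_A), (2, SEQ_B)], "g1",
                     GenomicInterval("chr1", 100, 4100, "-")),
            ProbeSet("ps2", [(1, SEQ_B)], "g2"),
        ]
        p = tmp_path / "ann.tsv"
        xio.write_probe_annotation(sets, p)
        back = xio.read_probe_annotation(p)
        assert [s.probeset_id for s in back] == ["ps1", "ps2"]
        assert back[0].probes == sets[0].probes
        assert back[0].coords == sets[0].coords
        assert back[1].coords is None


class TestIntensityIO:
    def _matrix(self):
        return make_matrix(
            {"h1": [10, 20, 30, 40], "h2": [11, 21, 31, 41],
             "x1": [5, 6, 7, 8], "x2": [5, 6, 7, 9]},
            [("h1", "home", 1), ("h2", "home", 2), ("x1", "het", 1), ("x2", "het", 2)],
            [("psA", 1), ("psA", 2), ("psB", 1), ("psB", 2)],
        )

    def test_wide_round_trip_preserves_sample_order(self, tmp_path):
        m = self._matrix()
        p = tmp_path / "wide.tsv"
        xio.write_intensities(m, p, layout="wide")
        back = xio.read_intensities(p)
        assert back.sample_ids == m.sample_ids
        pd.testing.assert_frame_equal(back.values, m.values)
        pd.testing.assert_frame_equal(back.samples, m.samples)

    def test_long_layout_equals_wide(self, tmp_path):
        m = self._matrix()
        pw, pl = tmp_path / "w.tsv", tmp_path / "l.tsv"
        xio.write_intensities(m, pw, layout="wide")
        xio.write_intensities(m, pl, layout="long")
        wide, long = xio.read_intensities(pw), xio.read_intensities(pl)
        pd.testing.assert_frame_equal(wide.values, long.values)
        pd.testing.assert_frame_equal(wide.samples, long.samples.astype(wide.samples.dtypes))

    def test_negative_intensity_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text(
            "#sample\ts1\thome\t1\n"
            "probeset_id\tprobe_index\ts1\nps1\t1\t-3.0\n"
        )
        with pytest.raises(ParseError, match="negative"):
            xio.read_intensities(p)

    def test_missing_species_label_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#sample\ts1\t\t1\n"
            "probeset_id\tprobe_index\ts1\nps1\t1\t3.0\n"
        )
        with pytest.raises(ParseError, match="species"):
            xio.read_intensities(p)


class TestSmallTableRoundTrips:
    def test_truth_set(self, tmp_path):
        truth = pd.Series(
            {"g1": "expanded", "g2": "single_copy", "g3": "reduced"}, name="status"
        )
        p = tmp_path / "truth.tsv"
        xio.write_truth_set(truth, p)
        back = xio.read_truth_set(p)
        pd.testing.assert_series_equal(back.sort_index(), truth.sort_index(),
                                       check_names=False)

    def test_truth_rejects_unknown_status(self, tmp_path):
        p = tmp_path / "truth.tsv"
        p.write_text("gene_id\tstatus\ng1\ttriplicated\n")
        with pytest.raises(ValidationError):
            xio.read_truth_set(p)

    def test_mismatch_table(self, tmp_path):
        mm = MismatchTable(
            pd.Series([0, 2], index=pd.MultiIndex.from_tuples(
                [("ps1", 1), ("ps1", 2)], names=["probeset_id", "probe_index"])),
            species="het",
        )
        p = tmp_path / "mm.tsv"
        xio.write_mismatch_table(mm, p)
        back = xio.read_mismatch_table(p)
        pd.testing.assert_series_equal(back.k, mm.k, check_names=False)
        assert back.species == "het"

    def test_scaling_factors_yaml(self, tmp_path):
        sf = ScalingFactors(
            pd.DataFrame({"S_k": [1.0, 1.6, 1.8], "N_k": [10, 12, 3]},
                         index=pd.Index([0, 1, 2], name="k")),
            S=1.4, renormalized=True, interpolated=(2,),
        )
        p = tmp_path / "sf.yaml"
        xio.write_scaling_factors(sf, p)
        back = xio.read_scaling_factors(p)
        assert back.S == pytest.approx(1.4)
        assert back.renormalized and back.interpolated == (2,)
        pd.testing.assert_frame_equal(
            back.per_k.astype(float), sf.per_k.astype(float), check_names=False
        )

    def test_category_map_round_trip(self, tmp_path):
        cats = pd.DataFrame(
            {"probeset_id": ["ps1", "ps1", "ps2"],
             "category": ["BIN01", "BIN02", "BIN01"],
             "name": ["metal handling", "", "metal handling"]}
        )
        p = tmp_path / "cats.tsv"
        xio.write_category_map(cats, p)
        back = xio.read_category_map(p)
        pd.testing.assert_frame_equal(back, cats)

    def test_target_fasta_round_trip(self, tmp_path):
        targets = {("ps1", 1): SEQ_A, ("ps2", 3): SEQ_B}
        p = tmp_path / "targets.fasta"
        xio.write_target_fasta(targets, p)
        assert xio.read_target_fasta(p) == targets


class TestIntervalIO:
    def test_bed_round_trip(self, tmp_path):
        bed = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 500], "end": [200, 900],
             "name": ["a", "b"], "score": [1, 2]}
        )
        p = tmp_path / "x.bed"
        xio.write_bed(bed, p)
        back = xio.read_bed(p)
        pd.testing.assert_frame_equal(back, bed)

    def test_gff_converts_to_zero_based(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t300\t.\t+\t.\tID=g1;Name=foo\n"
            "chr1\tsrc\texon\t101\t160\t.\t+\t.\tID=e1\n"
        )
        genes = xio.read_gff_genes(p)
        assert len(genes) == 1
        row = genes.iloc[0]
        assert (row["start"], row["end"], row["name"]) == (100, 300, "g1")


class TestContainerInvariants:
    def test_interval_requires_end_after_start(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)

    def test_probeset_rejects_duplicate_index(self):
        with pytest.raises(ValidationError):
            ProbeSet("ps1", [(1, SEQ_A), (1, SEQ_B)])

    def test_matrix_rejects_negative_linear_values(self):
        with pytest.raises(ValidationError):
            make_matrix({"s1": [-1.0], "s2": [1.0]},
                        [("s1", "home", 1), ("s2", "home", 2)], [("ps1", 1)])

    def test_select_species_and_masking(self):
        m = make_matrix(
            {"h1": [1, 2], "x1": [3, 4]},
            [("h1", "home", 1), ("x1", "het", 1)],
            [("psA", 1), ("psB", 1)],
        )
        m.mask.loc[("psB", 1)] = True
        sub = m.select_species("het")
        assert sub.sample_ids == ["x1"]
        assert sub.unmasked().shape[0] == 1
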