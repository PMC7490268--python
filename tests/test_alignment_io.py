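"""Codon alignments: validation, the cleandata policy, FASTA round-trips,
plate layouts and configuration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sporefit.alignment import CodonAlignment
from sporefit.codes import standard_code
from sporefit.io import (
    PipelineConfig,
    default_ff_layout,
    read_codon_fasta,
    write_codon_fasta,
)
from sporefit.io.layout import PlateLayout


class TestCodonAlignment:
    def test_two_sequences_of_nine_nt_give_three_columns(self):
        aln = CodonAlignment.from_sequences([("a", "ATGGCTAAA"), ("b", "ATGGCAAAA")])
        assert aln.n_taxa == 2 and aln.n_sites == 3
        assert aln.sequence("a") == "ATGGCTAAA"

    def test_internal_stop_raises_under_strict_policy_naming_taxon(self):
        with pytest.raises(ValueError, match=r"column 2.*stop.*b"):
            CodonAlignment.from_sequences(
                [("a", "ATGGCTAAA"), ("b", "ATGTAAAAA")], cleandata=False
            )

    def test_cleandata_drops_gap_and_stop_columns_with_warning(self):
        with pytest.warns(UserWarning, match="dropped 2 of 3"):
            aln = CodonAlignment.from_sequences(
                [("a", "ATG---AAA"), ("b", "ATGGCTTAA")]
            )
        assert aln.n_sites == 1

    def test_unequal_lengths_and_duplicates_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            CodonAlignment.from_sequences([("a", "ATGGCT"), ("b", "ATG")])
        with pytest.raises(ValueError, match="duplicate"):
            CodonAlignment.from_sequences([("a", "ATGGCT"), ("a", "ATGGCA")])

    def test_site_patterns_compress_duplicate_columns(self):
        aln = CodonAlignment.from_sequences([("a", "ATGATGGCT"), ("b", "ATGATGAAA")])
        cols, inverse, counts = aln.site_patterns()
        assert cols.shape[1] == 2
        assert counts.sum() == 3
        assert (cols[:, inverse].T == aln.codons.T).all()


class TestFastaRoundtrip:
    def test_write_then_read_identical(self, tmp_path):
        aln = CodonAlignment.from_sequences(
            [("tax1", "ATGGCTAAAGGG"), ("tax2", "ATGGCAAAAGGC")]
        )
        path = tmp_path / "aln.fasta"
        write_codon_fasta(aln, path)
        back = read_codon_fasta(path)
        assert back.taxa == aln.taxa
        assert (back.codons == aln.codons).all()

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_random_alignment_roundtrip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        code = standard_code()
        n_taxa, n_sites = int(rng.integers(2, 6)), int(rng.integers(1, 40))
        codons = rng.integers(0, 61, size=(n_taxa, n_sites))
        aln = CodonAlignment(taxa=[f"s{i}" for i in range(n_taxa)], codons=codons)
        path = tmp_path_factory.mktemp("fa") / "r.fasta"
        write_codon_fasta(aln, path)
        back = read_codon_fasta(path)
        assert (back.codons == aln.codons).all()

    def test_duplicate_names_in_file_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">x\nATGGCT\n>x\nATGGCA\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_codon_fasta(path)


class TestPlateLayout:
    def test_packaged_layout_has_96_wells_and_one_water(self):
        layout = default_ff_layout()
        assert len(layout) == 96
        assert layout.water_well == "A1"
        assert len(set(layout.values())) == 96  # 95 sources + water, all distinct

    def test_wrong_well_count_rejected(self):
        with pytest.raises(ValueError, match="96 wells"):
            PlateLayout({"A1": "Water", "A2": "Sucrose"})


class TestPipelineConfig:
    def test_defaults_validate(self):
        PipelineConfig().validate()

    def test_bad_alpha_and_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            PipelineConfig(alpha=1.5).validate()
        with pytest.raises(ValueError, match="unknown stage"):
            PipelineConfig(stages=("repaint", "nope")).validate()

    def test_missing_path_rejected(self):
        with pytest.raises(FileNotFoundError):
            PipelineConfig(layout_csv="/nonexistent/layout.csv").validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig(seed=7, n_plates=1, stages=("fitness",))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = PipelineConfig.from_yaml(path)
        assert again == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            PipelineConfig.from_yaml(path)


class TestImageRoundtrip:
    def test_plate_and_label_images_roundtrip_losslessly(self, tmp_path):
        from sporefit.io import (
            read_label_image,
            read_plate_image,
            write_label_image,
            write_plate_image,
        )
        from sporefit.synth import PlateSpec, generate_plate_image

        spec = PlateSpec(n_rows=2, n_cols=3, image_width_px=180,
                         image_height_px=140, seed=5)
        image, truth = generate_plate_image(spec)
        write_plate_image(image, tmp_path / "plate.png")
        write_label_image(truth.pixel_labels, tmp_path / "labels.png")
        assert (read_plate_image(tmp_path / "plate.png") == image).all()
        assert (read_label_image(tmp_path / "labels.png") == truth.pixel_labels).all()
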