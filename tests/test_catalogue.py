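import datetime
import itertools

import numpy as np
import pandas as pd
import pytest

from finpigment import synth
from finpigment.catalogue import (
    ANGLE_SCORES,
    CLARITY_SCORES,
    CONTRAST_SCORES,
    EDGE_SCORES,
    Catalogue,
    CatalogueError,
    FinPhoto,
    GradeThresholds,
    filter_by_grade,
    pq_score,
    read_catalogue,
    write_catalogue,
)

ALL_COMBINATIONS = list(
    itertools.product(CLARITY_SCORES, CONTRAST_SCORES, ANGLE_SCORES, EDGE_SCORES)
)


def _photo(image_id="p1", individual="D1", shape=(20, 20), grade=None):
    mask = np.zeros(shape, dtype=bool)
    mask[5:15, 5:15] = True
    pixels = np.full(shape, 100, dtype=np.uint8)
    pixels[6:9, 6:12] = 40
    return FinPhoto(
        image_id=image_id,
        individual_id=individual,
        date=datetime.date(2010, 3, 2),
        session_id="s1",
        pixels=pixels,
        mask=mask,
        grade=grade,
    )


class TestFinPhoto:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(CatalogueError, match="does not match"):
            FinPhoto("x", "D1", datetime.date(2010, 1, 1), "s", np.zeros((5, 5)), np.ones((4, 4), bool))

    def test_empty_mask_rejected(self):
        with pytest.raises(CatalogueError, match="empty mask"):
            FinPhoto("x", "D1", datetime.date(2010, 1, 1), "s", np.zeros((5, 5)), np.zeros((5, 5), bool))

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = True
        mask[8, 8] = True
        with pytest.raises(CatalogueError, match="components"):
            FinPhoto("x", "D1", datetime.date(2010, 1, 1), "s", np.zeros((10, 10)), mask)

    def test_diagonal_touch_is_two_components(self):
        # 4-connectivity: diagonal neighbours are separate components
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = True
        mask[3, 3] = True
        with pytest.raises(CatalogueError, match="components"):
            FinPhoto("x", "D1", datetime.date(2010, 1, 1), "s", np.zeros((10, 10)), mask)


class TestCatalogue:
    def test_duplicate_image_id_rejected(self):
        with pytest.raises(CatalogueError, match="duplicate"):
            Catalogue([_photo("a"), _photo("a")])

    def test_individuals_set(self):
        cat = Catalogue([_photo("a", "D1"), _photo("b", "D2"), _photo("c", "")])
        assert cat.individuals == {"D1", "D2"}


class TestReadWrite:
    def test_round_trip_small(self, tmp_path):
        cat = Catalogue([_photo("a", "D1"), _photo("b", "D2")])
        csv = write_catalogue(cat, tmp_path)
        back = read_catalogue(csv)
        assert len(back) == 2
        assert back.individuals == {"D1", "D2"}
        for orig, re_read in zip(cat, back):
            assert orig.image_id == re_read.image_id
            assert orig.date == re_read.date
            np.testing.assert_array_equal(orig.mask, re_read.mask)
            np.testing.assert_array_equal(orig.pixels, re_read.pixels)

    def test_synthetic_round_trip_bit_identical(self, tmp_path, small_catalogue):
        catalogue, gt = small_catalogue
        csv = synth.write_synthetic_catalogue(catalogue, gt, tmp_path)
        back = read_catalogue(csv)
        assert len(back) == len(catalogue)
        for orig, re_read in zip(catalogue, back):
            assert orig.image_id == re_read.image_id
            assert orig.individual_id == re_read.individual_id
            assert orig.date == re_read.date
            assert orig.session_id == re_read.session_id
            np.testing.assert_array_equal(orig.pixels, re_read.pixels)
            np.testing.assert_array_equal(orig.mask, re_read.mask)

    def test_missing_file_fatal(self, tmp_path):
        pd.DataFrame(
            [
                {
                    "image_id": "a",
                    "individual_id": "D1",
                    "date": "2010-01-01",
                    "session_id": "s",
                    "image_file": "nope.png",
                    "mask_file": "nope_mask.png",
                }
            ]
        ).to_csv(tmp_path / "metadata.csv", index=False)
        with pytest.raises(CatalogueError, match="not found"):
            read_catalogue(tmp_path / "metadata.csv")

    def test_all_false_mask_fatal(self, tmp_path):
        from PIL import Image

        Image.fromarray(np.full((8, 8), 50, np.uint8)).save(tmp_path / "img.png")
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(tmp_path / "msk.png")
        pd.DataFrame(
            [
                {
                    "image_id": "a",
                    "individual_id": "D1",
                    "date": "2010-01-01",
                    "session_id": "s",
                    "image_file": "img.png",
                    "mask_file": "msk.png",
                }
            ]
        ).to_csv(tmp_path / "metadata.csv", index=False)
        with pytest.raises(CatalogueError, match="empty mask"):
            read_catalogue(tmp_path / "metadata.csv")


class TestPQScore:
    def test_all_excellent_total_35(self):
        grade = pq_score("excellent", "excellent", "excellent", "excellent")
        assert grade.total == 35
        assert grade.grade_label == "excellent"

    def test_all_poor_total_4(self):
        grade = pq_score("poor", "poor", "poor", "poor_reasonable")
        assert grade.total == 4
        assert grade.grade_label == "poor"

    def test_single_poor_category_forces_poor(self):
        grade = pq_score("poor", "excellent", "excellent", "excellent")
        assert grade.total == 27
        assert grade.grade_label == "poor"

    def test_unknown_label_rejected(self):
        with pytest.raises(CatalogueError, match="unknown"):
            pq_score("amazing", "excellent", "excellent", "excellent")

    @pytest.mark.parametrize("clarity,contrast,angle,edge", ALL_COMBINATIONS)
    def test_total_is_sum_of_mapped_scores(self, clarity, contrast, angle, edge):
        grade = pq_score(clarity, contrast, angle, edge)
        expected = (
            CLARITY_SCORES[clarity] + CONTRAST_SCORES[contrast] + ANGLE_SCORES[angle] + EDGE_SCORES[edge]
        )
        assert grade.total == expected

    def test_any_minimum_category_rates_poor_over_all_54_combinations(self):
        # the weighting rule: inadequate quality in one category alone
        # ensures a poor rating, regardless of the other categories
        for clarity, contrast, angle, edge in ALL_COMBINATIONS:
            grade = pq_score(clarity, contrast, angle, edge)
            has_min = (
                CLARITY_SCORES[clarity] == 1
                or CONTRAST_SCORES[contrast] == 1
                or ANGLE_SCORES[angle] == 1
                or EDGE_SCORES[edge] == 1
            )
            if has_min:
                assert grade.grade_label == "poor", (clarity, contrast, angle, edge)
            elif grade.total >= 30:
                assert grade.grade_label == "excellent"
            elif grade.total >= 20:
                assert grade.grade_label == "good"
            else:
                assert grade.grade_label == "poor"

    def test_custom_thresholds(self):
        grade = pq_score("reasonable", "reasonable", "reasonable", "excellent",
                         thresholds=GradeThresholds(good=10, excellent=17))
        assert grade.total == 17
        assert grade.grade_label == "excellent"


class TestFilterByGrade:
    def _graded_catalogue(self):
        photos = []
        combos = [
            ("excellent", "excellent", "excellent", "excellent"),  # excellent
            ("reasonable", "reasonable", "reasonable", "excellent"),  # poor (17 < 20)
            ("excellent", "reasonable", "excellent", "excellent"),  # excellent (29 -> good)
            ("poor", "excellent", "excellent", "excellent"),  # poor
        ]
        for i, combo in enumerate(combos):
            photos.append(_photo(f"p{i}", f"D{i}", grade=pq_score(*combo)))
        return Catalogue(photos)

    def test_counts(self):
        cat = self._graded_catalogue()
        kept = filter_by_grade(cat, {"good", "excellent"})
        assert len(kept) == 2
        assert [p.image_id for p in kept] == ["p0", "p2"]

    def test_keep_all_is_identity(self):
        cat = self._graded_catalogue()
        kept = filter_by_grade(cat, {"poor", "good", "excellent"})
        assert [p.image_id for p in kept] == [p.image_id for p in cat]

    def test_contents_unchanged(self):
        cat = self._graded_catalogue()
        kept = filter_by_grade(cat, {"excellent"})
        for photo in kept:
            original = cat[photo.image_id]
            assert photo is original

    def test_exhaustive_excellent_filter_matches_brute_force(self):
        photos = []
        for i, combo in enumerate(ALL_COMBINATIONS):
            photos.append(_photo(f"p{i}", f"D{i}", grade=pq_score(*combo)))
        cat = Catalogue(photos)
        kept = filter_by_grade(cat, {"excellent"})
        expected = {
            f"p{i}" for i, combo in enumerate(ALL_COMBINATIONS) if pq_score(*combo).grade_label == "excellent"
        }
        assert {p.image_id for p in kept} == expected
        assert len(expected) > 0

    def test_empty_result_warns(self):
        cat = self._graded_catalogue()
        with pytest.warns(UserWarning, match="no photos"):
            kept = filter_by_grade(cat, {"nonexistent"})
        assert len(kept) == 0

    def test_ungraded_photo_rejected(self):
        cat = Catalogue([_photo("a")])
        with pytest.raises(CatalogueError, match="grade"):
            filter_by_grade(cat, {"good"})
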