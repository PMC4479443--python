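"""Region identification: descriptors, containment, nucleus/cell rules."""

import numpy as np
import pytest
from skimage import measure

from conftest import disc_mask, fused_discs
from leukosmear.regions import (
    IdentificationRules,
    compute_region_descriptors,
    containment_proportion,
    identify_cells,
    identify_nuclei,
    induce_shape_thresholds,
)


def _region_of(mask, intensity=None):
    regions = compute_region_descriptors(mask, intensity=intensity)
    assert len(regions) == 1
    return regions[0]


class TestDescriptors:
    def test_filled_square(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        r = _region_of(mask)
        assert r.area == 100
        assert r.bbox == (5, 5, 15, 15)

    def test_digital_disc_circularity(self):
        mask = disc_mask((60, 60), (30, 30), 20)
        r = _region_of(mask)
        assert 0.95 <= r.circularity <= 1.25
        # oracle: independent sub-pixel contour (marching squares) perimeter
        contour = measure.find_contours(mask.astype(float), 0.5)[0]
        perim = np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum()
        oracle_circ = perim**2 / (4 * np.pi * mask.sum())
        assert r.circularity == pytest.approx(oracle_circ, rel=0.15)

    def test_rectangle_eccentricity(self):
        mask = np.zeros((50, 20), dtype=bool)
        mask[5:45, 5:15] = True
        r = _region_of(mask)
        # oracle: second-moment ellipse of a uniform a x b rectangle
        a, b = 40.0, 10.0
        ecc = np.sqrt(1 - (b / a) ** 2)
        assert r.eccentricity > 0.9
        assert r.eccentricity == pytest.approx(ecc, abs=0.02)

    def test_empty_mask(self):
        assert compute_region_descriptors(np.zeros((5, 5), dtype=bool)) == []

    def test_mean_intensity_descriptor(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        intensity = np.full((10, 10), 40.0)
        intensity[mask] = 11.0
        r = _region_of(mask.astype(int), intensity=intensity)
        assert r.mean_L == pytest.approx(11.0)


class TestContainment:
    def test_full_containment(self):
        inner = _region_of(disc_mask((50, 50), (25, 25), 8))
        outer = _region_of(disc_mask((50, 50), (25, 25), 20))
        assert containment_proportion(inner, outer) == pytest.approx(1.0)

    def test_disjoint(self):
        a = _region_of(disc_mask((50, 100), (25, 25), 10))
        b = _region_of(disc_mask((50, 100), (25, 75), 10))
        assert containment_proportion(a, b) == 0.0

    def test_half_inside(self):
        inner = np.zeros((20, 20), dtype=bool)
        inner[8:12, 6:14] = True  # 32 px, half left of column 10
        outer = np.zeros((20, 20), dtype=bool)
        outer[:, :10] = True
        ri = _region_of(inner)
        ro = _region_of(outer)
        assert containment_proportion(ri, ro) == pytest.approx(0.5)

    def test_empty_inner_rejected(self):
        r = _region_of(disc_mask((20, 20), (10, 10), 5))
        empty = r.__class__(
            instance_id=99,
            mask=np.zeros((20, 20), dtype=bool),
            area=0,
            perimeter=0,
            centroid=(0, 0),
            circularity=1,
            eccentricity=0,
            mean_L=0,
            bbox=(0, 0, 0, 0),
        )
        with pytest.raises(ValueError):
            containment_proportion(empty, r)


class TestIdentifyNuclei:
    def test_round_region_is_nucleus(self):
        r = _region_of(disc_mask((60, 60), (30, 30), 15))
        parts = identify_nuclei([r])
        assert parts["nucleus"] == [r]

    def test_dumbbell_is_overlapped(self):
        mask = fused_discs([(30, 25), (30, 50)], radius=17, shape=(60, 80))
        r = _region_of(mask)
        single = _region_of(disc_mask((60, 60), (30, 30), 17))
        # oracle: a fused-disc contour is strictly less circular than a disc
        assert r.circularity > single.circularity
        parts = identify_nuclei([r], IdentificationRules(circ_max=1.10, ecc_max=0.70))
        assert parts["overlapped"] == [r]

    def test_speck_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:6, 5:10] = True  # 5 px
        parts = identify_nuclei([_region_of(mask)])
        assert parts["reject"]

    def test_partition_complete(self):
        regions = [
            _region_of(disc_mask((60, 60), (30, 30), 15)),
            _region_of(fused_discs([(30, 25), (30, 50)], radius=16, shape=(60, 80))),
            _region_of(disc_mask((20, 20), (10, 10), 2)),
        ]
        parts = identify_nuclei(regions, IdentificationRules(circ_max=1.10, ecc_max=0.70))
        assert sum(len(v) for v in parts.values()) == len(regions)


class TestIdentifyCells:
    def _scene(self, containment_shift=0):
        """One cell with a darker nucleus, optional nucleus shift out of the cell."""
        shape = (80, 80)
        cell = disc_mask(shape, (40, 40), 22)
        nucleus = disc_mask(shape, (40, 40 + containment_shift), 12)
        intensity = np.full(shape, 90.0)
        intensity[cell] = 70.0
        intensity[nucleus] = 35.0
        cr = compute_region_descriptors(cell, intensity=intensity)
        nr = compute_region_descriptors(nucleus, intensity=intensity)
        return cr, nr

    def test_single_ok_record(self):
        cells, nuclei = self._scene()
        records, unmatched = identify_cells(cells, nuclei)
        assert len(records) == 1 and records[0].flag == "ok"
        assert not unmatched
        assert not (records[0].cytoplasm_mask & records[0].nucleus.mask).any()

    def test_two_nuclei_flags_overlapped(self):
        shape = (80, 120)
        cell = fused_discs([(40, 40), (40, 75)], radius=24, shape=shape)
        n1 = disc_mask(shape, (40, 35), 10)
        n2 = disc_mask(shape, (40, 80), 10)
        intensity = np.full(shape, 90.0)
        intensity[cell] = 70.0
        intensity[n1 | n2] = 35.0
        cells = compute_region_descriptors(cell, intensity=intensity)
        nuclei = compute_region_descriptors(n1.astype(int) + 2 * n2.astype(int), intensity=intensity)
        records, _ = identify_cells(cells, nuclei)
        assert len(records) == 1 and records[0].flag == "overlapped"
        assert records[0].extra_nuclei

    def test_low_containment_unmatched(self):
        # nucleus pushed so containment < 95% threshold
        cells, nuclei = self._scene(containment_shift=14)
        c = containment_proportion(nuclei[0], cells[0])
        assert c < 0.95
        records, unmatched = identify_cells(cells, nuclei)
        assert not records
        assert unmatched == nuclei

    def test_nucleus_not_darker_rejected(self):
        shape = (80, 80)
        cell = disc_mask(shape, (40, 40), 22)
        nucleus = disc_mask(shape, (40, 40), 12)
        intensity = np.full(shape, 90.0)
        intensity[cell] = 40.0
        intensity[nucleus] = 80.0  # brighter than the cytoplasm: not a nucleus relation
        cells = compute_region_descriptors(cell, intensity=intensity)
        nuclei = compute_region_descriptors(nucleus, intensity=intensity)
        records, unmatched = identify_cells(cells, nuclei)
        assert not records and unmatched


class TestRuleInduction:
    def test_thresholds_separate_training_shapes(self):
        rng = np.random.default_rng(0)
        regular, irregular = [], []
        for i in range(20):
            r = int(rng.integers(10, 18))
            regular.append(_region_of(disc_mask((60, 60), (30, 30), r)))
            gap = int(rng.integers(18, 26))
            irregular.append(
                _region_of(fused_discs([(30, 20), (30, 20 + gap)], radius=14, shape=(60, 80)))
            )
        rules = induce_shape_thresholds(regular, irregular)
        for r in regular:
            assert r.circularity <= rules.circ_max and r.area <= rules.max_area
        flagged = [
            i for i in irregular if i.circularity > rules.circ_max or i.area > rules.max_area
        ]
        assert len(flagged) >= 18  # rules flag nearly every irregular example
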