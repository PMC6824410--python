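"""Curated reference tracks from a published multi-cohort Merino scan.

Three small summary tables from a genome-wide selection-signature study of
Merino and Merino-derived sheep (Illumina OvineSNP50 data, Oar_V4
coordinates) are embedded here as plain data:

* ``ANCESTRY_REGIONS`` -- Merino-ancestry-excess intervals called per breed
  by the local-ancestry scan, for the regions shared by at least three of
  the four tested breeds (start/end SNP, position, region MAA);
* ``OUTLIER_CONSENSUS`` -- SNPs of the four consensus regions from nine
  pair-wise F_ST-outlier comparisons, with the per-SNP count N of
  comparisons significant at q < 0.05;
* ``ROH_ISLANDS`` -- per-breed ROH islands (locus-homozygosity threshold,
  intervals, member-SNP counts).

They serve as worked-example inputs and as regression fixtures for the
interval operations (region construction, strict intersection, cross-breed
island overlap), which are exactly recomputable from these printed values.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import SnpMap
from .fst_outlier import ConsensusTrack
from .local_ancestry import SignalRegion
from .roh_islands import IslandTrack

__all__ = [
    "ANCESTRY_REGIONS",
    "OUTLIER_CONSENSUS",
    "ROH_ISLANDS",
    "ancestry_region_objects",
    "outlier_consensus_track",
    "roh_island_tracks",
]

# breed -> chromosome -> (start_snp, start_bp, end_snp, end_bp, region MAA)
ANCESTRY_REGIONS: dict[str, dict[int, tuple[str, int, str, int, float]]] = {
    "Australian Merino": {
        5: ("rs418698529", 26_341_551, "rs414589041", 56_778_930, 1.00),
        13: ("rs421927509", 62_007_588, "rs421743434", 82_928_768, 1.00),
        14: ("rs405740814", 173_039, "rs409789065", 18_615_310, 1.00),
        15: ("rs398486856", 747_553, "rs417609233", 48_071_326, 0.97),
        16: ("rs429048373", 41_142_879, "rs399764897", 49_217_439, 0.93),
        17: ("rs398968259", 20_314_798, "rs414015395", 71_582_708, 0.97),
        18: ("rs416601769", 42_864_163, "rs416850669", 51_943_741, 0.97),
        19: ("rs409364012", 28_430_094, "rs412219091", 53_122_560, 0.97),
    },
    "Chinese Merino": {
        5: ("rs414589041", 56_778_930, "rs415945949", 66_146_282, 0.97),
        13: ("rs160614980", 67_099_575, "rs421743434", 82_928_768, 0.97),
        14: ("rs403113459", 6_678_882, "rs423800989", 12_841_601, 0.97),
        17: ("rs424790285", 47_829_307, "rs400781870", 72_084_885, 0.95),
        18: ("rs414805156", 33_332_554, "rs400436533", 59_172_019, 1.00),
        19: ("rs419333175", 31_614_145, "rs412185520", 60_327_629, 0.97),
    },
    "Sopravissana": {
        5: ("rs409779782", 34_321_292, "rs407964514", 56_019_746, 0.89),
        15: ("rs430560325", 24_611_939, "rs410686010", 42_463_484, 0.87),
        16: ("rs419085314", 41_237_027, "rs421054947", 55_127_918, 0.91),
        17: ("rs419855399", 46_130_137, "rs411845108", 58_410_640, 0.91),
        18: ("rs401597794", 28_792_875, "rs415998758", 68_381_958, 0.83),
    },
    "Spanish Merino": {
        13: ("rs160604475", 63_340_057, "rs421743434", 82_928_768, 0.92),
        14: ("rs405740814", 173_039, "rs407274307", 22_608_758, 0.80),
        15: ("rs398442436", 19_097_698, "rs404810360", 39_888_859, 0.96),
        16: ("rs403615656", 31_260_763, "rs408523982", 54_928_813, 0.92),
        17: ("rs426738329", 48_474_658, "rs414015395", 71_582_708, 0.88),
        18: ("rs415215918", 42_698_731, "rs415998758", 68_381_958, 0.88),
        19: ("rs408609148", 34_392_185, "rs412185520", 60_327_629, 0.84),
    },
}

# (chromosome, snp_id, position_bp, N significant comparisons out of 9)
OUTLIER_CONSENSUS: list[tuple[int, str, int, int]] = [
    (3, "rs429917763", 153_826_281, 2),
    (3, "rs426111530", 153_889_169, 2),
    (3, "rs408016275", 153_927_239, 3),
    (3, "rs414901427", 153_976_304, 3),
    (3, "rs409568101", 153_996_225, 1),
    (3, "rs416115321", 154_033_734, 2),
    (3, "rs423370130", 154_072_493, 6),
    (3, "rs417916710", 154_223_123, 2),
    (3, "rs159858948", 154_318_689, 3),
    (10, "rs419203432", 29_392_142, 3),
    (10, "rs401979890", 29_413_536, 6),
    (10, "rs413264476", 29_453_722, 1),
    (10, "rs424871667", 29_479_711, 5),
    (10, "rs399348601", 29_489_616, 3),
    (10, "rs425859016", 29_660_838, 1),
    (10, "rs404720287", 29_685_665, 2),
    (10, "rs415997827", 29_742_016, 2),
    (10, "rs414794714", 29_776_019, 5),
    (13, "rs401457425", 62_707_138, 4),
    (13, "rs415003205", 62_747_155, 9),
    (19, "rs421064536", 454_178, 1),
    (19, "rs409839516", 504_608, 2),
    (19, "rs404730996", 566_456, 5),
    (19, "rs424406294", 607_539, 1),
]

# breed -> (locus-homozygosity threshold, [(chrom, start_bp, end_bp, n_snps)])
ROH_ISLANDS: dict[str, tuple[float, list[tuple[int, int, int, int]]]] = {
    "Australian Merino": (0.196, [
        (3, 33_232_651, 34_050_238, 19),
        (25, 19_861_459, 20_568_885, 15),
        (25, 21_904_797, 22_347_925, 13),
    ]),
    "Spanish Merino": (0.231, [
        (1, 249_023_519, 249_191_465, 5),
        (6, 32_912_993, 35_003_625, 47),
        (6, 37_126_564, 38_480_285, 30),
        (6, 39_589_194, 39_715_842, 4),
        (6, 40_342_592, 43_655_868, 72),
        (7, 1_830_665, 3_913_607, 45),
        (12, 31_598_245, 34_784_182, 72),
        (12, 38_121_281, 38_765_181, 15),
        (12, 41_659_697, 42_066_590, 8),
        (12, 47_013_871, 52_019_776, 93),
        (12, 53_371_161, 56_327_304, 61),
        (12, 63_599_219, 64_794_499, 26),
    ]),
    "Gentile di Puglia": (0.166, [
        (1, 211_018_133, 216_875_491, 107),
        (1, 270_012_629, 271_410_339, 28),
        (2, 99_442_340, 101_718_337, 110),
        (2, 202_780_179, 203_472_364, 20),
        (2, 217_829_936, 223_681_332, 116),
        (2, 223_981_060, 226_600_106, 55),
        (2, 240_008_834, 243_300_137, 61),
        (3, 211_410_359, 218_603_858, 139),
        (5, 93_955, 3_046_488, 66),
        (5, 25_728_102, 28_636_862, 65),
        (10, 13_800_857, 13_988_776, 5),
        (10, 14_165_558, 20_000_839, 111),
        (10, 20_273_388, 23_396_844, 64),
        (12, 44_162_620, 52_019_776, 154),
        (12, 70_838_617, 78_861_071, 151),
        (17, 8_532_536, 9_566_661, 21),
        (17, 17_289_600, 17_844_323, 10),
        (18, 3_363_915, 6_142_721, 47),
        (22, 11_697_681, 12_751_792, 20),
        (26, 8_124_065, 13_498_474, 91),
        (26, 17_062_097, 19_422_382, 38),
    ]),
    "Sopravissana": (0.208, [
        (5, 65_184_537, 69_108_780, 79),
        (5, 72_592_808, 73_484_347, 20),
        (5, 73_814_249, 81_172_608, 150),
        (15, 17_158_900, 22_517_143, 94),
        (22, 18_932_514, 24_872_911, 109),
        (22, 28_773_373, 30_395_735, 29),
    ]),
    "Chinese Merino": (0.261, [
        (2, 92_669_379, 95_401_516, 60),
        (2, 95_689_756, 100_215_565, 82),
        (3, 142_710_943, 142_862_611, 3),
        (6, 30_411_203, 30_508_550, 5),
        (10, 67_762_612, 70_157_217, 45),
        (16, 30_100_068, 30_670_323, 16),
    ]),
    "Churra": (0.229, [
        (8, 32_122_858, 34_554_414, 49),
    ]),
    "Ojalada": (0.167, [
        (21, 17_001_944, 19_824_196, 44),
    ]),
    "Bergamasca": (0.167, [
        (2, 10_823_174, 12_893_239, 45),
        (9, 36_932_939, 37_952_215, 24),
    ]),
    "Appenninica": (0.208, [
        (4, 44_524_519, 44_524_519, 1),     # single-SNP island
        (16, 26_703_405, 30_695_539, 88),
    ]),
    "Tibetan": (0.243, [
        (8, 26_853_601, 30_314_835, 77),
        (23, 77_105_889, 83_429_082, 103),
        (23, 90_336_146, 94_196_356, 64),
        (23, 98_904_521, 101_871_791, 52),
        (23, 104_351_418, 108_119_862, 57),
        (23, 114_615_110, 120_163_589, 90),
        (23, 121_125_567, 125_963_555, 81),
    ]),
}

_EMPTY_MAP = SnpMap(np.array([], dtype=object), np.array([], dtype=np.int64),
                    np.array([], dtype=np.int64))


def ancestry_region_objects() -> dict[str, list[SignalRegion]]:
    """The per-breed ancestry-excess intervals as SignalRegion lists."""
    out: dict[str, list[SignalRegion]] = {}
    for breed, rows in ANCESTRY_REGIONS.items():
        out[breed] = [
            SignalRegion(chromosome=c, start_bp=s_bp, end_bp=e_bp,
                         start_snp_id=s_id, end_snp_id=e_id, score=maa,
                         n_snps=0)
            for c, (s_id, s_bp, e_id, e_bp, maa) in sorted(rows.items())]
    return out


def outlier_consensus_track() -> ConsensusTrack:
    """The consensus-count rows as a per-SNP track over their own map."""
    chroms = np.array([r[0] for r in OUTLIER_CONSENSUS])
    ids = np.array([r[1] for r in OUTLIER_CONSENSUS], dtype=object)
    pos = np.array([r[2] for r in OUTLIER_CONSENSUS])
    n_sig = np.array([r[3] for r in OUTLIER_CONSENSUS])
    return ConsensusTrack(SnpMap(ids, chroms, pos), n_sig, 9)


def roh_island_tracks() -> list[IslandTrack]:
    """The per-breed island lists as IslandTrack objects (intervals only)."""
    return [IslandTrack(breed, _EMPTY_MAP, np.array([]), thr,
                        [tuple(row) for row in islands])
            for breed, (thr, islands) in ROH_ISLANDS.items()]
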