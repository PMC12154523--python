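"""Bundled reference tables.

``grafting_read_accounting`` is the published per-sample read-accounting
summary of a pumpkin-rootstock / watermelon-scion grafting RNA-seq
experiment (12 libraries: homograft/heterograft x pulp/stem x 3
replicates). For each library it lists, per reference genome, the clean
reads submitted to that alignment stage, the reads mapped, and the printed
mapped rate in percent. The pumpkin (rootstock) stage receives the reads
left unmapped by the watermelon (scion) stage, so its "clean reads" equal
the scion-stage unmapped count.

Sample codes: XG/XJ = homograft pulp/stem, YG/YJ = heterograft pulp/stem.
The table is used to validate the package's mapped-rate arithmetic against
published values.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["grafting_read_accounting"]

_ROWS = [
    # sample, pumpkin clean, pumpkin mapped, printed %, watermelon clean,
    # watermelon mapped, printed %
    ("XG_1", 8_828_672, 32_064, 0.36, 60_528_066, 51_699_394, 85.41),
    ("XG_2", 9_883_596, 37_851, 0.38, 65_356_312, 55_472_716, 84.88),
    ("XG_3", 11_348_068, 53_431, 0.47, 72_865_870, 61_517_802, 84.43),
    ("XJ_1", 5_499_504, 47_294, 0.86, 91_199_184, 85_699_680, 93.97),
    ("XJ_2", 5_855_008, 46_574, 0.80, 84_643_282, 78_788_274, 93.08),
    ("XJ_3", 3_536_176, 32_162, 0.91, 58_043_296, 54_507_120, 93.91),
    ("YG_1", 67_836_182, 244_339, 0.36, 450_405_130, 382_568_948, 84.94),
    ("YG_2", 71_149_316, 270_573, 0.38, 462_696_550, 391_547_234, 84.62),
    ("YG_3", 69_412_674, 276_379, 0.40, 453_891_800, 384_479_126, 84.71),
    ("YJ_1", 16_256_512, 495_277, 3.05, 462_670_224, 446_413_712, 96.49),
    ("YJ_2", 15_682_756, 241_877, 1.54, 418_630_324, 402_947_568, 96.25),
    ("YJ_3", 19_086_908, 315_904, 1.66, 495_488_346, 476_401_438, 96.15),
]


def grafting_read_accounting() -> pd.DataFrame:
    """Published read accounting of the watermelon/pumpkin graft experiment."""
    df = pd.DataFrame(_ROWS, columns=[
        "sample_id",
        "rootstock_clean_reads", "rootstock_mapped_reads", "rootstock_rate_pct",
        "scion_clean_reads", "scion_mapped_reads", "scion_rate_pct",
    ]).set_index("sample_id")
    df["graft_type"] = ["homo"] * 6 + ["hetero"] * 6
    df["tissue"] = (["pulp"] * 3 + ["stem"] * 3) * 2
    return df
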