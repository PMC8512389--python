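"""Reference feature-index subsets for the WISDM smartphone/smartwatch data.

These are the published 0-based feature indices selected by the hybrid
selector from the pre-extracted WISDM feature sets — `sfp` for the
smartphone sensors, `sfw` for the smartwatch sensors — over the
eight-activity subset (clapping, writing, eating soup, climbing stairs,
folding clothes, playing catch, dribbling a basketball, kicking a soccer
ball).  They illustrate that sensors worn on different body parts need
different feature subsets: fewer than half of either subset's features
are shared with the other.
"""

from __future__ import annotations

__all__ = ["SFP_FEATURES", "SFW_FEATURES", "subset_overlap"]

SFP_FEATURES: tuple[int, ...] = (
    0, 2, 3, 5, 6, 7, 9, 12, 14, 15, 20, 21, 22, 23, 25, 33, 35, 36, 37, 39,
    40, 42, 43, 44, 45, 46, 47, 49, 50, 53, 55, 56, 59, 60, 61, 63, 65, 66,
    68, 69, 70, 71, 73, 78, 80, 81, 88, 89, 90, 91, 92, 104, 105, 109, 118,
    119, 122, 125, 127, 128, 129, 133, 135, 136, 138, 139, 141, 145, 148,
    150, 152, 155, 156, 159, 161, 164, 169, 171, 175, 178, 179, 180, 181,
)

SFW_FEATURES: tuple[int, ...] = (
    0, 5, 9, 10, 11, 15, 16, 20, 21, 27, 31, 36, 45, 50, 51, 54, 58, 59, 61,
    64, 70, 76, 80, 81, 82, 85, 86, 90, 91, 96, 98, 99, 105, 108, 110, 111,
    116, 123, 125, 126, 128, 130, 131, 137, 141, 145, 146, 148, 150, 151,
    156, 158, 160, 161, 164, 166, 167, 168, 172, 178, 181,
)


def subset_overlap(a=SFP_FEATURES, b=SFW_FEATURES) -> dict:
    """Set arithmetic between two selected-feature index lists.

    Returns sizes, the sorted intersection, and the two overlap ratios
    |a & b| / |a| and |a & b| / |b|.
    """
    sa, sb = set(a), set(b)
    joint = sorted(sa & sb)
    return {
        "size_a": len(sa),
        "size_b": len(sb),
        "intersection": joint,
        "n_joint": len(joint),
        "overlap_ratio_a": len(joint) / len(sa),
        "overlap_ratio_b": len(joint) / len(sb),
    }
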