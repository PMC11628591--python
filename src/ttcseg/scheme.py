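"""The five-class tissue scheme for TTC-stained heart-slice segmentation.

Class indices are stable across the whole package: masks on disk, network
outputs, area tables and metric reports all use the same ordering.

=====  ===================  =============================================
index  name                 meaning on the cut surface
=====  ===================  =============================================
0      remaining            background, lumina, epicardial projection
1      remote               perfused non-ischemic LV (brick red)
2      non_infarcted_aar    viable area at risk (light red)
3      infarct              TTC-negative necrotic tissue (white)
4      right_ventricle      right-ventricular wall
=====  ===================  =============================================
"""

from __future__ import annotations

N_CLASSES = 5

CLASS_NAMES = (
    "remaining",
    "remote",
    "non_infarcted_aar",
    "infarct",
    "right_ventricle",
)

REMAINING, REMOTE, NON_INFARCTED_AAR, INFARCT, RIGHT_VENTRICLE = range(N_CLASSES)

#: classes that carry left-ventricular mass in the quantification step
LV_CLASSES = (REMOTE, NON_INFARCTED_AAR, INFARCT)

#: display palette for indexed-PNG masks (RGB per class index)
DISPLAY_PALETTE = (
    (0, 0, 0),        # remaining: black
    (148, 48, 42),    # remote: brick red
    (225, 128, 112),  # non-infarcted AAR: light red
    (246, 240, 228),  # infarct: white
    (180, 85, 75),    # right ventricle: muted red-brown
)
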