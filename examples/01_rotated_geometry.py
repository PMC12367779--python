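"""Rotated-box geometry: five-parameter boxes, vertices, IoU, NMS.

Builds two overlapping leaf-like boxes, converts them to their four-vertex
form, and prints their rotated IoU and what greedy NMS keeps.
"""

from rotphenex import RotatedBox, rotated_iou, rotated_nms, to_quad

# a leaf blade 60 px long and 10 px wide, leaning 30 degrees, and a slightly
# shifted copy such as a duplicate detection would produce
a = RotatedBox(cx=100, cy=100, w=10, h=60, theta=30)
b = RotatedBox(cx=104, cy=98, w=11, h=58, theta=27)

print("box a vertices:", [(round(x, 1), round(y, 1)) for x, y in to_quad(a).vertices])
iou = rotated_iou(a, b)
print(f"rotated IoU(a, b) = {iou:.3f}")
# the IoU is well above a typical 0.45 suppression threshold, so NMS keeps
# only the higher-scoring of the two
kept = rotated_nms([(a, 0.9), (b, 0.8)], iou_threshold=0.45)
print(f"NMS keeps detection indices {kept} (the 0.9-scored box only)")
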