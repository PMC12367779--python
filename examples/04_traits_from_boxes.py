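"""Leaf phenotypic traits from rotated detection boxes.

Applies the vertex-pair trait formulas to a detected box: inclination from
arctan(|y2-y3| / |x2-x3|), length and width from consecutive vertex
distances, aspect ratio and area from their product, plus optional
millimeter calibration and a per-plant summary.
"""

from rotphenex import RotatedBox, ScaleCalibration, extract_plant

detections = [
    (RotatedBox(150, 200, w=12, h=85, theta=40), 0.95),
    (RotatedBox(260, 180, w=18, h=140, theta=-62), 0.91),
    (RotatedBox(210, 320, w=9, h=60, theta=12), 0.88),
]

summary, table = extract_plant(detections, scale=ScaleCalibration(0.5),
                               image_name="pot_01")
print(f"leaf count: {summary.leaf_count}")
cols = ["leaf_id", "confidence", "inclination_deg", "length", "width",
        "aspect", "area"]
print(table[cols].round(2).to_string(index=False))
print(f"mean leaf length {summary.mean_length:.1f} mm, "
      f"total leaf area {summary.total_area:.0f} mm^2")
# lengths/areas are in millimeters because a 0.5 mm/px calibration was given;
# inclination is reported in [0, 90] degrees (lean direction is kept in the
# signed_theta_deg column)
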