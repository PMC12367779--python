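"""Annotation dialects and the 7:2:1 dataset split.

Writes one record in both supported on-disk dialects (roLabelImg XML and
DOTA text), reads them back, and shows the deterministic 7:2:1 split
bookkeeping on 1220 items.
"""

import tempfile
from pathlib import Path

from rotphenex import (
    Annotation, ImageRecord, RotatedBox, read_dota, read_rolabelimg,
    split_dataset, write_dota, write_rolabelimg,
)

record = ImageRecord(None, 640, 640, [
    Annotation(RotatedBox(320, 200, w=14, h=90, theta=55), "leaf", 0),
    Annotation(RotatedBox(400, 420, w=22, h=130, theta=-35), "leaf", 0),
])

with tempfile.TemporaryDirectory() as tmp:
    xml, txt = Path(tmp) / "plant.xml", Path(tmp) / "plant.txt"
    write_rolabelimg(record, xml)
    write_dota(record, txt)
    print("DOTA lines (x1 y1 ... x4 y4 label difficult):")
    print(txt.read_text())
    back = read_rolabelimg(xml)
    print("XML round trip first box:", back.annotations[0].box)
    back2 = read_dota(txt, (640, 640))
    print("DOTA round trip first box:", back2.annotations[0].box)

train, test, val = split_dataset(list(range(1220)), (7, 2, 1), seed=42)
print(f"split of 1220 items -> train {len(train)}, test {len(test)}, val {len(val)}")
# 854/244/122: the sizes follow round(n * r_i / sum(r)) with the remainder
# going to the training set
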