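"""Readers and writers for Pascal-VOC XML and YOLO-txt box annotations.

Internally every box is the half-open, 0-based :class:`~jellydet.boxes.DetectionBox`.
VOC files use the format's 1-based inclusive pixel convention; YOLO-txt rows are
``class cx cy w h`` normalized to the image size.  Both converters round-trip
within half a pixel.
"""

from __future__ import annotations

import os
from typing import Sequence

from lxml import etree

from .boxes import CLASS_NAMES, DetectionBox


def write_voc_xml(
    path: str | os.PathLike,
    boxes: Sequence[DetectionBox],
    width: int,
    height: int,
    filename: str = "",
    class_names: Sequence[str] = CLASS_NAMES,
) -> None:
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(width)
    etree.SubElement(size, "height").text = str(height)
    etree.SubElement(size, "depth").text = "3"
    for b in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_names[b.class_id]
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        # half-open 0-based -> VOC 1-based inclusive
        etree.SubElement(bb, "xmin").text = str(int(round(b.x_min)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(b.y_min)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(b.x_max)))
        etree.SubElement(bb, "ymax").text = str(int(round(b.y_max)))
    etree.ElementTree(root).write(str(path), pretty_print=True)


def read_voc_xml(
    path: str | os.PathLike, class_names: Sequence[str] = CLASS_NAMES
) -> tuple[list[DetectionBox], tuple[int, int]]:
    """Returns ``(boxes, (width, height))``."""
    tree = etree.parse(str(path))
    width = int(tree.findtext("size/width"))
    height = int(tree.findtext("size/height"))
    name_to_id = {n: i for i, n in enumerate(class_names)}
    boxes = []
    for obj in tree.iterfind("object"):
        name = obj.findtext("name")
        bb = obj.find("bndbox")
        boxes.append(
            DetectionBox(
                x_min=float(bb.findtext("xmin")) - 1,
                y_min=float(bb.findtext("ymin")) - 1,
                x_max=float(bb.findtext("xmax")),
                y_max=float(bb.findtext("ymax")),
                class_id=name_to_id[name],
            )
        )
    return boxes, (width, height)


def write_yolo_txt(
    path: str | os.PathLike,
    boxes: Sequence[DetectionBox],
    width: int,
    height: int,
    with_confidence: bool = False,
) -> None:
    lines = []
    for b in boxes:
        cx, cy = b.center
        row = (
            f"{b.class_id} {cx / width:.6f} {cy / height:.6f} "
            f"{b.width / width:.6f} {b.height / height:.6f}"
        )
        if with_confidence:
            row += f" {b.confidence:.6f}"
        lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(
    path: str | os.PathLike, width: int, height: int
) -> list[DetectionBox]:
    boxes = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            cls = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) > 5 else None
            boxes.append(
                DetectionBox(
                    x_min=(cx - w / 2) * width,
                    y_min=(cy - h / 2) * height,
                    x_max=(cx + w / 2) * width,
                    y_max=(cy + h / 2) * height,
                    class_id=cls,
                    confidence=conf,
                )
            )
    return boxes
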