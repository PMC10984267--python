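"""Detection and annotation I/O: COCO-style JSON and YOLO text files.

Two interchange formats are supported, both single-class ("panicle"):

* COCO-style JSON — ``images`` / ``annotations`` / ``categories`` arrays with
  ``bbox`` as ``[x, y, width, height]`` in pixels; prediction files carry a
  ``score`` per annotation.
* YOLO text — one file per image, one line per box:
  ``class cx cy w h [score]`` with coordinates normalised to the image size.

Converters are lossless up to float round-trip: values are written with
``repr`` precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .boxes import DetectionSet, Frame, ScoredBox

__all__ = [
    "ParseError",
    "detections_to_coco",
    "detections_from_coco",
    "detections_to_yolo",
    "detections_from_yolo",
    "load_external_detections",
]

CATEGORY = {"id": 1, "name": "panicle"}


class ParseError(ValueError):
    """A detection file record could not be interpreted."""


def detections_to_coco(
    per_image: dict[str, DetectionSet],
    image_sizes: dict[str, tuple[int, int]],
) -> dict:
    """Build a COCO-style dict from detection sets keyed by image id.

    ``image_sizes`` maps image id to (width, height).
    """
    images, annotations = [], []
    ann_id = 1
    for img_idx, (image_id, dets) in enumerate(sorted(per_image.items()), start=1):
        w, h = image_sizes[image_id]
        images.append(
            {"id": img_idx, "file_name": image_id, "width": w, "height": h}
        )
        for box in dets:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": CATEGORY["id"],
                    "bbox": [
                        box.x_min,
                        box.y_min,
                        box.x_max - box.x_min,
                        box.y_max - box.y_min,
                    ],
                    "area": box.area,
                    "score": box.score,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": [CATEGORY]}


def detections_from_coco(doc: dict, frame: Frame = Frame.TILE) -> dict[str, DetectionSet]:
    """Group a COCO-style dict's annotations into per-image detection sets."""
    try:
        id_to_name = {img["id"]: img["file_name"] for img in doc["images"]}
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed COCO images array: {exc}") from exc
    out: dict[str, DetectionSet] = {
        name: DetectionSet(boxes=[], frame=frame) for name in id_to_name.values()
    }
    for ann in doc.get("annotations", []):
        try:
            name = id_to_name[ann["image_id"]]
            x, y, w, h = ann["bbox"]
            score = float(ann.get("score", 1.0))
            box = ScoredBox(float(x), float(y), float(x) + float(w),
                            float(y) + float(h), score)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed COCO annotation {ann!r}: {exc}") from exc
        out[name].boxes.append(box)
    return out


def detections_to_yolo(
    dets: DetectionSet, image_w: int, image_h: int, with_scores: bool = True
) -> str:
    """Serialise one image's boxes as YOLO text (class 0 = panicle)."""
    lines = []
    for b in dets:
        cx = (b.x_min + b.x_max) / 2.0 / image_w
        cy = (b.y_min + b.y_max) / 2.0 / image_h
        w = (b.x_max - b.x_min) / image_w
        h = (b.y_max - b.y_min) / image_h
        fields = ["0", repr(cx), repr(cy), repr(w), repr(h)]
        if with_scores:
            fields.append(repr(b.score))
        lines.append(" ".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def detections_from_yolo(
    text: str, image_w: int, image_h: int, frame: Frame = Frame.TILE
) -> DetectionSet:
    """Parse YOLO text for one image back into a detection set."""
    boxes: list[ScoredBox] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ParseError(f"YOLO line {lineno}: expected 5 or 6 fields: {line!r}")
        try:
            cx, cy, w, h = (float(v) for v in parts[1:5])
            score = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise ParseError(f"YOLO line {lineno}: {exc}") from exc
        boxes.append(
            ScoredBox(
                (cx - w / 2) * image_w,
                (cy - h / 2) * image_h,
                (cx + w / 2) * image_w,
                (cy + h / 2) * image_h,
                score,
            )
        )
    return DetectionSet(boxes=boxes, frame=frame)


def load_external_detections(
    path: str | Path,
    image_sizes: Optional[dict[str, tuple[int, int]]] = None,
) -> dict[str, DetectionSet]:
    """Load per-tile detections from a COCO-JSON file or a YOLO-txt directory.

    A ``.json`` path is read as one COCO-style file. A directory is read as
    YOLO text files (one per tile, stem = tile id), which requires
    ``image_sizes`` to de-normalise the coordinates. Detections are returned
    keyed by tile/image identifier, in the tile frame.
    """
    path = Path(path)
    if path.is_dir():
        if image_sizes is None:
            raise ParseError("YOLO directories need image_sizes to de-normalise")
        out = {}
        for txt in sorted(path.glob("*.txt")):
            tile_id = txt.stem
            if tile_id not in image_sizes:
                raise ParseError(f"no image size given for tile {tile_id!r}")
            w, h = image_sizes[tile_id]
            out[tile_id] = detections_from_yolo(txt.read_text(), w, h)
        return out
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        return detections_from_coco(doc)
    raise ParseError(f"{path}: expected a .json file or a YOLO .txt directory")
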