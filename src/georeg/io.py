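"""File formats: keypoint CSV, descriptor hex, matches/transform JSON, images.

Keypoint CSV columns: x,y,level,scale,response,orientation_rad (0-based pixel
coordinates).  Descriptor files hold one 64-hex-character row per descriptor,
paired 1:1 with the keypoint CSV.
"""

from __future__ import annotations

import csv
import json

import imageio.v3 as iio
import numpy as np

from .describe import BinaryDescriptor
from .types import GrayImage, KeyPoint, SimilarityTransform, as_gray

KEYPOINT_FIELDS = ("x", "y", "level", "scale", "response", "orientation_rad")


def load_image(path) -> GrayImage:
    """Read PNG/TIFF/JPEG, converting color to 8-bit gray."""
    return GrayImage(as_gray(iio.imread(path)))


def save_image(path, image) -> None:
    arr = np.clip(np.round(as_gray(image)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def write_keypoints_csv(path, keypoints: list[KeyPoint]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(KEYPOINT_FIELDS)
        for kp in keypoints:
            w.writerow([kp.x, kp.y, kp.level, kp.scale, kp.response, kp.orientation])


def read_keypoints_csv(path) -> list[KeyPoint]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                KeyPoint(
                    x=float(row["x"]), y=float(row["y"]), level=int(row["level"]),
                    scale=float(row["scale"]), response=float(row["response"]),
                    orientation=float(row["orientation_rad"]),
                )
            )
    return out


def write_descriptors_hex(path, descriptors: np.ndarray) -> None:
    packed = np.atleast_2d(np.asarray(descriptors, dtype=np.uint8))
    with open(path, "w") as fh:
        for row in packed:
            fh.write(BinaryDescriptor(row).to_hex() + "\n")


def read_descriptors_hex(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(BinaryDescriptor.from_hex(line).packed)
    return np.array(rows, dtype=np.uint8).reshape(-1, 32)


def write_transform_json(path, transform: SimilarityTransform) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def read_transform_json(path) -> SimilarityTransform:
    with open(path) as fh:
        d = json.load(fh)
    return SimilarityTransform(alpha=d["alpha_rad"], du=d["du"], dv=d["dv"], s=d.get("s", 1.0))


def write_result_json(path, result) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def write_histogram_dump(csv_path, json_path, hist) -> None:
    """Diagnostics: bin_center,count CSV plus d/window JSON sidecar."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_center", "count"])
        for c, n in zip(hist.bin_centers, hist.counts):
            w.writerow([float(c), int(n)])
    with open(json_path, "w") as fh:
        json.dump(
            {"d": hist.d, "omega": hist.omega, "window": list(hist.window),
             "peak_bin": hist.peak_bin},
            fh, indent=2,
        )
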