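"""File I/O: 16-bit two-channel TIFFs, PNG previews, JSON/YAML round-trips."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .electrophoresis import GelImage

__all__ = [
    "save_gel_tiff",
    "load_gel_tiff",
    "save_preview_png",
    "save_overlay_png",
    "save_json",
    "load_json",
    "save_yaml",
    "load_yaml",
]


def save_gel_tiff(image: GelImage, path) -> None:
    """Write a two-page 16-bit TIFF (page 1 stain, page 2 Cy5).

    Intensities are clipped to the 16-bit range; the run metadata (including
    the well origin) is embedded as a JSON ImageDescription.
    """
    stack = np.stack(
        [
            np.clip(image.stain_channel, 0, 65535).astype(np.uint16),
            np.clip(image.cy5_channel, 0, 65535).astype(np.uint16),
        ]
    )
    desc = json.dumps(
        {"well_origin": list(image.well_origin), "px_per_mm": image.px_per_mm,
         "metadata": _jsonable(image.metadata)}
    )
    tifffile.imwrite(str(path), stack, description=desc)


def load_gel_tiff(path) -> GelImage:
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page (stain, Cy5) TIFF")
    meta: dict = {}
    well = (0.0, 0.0)
    px_per_mm = 10.0
    if desc:
        try:
            d = json.loads(desc)
            well = tuple(d.get("well_origin", well))
            px_per_mm = d.get("px_per_mm", px_per_mm)
            meta = d.get("metadata", {})
        except (json.JSONDecodeError, TypeError):
            pass
    return GelImage(
        stain_channel=stack[0].astype(np.float64),
        cy5_channel=stack[1].astype(np.float64),
        well_origin=well,
        px_per_mm=px_per_mm,
        metadata=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_preview_png(image: GelImage, path) -> None:
    """8-bit RGB preview: stain in green, Cy5 marker in red."""
    import imageio.v3 as iio

    def norm(ch):
        lo, hi = np.percentile(ch, [1, 99.9])
        return np.clip((ch - lo) / max(hi - lo, 1e-9), 0, 1)

    rgb = np.zeros((*image.shape, 3), dtype=np.float64)
    rgb[..., 1] = norm(image.stain_channel)
    rgb[..., 0] = norm(image.cy5_channel)
    iio.imwrite(str(path), (rgb * 255).astype(np.uint8))


def save_overlay_png(image: GelImage, regions, path) -> None:
    """Quantification QC overlay: stain channel with region outlines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "undigested": "purple",
        "dsDNA": "green",
        "behind": "blue",
        "front": "red",
        "ssb_streak": "saddlebrown",
    }
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(image.stain_channel, cmap="gray_r", interpolation="nearest")
    for name, poly in regions.polygons.items():
        xs = [p[0] for p in poly] + [poly[0][0]]
        ys = [p[1] for p in poly] + [poly[0][1]]
        ax.plot(xs, ys, color=colors.get(name, "orange"), lw=1.2, label=name)
    x0, y0, x1, y1 = regions.background_box
    ax.plot([x0, x1, x1, x0, x0], [y0, y0, y1, y1, y0], color="gray", ls="--", lw=1, label="background")
    ax.legend(loc="lower left", fontsize=7)
    ax.set_axis_off()
    fig.savefig(str(path), dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(obj), sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
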