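"""Stack I/O and dataset blinding.

Images live in memory as :class:`TwoChannelStack`: a 5D array indexed
``(t, z, y, x, channel)`` with channel 0 = green (microglia) and channel 1 =
red (Purkinje cells), plus physical calibration.  On disk stacks are stored
as multi-page TIFF with the calibration embedded in the (deterministic)
shaped-TIFF JSON description, so write -> read round-trips bit-exactly.

Blinding copies files to opaque codes in randomized order; the key is stored
separately as JSON and is only rejoined to results at the statistics stage.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

GREEN = 0
RED = 1

__all__ = [
    "GREEN",
    "RED",
    "TwoChannelStack",
    "BlindingKey",
    "read_stack",
    "write_stack",
    "blind_dataset",
    "unblind",
    "save_masks",
    "load_masks",
]


@dataclass
class TwoChannelStack:
    """A calibrated ``(t, z, y, x, channel)`` two-channel image volume.

    Attributes
    ----------
    data : ndarray
        Nonnegative intensities, axis order TZYXC, 2 channels.
    dt_min : float
        Minutes between consecutive timepoints.
    dz_um : float
        Axial step in micrometers per z slice.
    pixel_size_um : float
        Lateral size of one pixel in micrometers.
    """

    data: np.ndarray
    dt_min: float = 5.0
    dz_um: float = 1.0
    pixel_size_um: float = 0.4

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"stack data must be 5D (t, z, y, x, channel); got {self.data.ndim}D"
            )
        if self.data.shape[-1] != 2:
            raise ValueError(
                "stack must have exactly 2 channels (green=microglia, "
                f"red=Purkinje); got {self.data.shape[-1]}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")
        for name in ("dt_min", "dz_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, c: int) -> np.ndarray:
        """Return the ``(t, z, y, x)`` volume of one channel."""
        return self.data[..., c]

    def copy(self) -> "TwoChannelStack":
        return TwoChannelStack(
            self.data.copy(),
            dt_min=self.dt_min,
            dz_um=self.dz_um,
            pixel_size_um=self.pixel_size_um,
        )


def write_stack(stack: TwoChannelStack, path: str | Path) -> Path:
    """Write a stack as TIFF with calibration in the shaped metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        metadata={
            "axes": "TZYXC",
            "dt_min": float(stack.dt_min),
            "dz_um": float(stack.dz_um),
            "pixel_size_um": float(stack.pixel_size_um),
        },
    )
    return path


def read_stack(
    path: str | Path,
    dt_min: float | None = None,
    dz_um: float | None = None,
    pixel_size_um: float | None = None,
) -> TwoChannelStack:
    """Read a TIFF stack written by :func:`write_stack`.

    Calibration is taken from file metadata; keyword overrides win.  A file
    without calibration metadata and without overrides raises.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta: dict = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
    if data.ndim == 4:
        # tolerate a dropped singleton t or z axis
        data = data[None]
    if data.ndim != 5 or data.shape[-1] != 2:
        raise ValueError(
            f"{path.name}: expected a 2-channel TZYXC stack, got shape {data.shape}; "
            "green (microglia) and red (Purkinje) channels are both required"
        )
    cal = {}
    for key, override in (
        ("dt_min", dt_min),
        ("dz_um", dz_um),
        ("pixel_size_um", pixel_size_um),
    ):
        if override is not None:
            cal[key] = float(override)
        elif key in meta:
            cal[key] = float(meta[key])
        else:
            raise ValueError(
                f"{path.name}: calibration field '{key}' missing from metadata; "
                "pass an explicit override"
            )
    return TwoChannelStack(data, **cal)


# ---------------------------------------------------------------------------
# blinding


@dataclass
class BlindingKey:
    """Bijective mapping from opaque codes to original file paths."""

    mapping: dict[str, str]
    seed: int
    created: str = ""
    _inverse: dict[str, str] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._inverse = {v: k for k, v in self.mapping.items()}
        if len(self._inverse) != len(self.mapping):
            raise ValueError("blinding mapping is not bijective")

    def code_for(self, original: str | Path) -> str:
        return self._inverse[str(original)]

    def original_for(self, code: str) -> str:
        return self.mapping[code]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"mapping": self.mapping, "seed": self.seed, "created": self.created}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BlindingKey":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"blinding key not found: {path}")
        payload = json.loads(path.read_text())
        return cls(
            mapping=payload["mapping"],
            seed=payload["seed"],
            created=payload.get("created", ""),
        )


def blind_dataset(
    paths: list[str | Path],
    seed: int,
    out_dir: str | Path,
    created: str = "",
) -> BlindingKey:
    """Copy files to opaque codes in randomized order; return the key.

    ``created`` is an optional timestamp string recorded in the key; it is
    left empty by default so that blinding output is byte-reproducible for a
    given seed.
    """
    paths = [Path(p) for p in paths]
    if len({str(p) for p in paths}) != len(paths):
        raise ValueError("paths must be distinct")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))
    mapping: dict[str, str] = {}
    for code_i, path_i in enumerate(order):
        src = paths[path_i]
        code = f"blind_{code_i:04d}{src.suffix}"
        mapping[code] = str(src)
        shutil.copyfile(src, out_dir / code)
    return BlindingKey(mapping=mapping, seed=seed, created=created)


def unblind(results, key: BlindingKey, code_column: str = "blinded_id"):
    """Restore original identifiers onto a results table.

    ``results`` is a pandas DataFrame with a column of blinded codes; a new
    column ``original_path`` is added.  Codes absent from the key raise.
    """
    out = results.copy()
    missing = [c for c in out[code_column] if c not in key.mapping]
    if missing:
        raise KeyError(f"codes not in blinding key: {missing}")
    out["original_path"] = [key.original_for(c) for c in out[code_column]]
    return out


# ---------------------------------------------------------------------------
# deterministic compressed mask archives

_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


def save_masks(masks: dict[str, np.ndarray], path: str | Path) -> Path:
    """Save named boolean masks as a compressed, byte-deterministic NPZ.

    ``numpy.savez_compressed`` stamps the archive with the current time; here
    zip entries carry a fixed epoch so identical inputs give identical bytes.
    The result is still readable with ``numpy.load``.
    """
    import io
    import zipfile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(masks):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(masks[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())
    return path


def load_masks(path: str | Path) -> dict[str, np.ndarray]:
    """Load a mask archive written by :func:`save_masks`."""
    with np.load(path) as npz:
        return {name: npz[name] for name in npz.files}
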