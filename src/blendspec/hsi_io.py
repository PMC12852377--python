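"""ENVI-style hypercube I/O, reflectance calibration, ROI extraction and
spectra-table round-tripping.

The instrument side of the pipeline: push-broom imagers write an ENVI
key=value header next to a flat binary raster; dark-current and white-board
reference frames turn raw counts into reflectance R = (I_raw - I_dark) /
(I_ref - I_dark); a region-of-interest mean turns each calibrated cube into
one spectrum per scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import FUSED, SpectraBlock

# ENVI numeric data-type codes -> numpy dtypes (little-endian assumed for
# byte order 0, the only order we emit or accept).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """Raw or calibrated hyperspectral raster (lines x pixels x bands).

    ``dark`` and ``white`` are reference frames with the same band count;
    they may be single frames (pixels x bands) broadcast across lines —
    push-broom practice, one reference pair per session.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    dark: np.ndarray | None = None
    white: np.ndarray | None = None
    interleave: str = "bil"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be lines x pixels x bands")
        bands = self.data.shape[2]
        if self.wavelengths.shape != (bands,):
            raise ValueError(
                f"{self.wavelengths.size} wavelengths for {bands} bands"
            )
        if bands > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("dark", "white"):
            ref = getattr(self, name)
            if ref is None:
                continue
            ref = np.asarray(ref)
            if ref.ndim not in (2, 3) or ref.shape[-1] != bands:
                raise ValueError(f"{name} frame band count must match data")
            setattr(self, name, ref)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _parse_envi_header(text: str) -> dict:
    """Parse the ENVI key = value dialect, including {...} lists."""
    # Collapse multi-line { ... } groups first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _locate_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    candidates = [stem] + [stem.with_suffix(ext) for ext in (".img", ".dat", ".raw")]
    for cand in candidates:
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(
        f"no binary raster found next to header {header_path}"
    )


def read_envi_cube(header_path: str | Path) -> Hypercube:
    """Read an ENVI header + flat binary raster into a Hypercube.

    The stored interleave (BIL/BIP/BSQ) is undone: the returned ``data``
    is always lines x pixels x bands.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"missing ENVI header {header_path}")
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:  # pragma: no cover - message is the point
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header lists no wavelengths")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    binary = _locate_binary(header_path)
    flat = np.fromfile(binary, dtype=_ENVI_DTYPES[dtype_code])
    if flat.size != samples * lines * bands:
        raise ValueError(
            f"raster holds {flat.size} values, header implies {samples * lines * bands}"
        )
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return Hypercube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        interleave=interleave,
    )


def write_envi_cube(cube: Hypercube, header_path: str | Path) -> Path:
    """Fixture writer: store a cube as ENVI header + raw raster.

    The cube's ``interleave`` attribute selects the stored layout.
    """
    header_path = Path(header_path)
    lines, samples, bands = cube.shape
    interleave = cube.interleave.lower()
    if interleave == "bip":
        arr = cube.data
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    elif interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    binary = header_path.with_suffix(".img")
    np.ascontiguousarray(arr).tofile(binary)
    wl = ", ".join(format(w, "g") for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return binary


def _broadcast_reference(ref: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Reduce a 3-D reference to one frame and broadcast over lines."""
    ref = np.asarray(ref, dtype=float)
    if ref.ndim == 3:
        ref = ref.mean(axis=0)
    if ref.shape != shape[1:]:
        raise ValueError(
            f"reference frame shape {ref.shape} incompatible with cube {shape}"
        )
    return ref[None, :, :]


def calibrate_reflectance(raw: Hypercube) -> Hypercube:
    """Black/white reflectance calibration R = (I_raw - I_dark)/(I_ref - I_dark).

    Computed per pixel per band; no clipping — reflectance may exceed 1 or
    go negative, preserving the linearity later stages (MSC, PLSR) assume.
    """
    if raw.dark is None or raw.white is None:
        raise ValueError("calibration requires both dark and white reference frames")
    dark = _broadcast_reference(raw.dark, raw.shape)
    white = _broadcast_reference(raw.white, raw.shape)
    denom = white - dark
    bad = np.nonzero(denom == 0)
    if bad[0].size:
        band = int(bad[2][0])
        raise ValueError(
            f"white == dark at band index {band} "
            f"({raw.wavelengths[band]:g} nm): reference saturation"
        )
    refl = (raw.data.astype(float) - dark) / denom
    return replace(raw, data=refl)


def extract_roi_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the cube over a boolean pixel mask."""
    mask = np.asarray(mask, dtype=bool)
    lines, pixels, _ = cube.shape
    if mask.shape != (lines, pixels):
        raise ValueError(
            f"mask shape {mask.shape} != spatial shape {(lines, pixels)}"
        )
    if not mask.any():
        raise ValueError("empty ROI mask")
    return cube.data[mask].mean(axis=0)


def roi_mask_from_threshold(cube: Hypercube, threshold: float = 0.15) -> np.ndarray:
    """Default sample segmentation against a dark background.

    Pixels whose band-averaged reflectance exceeds ``threshold`` are taken
    to be sample material rather than the black cardboard substrate.
    """
    return cube.data.mean(axis=2) > threshold


def trim_wavelengths(
    block: SpectraBlock, lo_nm: float, hi_nm: float
) -> SpectraBlock:
    """Retain columns with lo <= λ <= hi (closed interval); rows unchanged."""
    if lo_nm >= hi_nm:
        raise ValueError(f"lo_nm {lo_nm} must be < hi_nm {hi_nm}")
    keep = (block.wavelengths >= lo_nm) & (block.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(
            f"no wavelengths inside [{lo_nm}, {hi_nm}] nm "
            f"(grid spans {block.wavelengths[0]:g}-{block.wavelengths[-1]:g} nm)"
        )
    return block.select_columns(keep)


# ---------------------------------------------------------------------------
# spectra tables
# ---------------------------------------------------------------------------

def write_spectra_table(block: SpectraBlock, path: str | Path) -> None:
    """Serialise a block as delimited text: sample_id, then one column per
    wavelength (headers ``tag:λ`` for fused blocks to keep provenance)."""
    frame = pd.DataFrame(
        block.values, index=block.sample_ids, columns=block.column_labels()
    )
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_spectra_table(
    path: str | Path, range_tag: str | None = None
) -> SpectraBlock:
    """Read a spectra table written by :func:`write_spectra_table`.

    Plain tables have numeric wavelength headers; fused tables carry
    ``tag:λ`` headers, from which the block map is rebuilt.
    """
    frame = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in frame.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids {dupes}")
    headers = [str(c) for c in frame.columns]
    fused = any(":" in h for h in headers)
    if fused:
        tags, wavelengths = [], []
        for h in headers:
            tag, _, lam = h.partition(":")
            tags.append(tag)
            wavelengths.append(_parse_wavelength(h, lam))
        return SpectraBlock(
            values=frame.to_numpy(dtype=float),
            wavelengths=np.array(wavelengths),
            sample_ids=ids,
            range_tag=FUSED,
            block_map=np.array(tags, dtype=object),
        )
    wavelengths = np.array([_parse_wavelength(h, h) for h in headers])
    bad = np.flatnonzero(np.diff(wavelengths) <= 0)
    if bad.size:
        j = int(bad[0])
        raise ValueError(
            f"wavelength headers out of increasing order at columns "
            f"{headers[j]!r} -> {headers[j + 1]!r}"
        )
    return SpectraBlock(
        values=frame.to_numpy(dtype=float),
        wavelengths=wavelengths,
        sample_ids=ids,
        range_tag=range_tag or "VisNIR",
    )


def _parse_wavelength(header: str, token: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric wavelength header {header!r}") from None
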