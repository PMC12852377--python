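"""Sample-by-wavelength spectra containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Recognised instrument-range tags.
VISNIR = "VisNIR"
NIR = "NIR"
FUSED = "Fused"


@dataclass
class SpectraBlock:
    """A reflectance matrix (samples x wavelengths) with its wavelength grid.

    Parameters
    ----------
    values
        2-D float array, one row per sample, one column per wavelength.
        Reflectance is dimensionless, typically in [0, ~1.2]; negative or
        above-unity values are legal and propagate unclipped.
    wavelengths
        Per-column band centre in nm.  Strictly increasing within each
        source block (a fused block may restart at its block boundaries).
    sample_ids
        Unique per-row identifiers.
    range_tag
        ``"VisNIR"``, ``"NIR"`` or ``"Fused"``.
    block_map
        For fused blocks only: the source tag of every column.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]
    range_tag: str = VISNIR
    block_map: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample x wavelength matrix")
        n, p = self.values.shape
        if self.wavelengths.shape != (p,):
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != column count {p}"
            )
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.range_tag == FUSED:
            if self.block_map is None:
                raise ValueError("fused block requires a block_map")
            self.block_map = np.asarray(self.block_map, dtype=object)
            if self.block_map.shape != (p,):
                raise ValueError("block_map length must equal column count")
            for tag in self.source_tags():
                lam = self.wavelengths[self.block_map == tag]
                if np.any(np.diff(lam) <= 0):
                    raise ValueError(
                        f"wavelengths not strictly increasing within block {tag!r}"
                    )
        else:
            if self.block_map is not None:
                raise ValueError("block_map is only meaningful for fused blocks")
            if p > 1 and np.any(np.diff(self.wavelengths) <= 0):
                raise ValueError("wavelengths must be strictly increasing")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def source_tags(self) -> list[str]:
        """Distinct source tags in column order (one tag for plain blocks)."""
        if self.block_map is None:
            return [self.range_tag]
        seen: list[str] = []
        for tag in self.block_map:
            if tag not in seen:
                seen.append(str(tag))
        return seen

    # -- derived blocks ---------------------------------------------------
    def with_values(self, values: np.ndarray) -> "SpectraBlock":
        """Same metadata, new (same-shape) matrix."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the block shape")
        return replace(self, values=values)

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "SpectraBlock":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[index],
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def select_columns(self, index: Sequence[int] | np.ndarray) -> "SpectraBlock":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[:, index],
            wavelengths=self.wavelengths[index],
            block_map=None if self.block_map is None else self.block_map[index],
        )

    def column_labels(self) -> list[str]:
        """Serialisable column headers: ``λ`` or ``tag:λ`` for fused blocks."""
        if self.block_map is None:
            return [format(w, "g") for w in self.wavelengths]
        return [
            f"{tag}:{format(w, 'g')}"
            for tag, w in zip(self.block_map, self.wavelengths)
        ]
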