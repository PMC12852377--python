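"""Feature-level fusion: concatenate instrument-range blocks into one
predictor matrix, keeping per-column provenance.

Overlapping wavelength regions from different instruments (e.g. the
975-1020 nm overlap of a Vis-NIR and an NIR imager) are both kept as
distinct variables; the wavelength-selection stage decides which carry
information.  Columns of a fused block are addressed by a unified variable
index plus a (source tag, wavelength) label, since raw nm values are
ambiguous across instruments.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .blocks import FUSED, SpectraBlock


def fuse_blocks(blocks: Sequence[SpectraBlock]) -> SpectraBlock:
    """Concatenate blocks column-wise, in the given order.

    All blocks must share identical sample ids in identical order — no
    silent reordering.
    """
    if not blocks:
        raise ValueError("need at least one block to fuse")
    ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids:
            raise ValueError(
                "sample ids differ or are ordered differently across blocks"
            )
    tags = []
    for b in blocks:
        if b.block_map is not None:
            tags.append(np.asarray(b.block_map, dtype=object))
        else:
            tags.append(np.full(b.n_wavelengths, b.range_tag, dtype=object))
    return SpectraBlock(
        values=np.concatenate([b.values for b in blocks], axis=1),
        wavelengths=np.concatenate([b.wavelengths for b in blocks]),
        sample_ids=list(ids),
        range_tag=FUSED,
        block_map=np.concatenate(tags),
    )


def split_fused(block: SpectraBlock, tag: str) -> SpectraBlock:
    """Extract the sub-block of a fused block belonging to one source tag."""
    if block.range_tag != FUSED or block.block_map is None:
        raise ValueError("split_fused requires a fused block")
    keep = block.block_map == tag
    if not keep.any():
        raise ValueError(
            f"tag {tag!r} not present in fused block "
            f"(available: {block.source_tags()})"
        )
    return SpectraBlock(
        values=block.values[:, keep],
        wavelengths=block.wavelengths[keep],
        sample_ids=list(block.sample_ids),
        range_tag=tag,
    )


def variable_labels(block: SpectraBlock) -> list[tuple[int, str, float]]:
    """(variable index, source tag, wavelength nm) for every column."""
    tags = (
        block.block_map
        if block.block_map is not None
        else np.full(block.n_wavelengths, block.range_tag, dtype=object)
    )
    return [
        (j, str(tags[j]), float(block.wavelengths[j]))
        for j in range(block.n_wavelengths)
    ]
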