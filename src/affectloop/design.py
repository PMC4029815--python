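"""Block-design protocol for the two-emotion neurofeedback task.

A run alternates sustained neutral blocks with emotional blocks (tenderness
or pride).  The default protocol is 8 neutral blocks of 15 volumes
interleaved with 4 tenderness and 4 pride blocks of 22 volumes each at
TR = 2 s, for 296 volumes per run.  The first two volumes of every block
are excluded from decoding (hemodynamic stabilization), and neutral
volumes are never decoded -- they only serve as the running baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd


class Condition(str, enum.Enum):
    TENDERNESS = "tenderness"
    PRIDE = "pride"
    NEUTRAL = "neutral"


EMOTIONAL = (Condition.TENDERNESS, Condition.PRIDE)

#: Volumes at the start of every block excluded from training/decoding.
EDGE_EXCLUSION = 2


class DesignError(ValueError):
    """Raised for structurally invalid block designs."""


@dataclass(frozen=True)
class Block:
    condition: Condition
    n_volumes: int

    def __post_init__(self) -> None:
        if self.n_volumes <= 0:
            raise DesignError(f"block must have >0 volumes, got {self.n_volumes}")
        if self.condition in EMOTIONAL and self.n_volumes <= EDGE_EXCLUSION:
            raise DesignError(
                "emotional blocks need more than "
                f"{EDGE_EXCLUSION} volumes to leave usable ones"
            )


@dataclass(frozen=True)
class VolumeLabel:
    volume_index: int
    condition: Condition
    block_index: int
    usable_for_decoding: bool


@dataclass(frozen=True)
class BlockDesign:
    """Ordered blocks of one run plus acquisition timing."""

    blocks: tuple[Block, ...]
    run_id: int = 0
    tr_seconds: float = 2.0
    start_condition: Condition = Condition.TENDERNESS

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DesignError("design has no blocks")
        if self.blocks[0].condition is not Condition.NEUTRAL:
            raise DesignError("a run must begin with a neutral block")
        prev = None
        for blk in self.blocks:
            if blk.condition in EMOTIONAL and (
                prev is None or prev.condition is not Condition.NEUTRAL
            ):
                raise DesignError(
                    "every emotional block must be preceded by a neutral block"
                )
            prev = blk

    @property
    def n_volumes(self) -> int:
        return sum(b.n_volumes for b in self.blocks)

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_index": range(len(self.blocks)),
                "condition": [b.condition.value for b in self.blocks],
                "n_volumes": [b.n_volumes for b in self.blocks],
            }
        )


def make_default_design(
    start_condition: Condition | str = Condition.TENDERNESS,
    run_id: int = 0,
    *,
    n_emotional_pairs: int = 4,
    emotional_volumes: int = 22,
    neutral_volumes: int = 15,
    tr_seconds: float = 2.0,
) -> BlockDesign:
    """Build the default interleaved protocol.

    Strict alternation neutral -> emoA -> neutral -> emoB -> ..., with the
    first emotional block given by ``start_condition`` (counterbalanced
    across groups by the caller).  Defaults give 296 volumes per run.
    """
    start_condition = Condition(start_condition)
    if start_condition not in EMOTIONAL:
        raise DesignError("start_condition must be tenderness or pride")
    other = (
        Condition.PRIDE
        if start_condition is Condition.TENDERNESS
        else Condition.TENDERNESS
    )
    blocks: list[Block] = []
    for i in range(n_emotional_pairs):
        for emo in (start_condition, other):
            blocks.append(Block(Condition.NEUTRAL, neutral_volumes))
            blocks.append(Block(emo, emotional_volumes))
    return BlockDesign(
        blocks=tuple(blocks),
        run_id=run_id,
        tr_seconds=tr_seconds,
        start_condition=start_condition,
    )


def label_volumes(design: BlockDesign) -> list[VolumeLabel]:
    """Expand a design into one label per volume.

    A volume is usable for decoding iff it lies in an emotional block and
    is past that block's first ``EDGE_EXCLUSION`` volumes.
    """
    labels: list[VolumeLabel] = []
    vol = 0
    for b_idx, blk in enumerate(design.blocks):
        for within in range(blk.n_volumes):
            usable = blk.condition in EMOTIONAL and within >= EDGE_EXCLUSION
            labels.append(VolumeLabel(vol, blk.condition, b_idx, usable))
            vol += 1
    return labels


def labels_to_frame(labels: Iterable[VolumeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "volume_index": [l.volume_index for l in labels],
            "condition": [l.condition.value for l in labels],
            "block_index": [l.block_index for l in labels],
            "usable": [int(l.usable_for_decoding) for l in labels],
        }
    )


def usable_indices(labels: Iterable[VolumeLabel], condition: Condition | None = None) -> list[int]:
    """Volume indices usable for decoding, optionally for one condition."""
    return [
        l.volume_index
        for l in labels
        if l.usable_for_decoding and (condition is None or l.condition is condition)
    ]


def write_design_tsv(design: BlockDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design_tsv(
    path: str | Path,
    run_id: int = 0,
    tr_seconds: float = 2.0,
) -> BlockDesign:
    df = pd.read_csv(path, sep="\t")
    blocks = tuple(
        Block(Condition(row.condition), int(row.n_volumes))
        for row in df.itertuples()
    )
    start = next(b.condition for b in blocks if b.condition in EMOTIONAL)
    return BlockDesign(blocks, run_id=run_id, tr_seconds=tr_seconds, start_condition=start)


def write_labels_tsv(design: BlockDesign, path: str | Path) -> None:
    labels_to_frame(label_volumes(design)).to_csv(path, sep="\t", index=False)
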