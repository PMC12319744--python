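"""Containers for multi-block, multi-participant time-series studies.

A study is an ordered collection of blocks.  Each block is one continuous
recording (a resting-state segment or one music excerpt) for one
participant: a ``timepoints x channels`` float matrix plus labels.  All
downstream stages (dimensionality reduction, HMM fitting, state metrics,
latent-variable analyses) consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

#: recognised task conditions, in canonical order
CONDITIONS = ("rest", "control", "experiment")


@dataclass
class Block:
    """One continuous recording for one participant."""

    data: np.ndarray  # timepoints x channels
    participant: str
    task_id: str
    condition: str
    rate: float  # Hz
    excerpt_id: str | None = None  # shared across participants for stimuli

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"block data must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"block {self.block_id} contains non-finite values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def block_id(self) -> str:
        return f"{self.participant}/{self.task_id}"

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class StudyDataset:
    """Ordered participant x task collection of blocks.

    The block order is part of the dataset identity: fitting routines treat
    blocks as independent sequences that share one model, and results are
    reported back in the same order.
    """

    blocks: list[Block] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def __getitem__(self, i: int) -> Block:
        return self.blocks[i]

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            seen.setdefault(b.participant, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        present = {b.condition for b in self.blocks}
        return [c for c in CONDITIONS if c in present]

    def select(
        self,
        participant: str | None = None,
        condition: str | None = None,
        excerpt_id: str | None = None,
    ) -> "StudyDataset":
        out = [
            b
            for b in self.blocks
            if (participant is None or b.participant == participant)
            and (condition is None or b.condition == condition)
            and (excerpt_id is None or b.excerpt_id == excerpt_id)
        ]
        return StudyDataset(out)

    def matrices(self) -> list[np.ndarray]:
        return [b.data for b in self.blocks]

    def manifest(self) -> pd.DataFrame:
        """Index of blocks: one row per block, in dataset order."""
        return pd.DataFrame(
            {
                "participant": [b.participant for b in self.blocks],
                "task": [b.task_id for b in self.blocks],
                "condition": [b.condition for b in self.blocks],
                "excerpt_id": [b.excerpt_id or "" for b in self.blocks],
                "rate_hz": [b.rate for b in self.blocks],
                "n_timepoints": [b.n_timepoints for b in self.blocks],
            }
        )

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path: str | Path) -> None:
        """Write all blocks to one HDF5 container.

        Layout: ``/participants/<id>/blocks/<task_id>`` datasets with
        ``condition``, ``rate`` and ``excerpt_id`` attributes, plus a
        ``/block_order`` dataset preserving dataset order.
        """
        with h5py.File(path, "w") as f:
            order = f.create_dataset(
                "block_order",
                data=np.array([b.block_id for b in self.blocks], dtype="S"),
            )
            order.attrs["n_blocks"] = len(self.blocks)
            for b in self.blocks:
                grp = f.require_group(f"participants/{b.participant}/blocks")
                ds = grp.create_dataset(b.task_id, data=b.data)
                ds.attrs["condition"] = b.condition
                ds.attrs["rate"] = b.rate
                ds.attrs["excerpt_id"] = b.excerpt_id or ""

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "StudyDataset":
        blocks = []
        with h5py.File(path, "r") as f:
            order = [s.decode() for s in f["block_order"][()]]
            for block_id in order:
                participant, task_id = block_id.split("/", 1)
                ds = f[f"participants/{participant}/blocks/{task_id}"]
                blocks.append(
                    Block(
                        data=ds[()],
                        participant=participant,
                        task_id=task_id,
                        condition=ds.attrs["condition"],
                        rate=float(ds.attrs["rate"]),
                        excerpt_id=(ds.attrs["excerpt_id"] or None),
                    )
                )
        return cls(blocks)

    def to_csv_dir(self, directory: str | Path) -> Path:
        """Write one CSV per block plus a ``manifest.csv`` index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for b in self.blocks:
            fname = f"{b.participant}_{b.task_id}.csv"
            np.savetxt(directory / fname, b.data, delimiter=",")
            paths.append(fname)
        manifest = self.manifest()
        manifest["path"] = paths
        manifest_path = directory / "manifest.csv"
        manifest.to_csv(manifest_path, index=False)
        return manifest_path


def concatenate_studies(studies: Sequence[StudyDataset]) -> StudyDataset:
    blocks: list[Block] = []
    for s in studies:
        blocks.extend(s.blocks)
    return StudyDataset(blocks)
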