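"""Core in-memory containers for backbone structures and design outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ALPHABET


@dataclass
class BackboneStructure:
    """A single-chain protein backbone.

    Coordinates are stored as (L, 3) float arrays in Angstroms for the four
    backbone atoms N, C-alpha, C and O. ``mask`` is True where all four atoms
    are present; positions with any missing atom are masked out of every
    downstream computation (graphs, features, loss, metrics).
    """

    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray
    mask: np.ndarray
    native_seq: str | None = None
    chain_id: str = "A"
    name: str = "structure"
    residue_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for attr in ("coords_N", "coords_CA", "coords_C", "coords_O"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{attr} must have shape (L, 3)")
            setattr(self, attr, arr)
        self.mask = np.asarray(self.mask, dtype=bool)
        L = self.length
        if L < 1:
            raise ValueError("backbone must contain at least one residue")
        shapes = {getattr(self, a).shape[0]
                  for a in ("coords_N", "coords_CA", "coords_C", "coords_O")}
        if shapes != {L} or self.mask.shape != (L,):
            raise ValueError("coordinate arrays and mask disagree on length")
        if self.native_seq is not None and len(self.native_seq) != L:
            raise ValueError("native sequence length must equal L")
        if not self.residue_ids:
            self.residue_ids = [str(i + 1) for i in range(L)]
        for arr in (self.coords_N, self.coords_CA, self.coords_C, self.coords_O):
            if not np.isfinite(arr[self.mask]).all():
                raise ValueError("masked-in residues must have finite coordinates")

    @property
    def length(self) -> int:
        return self.coords_CA.shape[0]

    def atoms(self) -> dict[str, np.ndarray]:
        return {
            "N": self.coords_N,
            "CA": self.coords_CA,
            "C": self.coords_C,
            "O": self.coords_O,
        }

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    ) -> "BackboneStructure":
        """Return a copy under the rigid motion ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return BackboneStructure(
            coords_N=self.coords_N @ R.T + t,
            coords_CA=self.coords_CA @ R.T + t,
            coords_C=self.coords_C @ R.T + t,
            coords_O=self.coords_O @ R.T + t,
            mask=self.mask.copy(),
            native_seq=self.native_seq,
            chain_id=self.chain_id,
            name=self.name,
            residue_ids=list(self.residue_ids),
        )


@dataclass
class DesignRecord:
    """Per-residue design distribution plus sampled sequences for one backbone."""

    structure_id: str
    probabilities: np.ndarray  # (L, 20), rows sum to 1
    sequences: list[str]
    temperature: float
    seed: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != len(ALPHABET):
            raise ValueError("probabilities must have shape (L, 20)")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each per-residue distribution must sum to 1")
        L = self.probabilities.shape[0]
        for seq in self.sequences:
            if len(seq) != L:
                raise ValueError("sampled sequence length must equal L")
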