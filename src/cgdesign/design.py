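"""Turning per-residue logits into designed sequences."""

from __future__ import annotations

import numpy as np

from .constants import ALPHABET
from .structures import DesignRecord


def softmax_probabilities(logits: np.ndarray, T: float = 1.0) -> np.ndarray:
    """Row-wise softmax of logits / T; masked (non-finite) rows become
    uniform placeholders so the distribution invariant holds."""
    logits = np.asarray(logits, dtype=float)
    out = np.full_like(logits, 1.0 / logits.shape[1])
    finite = np.isfinite(logits).all(axis=1)
    z = logits[finite] / T
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    out[finite] = ez / ez.sum(axis=1, keepdims=True)
    return out


def sample_sequences(logits: np.ndarray, mode: str = "argmax",
                     T: float = 1.0, n: int = 1, seed: int = 0,
                     structure_id: str = "design") -> DesignRecord:
    """Sample designed sequences from per-residue logits.

    ``argmax`` emits the single modal sequence (ties broken toward the
    lowest index in the fixed alphabet ACDEFGHIKLMNPQRSTVWY, which is what
    ``np.argmax`` does); ``temperature`` draws ``n`` independent sequences
    from softmax(logits / T). Masked positions (non-finite logit rows)
    emit 'X'.
    """
    if mode not in ("argmax", "temperature"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    if n < 1:
        raise ValueError("sample count must be >= 1")
    logits = np.asarray(logits, dtype=float)
    masked = ~np.isfinite(logits).all(axis=1)
    probs = softmax_probabilities(logits, T=1.0)

    sequences: list[str] = []
    if mode == "argmax":
        choice = np.argmax(np.where(masked[:, None], -np.inf, logits), axis=1)
        seq = "".join("X" if masked[i] else ALPHABET[choice[i]]
                      for i in range(len(choice)))
        sequences = [seq]
    else:
        rng = np.random.default_rng(seed)
        p = softmax_probabilities(logits, T=T)
        for _ in range(n):
            draws = [int(rng.choice(len(ALPHABET), p=p[i]))
                     for i in range(p.shape[0])]
            sequences.append("".join(
                "X" if masked[i] else ALPHABET[draws[i]]
                for i in range(p.shape[0])))
    return DesignRecord(
        structure_id=structure_id, probabilities=probs,
        sequences=sequences, temperature=(0.0 if mode == "argmax" else T),
        seed=seed,
    )
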