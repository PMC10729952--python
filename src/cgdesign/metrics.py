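"""Sequence- and structure-quality measures for design evaluation.

Sequence measures compare designed sequences/distributions to natives:
perplexity (exponentiated pooled cross-entropy), recovery (identity %),
amino-acid composition deviation, a BLOSUM62-referenced log-odds confusion
matrix, probability-weighted BLOSUM scores, low-complexity fraction, and
hydrophobicity-class conservation. Structure measures compare coordinate
sets: Kabsch-superposed C-alpha RMSD and GDT-TS. Solvent accessibility
(Shrake-Rupley, probe 1.4 A) splits residues into core (RSA < 0.2) and
surface for per-class recovery.

Dataset summaries use medians across structures, with pooled variants
reported alongside where both are informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (ALPHABET, AA_INDEX, BLOSUM62, HYDROPHOBIC, MAX_ASA)
from .seg import lcr_fraction
from .structures import BackboneStructure, DesignRecord

_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------- sequence --
def perplexity(probabilities: list[np.ndarray], natives: list[str],
               masks: list[np.ndarray] | None = None) -> float:
    """Exponentiated pooled cross-entropy of native residues.

    Pools the negative log probabilities of all unmasked residues of all
    structures before exponentiating (one double sum, not a mean of
    per-structure perplexities). Zero probabilities are floored at 1e-12
    with a warning.
    """
    total_nll = 0.0
    total_count = 0
    for k, (probs, native) in enumerate(zip(probabilities, natives)):
        mask = None if masks is None else np.asarray(masks[k], dtype=bool)
        for i, letter in enumerate(native):
            code = AA_INDEX.get(letter)
            if code is None or (mask is not None and not mask[i]):
                continue
            p = float(probs[i, code])
            if p <= 0.0:
                warnings.warn("zero probability on a native residue; "
                              "flooring at 1e-12")
                p = _PROB_FLOOR
            total_nll -= np.log(p)
            total_count += 1
    if total_count == 0:
        raise ValueError("no native residues to evaluate")
    return float(np.exp(total_nll / total_count))


def recovery(designed: str, native: str,
             mask: np.ndarray | None = None) -> float:
    """Sequence identity of a designed sequence to the native, in percent."""
    if len(designed) != len(native):
        raise ValueError("sequence lengths differ")
    keep = np.array([c in AA_INDEX for c in native])
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("no unmasked residues")
    matches = sum(1 for i in np.flatnonzero(keep) if designed[i] == native[i])
    return 100.0 * matches / int(keep.sum())


def _pooled_frequencies(sequences: list[str]) -> np.ndarray:
    counts = np.zeros(len(ALPHABET))
    for seq in sequences:
        for letter in seq:
            code = AA_INDEX.get(letter)
            if code is not None:
                counts[code] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no standard residues in sequences")
    return counts / total


def composition_deviation(natives: list[str], designs: list[str],
                          ) -> tuple[np.ndarray, float]:
    """Per-type relative deviation |X - X'| / X of pooled amino-acid
    frequencies, plus the median over types present in the natives.

    Types absent from the natives get NaN (flagged, not divided by zero).
    """
    X = _pooled_frequencies(natives)
    Xp = _pooled_frequencies(designs)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(X > 0, np.abs(X - Xp) / X, np.nan)
    return dev, float(np.nanmedian(dev))


def confusion_logodds(natives: list[str], designs: list[str],
                      ) -> tuple[np.ndarray, float]:
    """20x20 substitution log-odds matrix and its Pearson r vs BLOSUM62.

    The joint distribution p(x, y) comes from position-wise (native,
    designed) pairs with a pseudocount of 1 on every cell of the pair-count
    table; marginals are p's own row/column sums; scores are
    log2(p / (q_x q_y)).
    """
    counts = np.zeros((20, 20))
    for native, designed in zip(natives, designs):
        for x, y in zip(native, designed):
            cx, cy = AA_INDEX.get(x), AA_INDEX.get(y)
            if cx is not None and cy is not None:
                counts[cx, cy] += 1
    if counts.sum() == 0:
        raise ValueError("no native/designed residue pairs")
    counts += 1.0  # pseudocount
    p = counts / counts.sum()
    qx = p.sum(axis=1, keepdims=True)
    qy = p.sum(axis=0, keepdims=True)
    s = np.log2(p / (qx * qy))
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(s.ravel(), BLOSUM62.ravel())[0, 1])
    return s, r


def blosum_scores(probabilities: np.ndarray, native: str,
                  mask: np.ndarray | None = None) -> tuple[float, float]:
    """Probability-weighted BLOSUM62 score of one design, absolute and
    relative.

    Per residue the score is sum_y P(y) * B(native, y); the relative score
    divides by the same quantity with one-hot native predictions (the
    native diagonal), so native predictions score exactly 1.
    """
    keep = np.array([c in AA_INDEX for c in native])
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no unmasked residues")
    codes = np.array([AA_INDEX[native[i]] for i in idx])
    rows = BLOSUM62[codes]  # (n, 20)
    absolute = float((probabilities[idx] * rows).sum(axis=1).mean())
    native_score = float(rows[np.arange(idx.size), codes].mean())
    return absolute, absolute / native_score


def hydrophobic_conservation(native: str, designed: str,
                             mask: np.ndarray | None = None,
                             ) -> dict[str, float]:
    """Conservation of hydrophobicity class between native and design.

    Returns the joint percentage over both classes (headline number) plus
    the per-class breakdown at natively hydrophobic / hydrophilic positions.
    """
    if len(native) != len(designed):
        raise ValueError("sequence lengths differ")
    keep = np.array([c in AA_INDEX for c in native])
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    stats = {"joint": [0, 0], "hydrophobic": [0, 0], "hydrophilic": [0, 0]}
    for i in np.flatnonzero(keep):
        native_hp = native[i] in HYDROPHOBIC
        same = native_hp == (designed[i] in HYDROPHOBIC)
        cls = "hydrophobic" if native_hp else "hydrophilic"
        for key in ("joint", cls):
            stats[key][0] += int(same)
            stats[key][1] += 1
    return {key: (100.0 * hit / n if n else float("nan"))
            for key, (hit, n) in stats.items()}


# --------------------------------------------------------------- structure --
def _as_biopdb(structure: BackboneStructure):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_chain(structure.chain_id[:1] or "A")
    builder.init_seg("    ")
    seq = structure.native_seq or "X" * structure.length
    from .constants import ONE_TO_THREE
    for i in range(structure.length):
        if not structure.mask[i]:
            continue
        builder.init_residue(ONE_TO_THREE.get(seq[i], "UNK"), " ", i + 1, " ")
        for name, element, xyz in (
                ("N", "N", structure.coords_N[i]),
                ("CA", "C", structure.coords_CA[i]),
                ("C", "C", structure.coords_C[i]),
                ("O", "O", structure.coords_O[i])):
            builder.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0,
                              " ", name, element=element)
    return builder.get_structure()


def rsa_classify(structure: BackboneStructure,
                 threshold: float = 0.2) -> list[str | None]:
    """Classify residues as ``"core"`` (RSA < threshold) or ``"surface"``.

    SASA is computed with the Shrake-Rupley method (probe 1.4 A) on the
    present backbone atoms and normalized by the residue type's maximum
    accessible surface area. Residues of unknown type or masked residues
    get ``None``.
    """
    from Bio.PDB.SASA import ShrakeRupley

    seq = structure.native_seq or "X" * structure.length
    model = _as_biopdb(structure)
    ShrakeRupley().compute(model, level="R")
    sasa_by_id = {res.id[1]: res.sasa for res in model.get_residues()}
    out: list[str | None] = []
    for i in range(structure.length):
        max_asa = MAX_ASA.get(seq[i])
        if not structure.mask[i] or max_asa is None:
            if max_asa is None and structure.mask[i]:
                warnings.warn(f"residue {i} has unknown type; "
                              "excluded from RSA classification")
            out.append(None)
            continue
        rsa = sasa_by_id.get(i + 1, 0.0) / max_asa
        out.append("core" if rsa < threshold else "surface")
    return out


def core_surface_recovery(structure: BackboneStructure, designed: str,
                          ) -> dict[str, float]:
    """Recovery split by burial class (core: RSA < 0.2)."""
    native = structure.native_seq
    if native is None:
        raise ValueError("structure has no native sequence")
    classes = rsa_classify(structure)
    out = {}
    for cls in ("core", "surface"):
        idx = [i for i, c in enumerate(classes) if c == cls]
        if idx:
            hits = sum(1 for i in idx if designed[i] == native[i])
            out[cls] = 100.0 * hits / len(idx)
        else:
            out[cls] = float("nan")
    return out


def kabsch_rotation(P: np.ndarray, Q: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids so that R(P - cP) ~ Q - cQ."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cP, cQ


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """C-alpha RMSD after optimal least-squares superposition (Angstroms)."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    R, cP, cQ = kabsch_rotation(P, Q)
    diff = (P - cP) @ R.T - (Q - cQ)
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def gdt_ts(P: np.ndarray, Q: np.ndarray,
           cutoffs: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
           seed_length: int = 7) -> float:
    """Global distance test (total score) between two C-alpha traces.

    For each cutoff, the score is the largest percentage of residue pairs
    superposable within the cutoff over a family of candidate
    superpositions: the global Kabsch fit plus fits seeded on every
    contiguous 7-mer and iteratively extended to the residues they bring
    within 4 A. This is a documented approximation of the exhaustive LGA
    search. The total score averages the four cutoff percentages.
    """
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError("coordinate sets must have equal shapes")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 residues")

    def distances(subset: np.ndarray) -> np.ndarray:
        R, cP, cQ = kabsch_rotation(P[subset], Q[subset])
        return np.linalg.norm((P - P[subset].mean(axis=0)) @ R.T
                              - (Q - Q[subset].mean(axis=0)), axis=1)

    candidate_dists = [distances(np.arange(n))]
    for start in range(0, n - seed_length + 1):
        subset = np.arange(start, start + seed_length)
        for _ in range(3):  # iterative extension
            d = distances(subset)
            grown = np.flatnonzero(d <= 4.0)
            if len(grown) < 3 or np.array_equal(grown, subset):
                break
            subset = grown
        candidate_dists.append(distances(subset))
    dmat = np.stack(candidate_dists)  # (n_candidates, n)
    score = 0.0
    for cutoff in cutoffs:
        score += 100.0 * (dmat <= cutoff).mean(axis=1).max()
    return score / len(cutoffs)


# --------------------------------------------------------------- aggregate --
@dataclass
class MetricsReport:
    """All per-dataset evaluation statistics for one design run."""

    perplexity: float
    recovery_per_structure: list[float]
    recovery_median: float
    recovery_pooled: float
    composition_rel_dev: np.ndarray
    composition_rel_dev_median: float
    confusion_logodds: np.ndarray
    blosum62_pearson_r: float
    blosum_score_median: float
    relative_blosum_score_median: float
    lcr_percent: float
    native_lcr_percent: float
    hydrophobic_conservation: dict[str, float]
    per_structure: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "perplexity": self.perplexity,
            "median_recovery_pct": self.recovery_median,
            "pooled_recovery_pct": self.recovery_pooled,
            "median_composition_rel_dev": self.composition_rel_dev_median,
            "blosum62_pearson_r": self.blosum62_pearson_r,
            "median_relative_blosum_score": self.relative_blosum_score_median,
            "lcr_pct": self.lcr_percent,
            "native_lcr_pct": self.native_lcr_percent,
            "hydrophobic_conservation_pct":
                self.hydrophobic_conservation["joint"],
        }


def evaluate_designs(structures: list[BackboneStructure],
                     records: list[DesignRecord],
                     compute_rsa: bool = False) -> MetricsReport:
    """Run the full sequence-evaluation battery for native/designed pairs.

    Each record's first sampled sequence is treated as "the" design for
    identity-based measures; the record's distributions feed perplexity and
    BLOSUM scores. ``compute_rsa=True`` adds per-structure core/surface
    recovery (slower; needs SASA).
    """
    if len(structures) != len(records):
        raise ValueError("structures and records must align")
    natives, designs, masks = [], [], []
    for s, r in zip(structures, records):
        if s.native_seq is None:
            raise ValueError(f"structure {s.name} has no native sequence")
        if len(r.sequences[0]) != s.length:
            raise ValueError(
                f"designed sequence length {len(r.sequences[0])} does not "
                f"match structure {s.name} of length {s.length}")
        natives.append(s.native_seq)
        designs.append(r.sequences[0])
        masks.append(s.mask)

    rec = [recovery(d, n, m) for d, n, m in zip(designs, natives, masks)]
    pooled_hits = sum(
        sum(1 for i in np.flatnonzero(m & np.array([c in AA_INDEX for c in n]))
            if d[i] == n[i])
        for d, n, m in zip(designs, natives, masks))
    pooled_total = sum(
        int((m & np.array([c in AA_INDEX for c in n])).sum())
        for n, m in zip(natives, masks))

    dev, dev_median = composition_deviation(natives, designs)
    conf, pearson_r = confusion_logodds(natives, designs)
    blosum_abs, blosum_rel = zip(*[
        blosum_scores(r.probabilities, n, m)
        for r, n, m in zip(records, natives, masks)])
    lcr_designed = [lcr_fraction(d) for d in designs]
    lcr_native = [lcr_fraction(n) for n in natives]
    hydro = hydrophobic_conservation("".join(natives), "".join(designs),
                                     np.concatenate(masks))

    per_structure = []
    for s, r, n, d, rv in zip(structures, records, natives, designs, rec):
        entry = {
            "name": s.name,
            "recovery_pct": rv,
            "lcr_pct": lcr_fraction(d),
            "hydrophobic_conservation_pct":
                hydrophobic_conservation(n, d, s.mask)["joint"],
        }
        if compute_rsa:
            entry.update({f"{k}_recovery_pct": v
                          for k, v in core_surface_recovery(s, d).items()})
        per_structure.append(entry)

    return MetricsReport(
        perplexity=perplexity([r.probabilities for r in records], natives),
        recovery_per_structure=rec,
        recovery_median=float(np.median(rec)),
        recovery_pooled=100.0 * pooled_hits / pooled_total,
        composition_rel_dev=dev,
        composition_rel_dev_median=dev_median,
        confusion_logodds=conf,
        blosum62_pearson_r=pearson_r,
        blosum_score_median=float(np.median(blosum_abs)),
        relative_blosum_score_median=float(np.median(blosum_rel)),
        lcr_percent=float(np.mean(lcr_designed)),
        native_lcr_percent=float(np.mean(lcr_native)),
        hydrophobic_conservation=hydro,
        per_structure=per_structure,
    )
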