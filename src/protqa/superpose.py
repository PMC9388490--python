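"""Rigid-body superposition and the Global Distance Test score family.

GDT at cutoff j is the maximal fraction of corresponding residues that a
rigid superposition can bring within j Angstrom of each other.  GDT_TS
averages the fractions at cutoffs {1, 2, 4, 8} and GDT_HA ("high
accuracy") at {0.5, 1, 2, 4}; both lie in [0, 1].

By default the fraction's denominator is the *full target sequence
length*, so a model covering only part of the target can never score
higher than its coverage; ``denominator="common"`` restores the
common-residue denominator instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._gdt import _gdt_counts, _rmsd_after
from .structures import ModelStructure

GDT_TS_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
ALL_THRESHOLDS = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class Correspondence:
    """Residue positions carrying CA atoms in both structures."""

    positions: np.ndarray  # strictly increasing 1-based sequence positions
    n_common: int
    denominator_length: int

    def __post_init__(self) -> None:
        if self.n_common > self.denominator_length:
            raise ValueError("n_common exceeds denominator_length")


@dataclass
class GdtResult:
    """Per-threshold GDT fractions plus whole-common-set RMSD."""

    fractions: dict  # threshold (float, Angstrom) -> fraction in [0, 1]
    rmsd_common: float
    n_common: int
    denominator_length: int

    def mean_over(self, thresholds) -> float:
        return float(np.mean([self.fractions[float(j)] for j in thresholds]))


def kabsch_superpose(coords_a, coords_b):
    """Optimal rigid transform of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` where ``rotation`` is a
    proper 3x3 matrix (det +1) and ``rotation @ b + translation``
    least-squares-fits ``coords_a``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate arrays must share shape (n, 3); got {A.shape} and {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("coordinates must be finite")
    ac, bc = A.mean(axis=0), B.mean(axis=0)
    rot, rssd = Rotation.align_vectors(A - ac, B - bc)
    R = rot.as_matrix()
    t = ac - R @ bc
    rmsd = float(rssd) / np.sqrt(A.shape[0])
    return R, t, rmsd


def common_ca(d: ModelStructure, s: ModelStructure):
    """CA coordinates of the residues present (with CA) in both models."""
    pos_d, xyz_d = d.ca_trace()
    pos_s, xyz_s = s.ca_trace()
    common, ia, ib = np.intersect1d(pos_d, pos_s, return_indices=True)
    return common, xyz_d[ia], xyz_s[ib]


def correspondence(d: ModelStructure, s: ModelStructure, denominator_length: int) -> Correspondence:
    common, _, _ = common_ca(d, s)
    return Correspondence(common, len(common), denominator_length)


def gdt(
    d: ModelStructure,
    s: ModelStructure,
    thresholds=ALL_THRESHOLDS,
    denominator_length: int | None = None,
    denominator: str = "target",
) -> GdtResult:
    """GDT fractions of ``s`` against ``d`` at the given cutoffs.

    ``denominator="target"`` (default) divides counts by
    ``denominator_length`` (the target sequence length); ``"common"``
    divides by the number of common residues.
    """
    common, P, Q = common_ca(d, s)
    n = len(common)
    if n < 3:
        raise ValueError(
            f"models {d.model_id!r} and {s.model_id!r} share only {n} CA "
            "residues; need at least 3"
        )
    if denominator == "common":
        denom = n
    elif denominator == "target":
        if denominator_length is None:
            raise ValueError("denominator_length required for target denominator")
        denom = int(denominator_length)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n > denom:
        raise ValueError("common residue count exceeds the denominator length")

    thr = np.sort(np.asarray(thresholds, dtype=float))
    counts = _gdt_counts(np.ascontiguousarray(P), np.ascontiguousarray(Q), thr)
    # a superposition achieving count c at cutoff j achieves >= c at any
    # larger cutoff, so enforce monotonicity by a running maximum
    counts = np.maximum.accumulate(counts)
    fractions = {float(j): c / denom for j, c in zip(thr, counts)}
    rmsd = float(_rmsd_after(np.ascontiguousarray(P), np.ascontiguousarray(Q)))
    return GdtResult(fractions, rmsd, n, denom)


def gdt_ts(d, s, denominator_length=None, denominator="target") -> float:
    """GDT_TS: mean fraction at cutoffs 1, 2, 4, 8 Angstrom."""
    res = gdt(d, s, GDT_TS_THRESHOLDS, denominator_length, denominator)
    return res.mean_over(GDT_TS_THRESHOLDS)


def gdt_ha(d, s, denominator_length=None, denominator="target") -> float:
    """GDT_HA: mean fraction at cutoffs 0.5, 1, 2, 4 Angstrom."""
    res = gdt(d, s, GDT_HA_THRESHOLDS, denominator_length, denominator)
    return res.mean_over(GDT_HA_THRESHOLDS)
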