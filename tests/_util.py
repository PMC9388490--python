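"""Independent oracles and small builders shared across tests.

Everything here is deliberately naive — closed forms, double loops and
exhaustive enumeration — so it stays independent of the library code
paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from protqa.structures import ModelStructure, Residue


def ca_model(coords, model_id="m", target_id="T", start=1, sequence=None, cb=False):
    """Build a CA-only (optionally +CB) model from an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    residues = []
    for k, xyz in enumerate(coords):
        pos = start + k
        aa = sequence[pos - 1] if sequence else "A"
        atoms = [("CA", "C", xyz)]
        if cb and aa != "G":
            atoms.append(("CB", "C", xyz + np.array([0.0, 0.0, 1.53])))
        residues.append(Residue(pos, aa, atoms, xyz))
    return ModelStructure(model_id=model_id, target_id=target_id, residues=residues)


def random_chain(n, rng, spacing=3.8):
    """Random-walk CA trace with fixed consecutive spacing (no excluded volume)."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(steps * spacing, axis=0)])


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def apply_rigid(model: ModelStructure, R, t) -> ModelStructure:
    """Copy of a model with every atom rigidly transformed."""
    residues = []
    for r in model.residues:
        atoms = [(n, e, R @ xyz + t) for n, e, xyz in r.atoms]
        ca = R @ r.ca_xyz + t if r.ca_xyz is not None else None
        residues.append(Residue(r.seq_position, r.aa_type, atoms, ca))
    return ModelStructure(model.model_id, model.target_id, residues)


# ---------------------------------------------------------------------------
# Kabsch oracle: Horn's closed-form quaternion solution (no SVD).


def quaternion_superpose(A, B):
    """Optimal rotation/translation of B onto A via the quaternion method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ac, bc = A.mean(axis=0), B.mean(axis=0)
    P = A - ac
    Q = B - bc
    M = Q.T @ P  # correlation matrix
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = ac - R @ bc
    rmsd = float(np.sqrt(np.mean(np.sum((A - (B @ R.T + t)) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Exhaustive GDT oracle: superpose on every residue subset of size >= 3,
# count residues within the cutoff, take the maximum.


def gdt_oracle_fractions(P, Q, thresholds, denominator):
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    thresholds = sorted(float(j) for j in thresholds)
    best = {j: 0 for j in thresholds}
    for k in range(3, n + 1):
        for sub in combinations(range(n), k):
            idx = list(sub)
            R, t, _ = quaternion_superpose(P[idx], Q[idx])
            d = np.linalg.norm(P - (Q @ R.T + t), axis=1)
            for j in thresholds:
                cnt = int((d < j).sum())
                if cnt > best[j]:
                    best[j] = cnt
    # monotone by construction of the maximum, but enforce for safety
    run = 0
    out = {}
    for j in thresholds:
        run = max(run, best[j])
        out[j] = run / denominator
    return out


def naive_contact_count(res_idx, xyz, threshold):
    """O(n^2) cross-residue carbon contact pairs within a cutoff."""
    n = len(res_idx)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if res_idx[i] == res_idx[j]:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) <= threshold:
                count += 1
    return count
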