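"""Synthetic decoy sets with the statistical structure of CASP model pools.

Real EMA benchmarks contain, per target, tens to hundreds of server
models of graded accuracy: a cluster of good, mutually similar models
near the native structure, a tail of poor and partly modeled ones.  The
generator reproduces exactly that structure at desk scale so every
pipeline stage — parsing, superposition, consensus, training, LOTO
evaluation — can be exercised end-to-end without external data:

* a reference ("native") structure is a self-avoiding CA trace with
  realistic consecutive-CA spacing (3.8 +/- 0.1 A) and excluded volume,
  decorated with CB side-chain carbons (except glycine);
* decoys perturb the reference coordinates with per-axis Gaussian noise
  of a model-specific sigma and optionally truncate to a contiguous
  window (partial coverage);
* each decoy's label is its GDT_TS against the reference, computed by the
  same superposition kernel the features use.

These are not physically realistic protein models: side chains stop at
CB, noise is isotropic and unconstrained by bond geometry.  They are
sufficient — and intended only — to give graded labels and informative
consensus structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import (
    AA1_TO_3,
    STANDARD_AA,
    ModelStructure,
    Residue,
    TargetSet,
    read_fasta_target,
    read_pdb_model,
    write_fasta_target,
    write_pdb_model,
)
from .superpose import gdt_ts

logger = logging.getLogger(__name__)

CA_DISTANCE = 3.8
CA_JITTER = 0.1
MIN_NONCONSECUTIVE = 3.5
CB_DISTANCE = 1.53


@dataclass(frozen=True)
class DecoyConfig:
    """Study conditions for a generated benchmark.

    Defaults are the package's desk-scale benchmark: 30 targets of 30-60
    residues with 60 models each; 40% of models form a low-noise cluster
    (sigma in the lowest Angstrom of the noise range) and the rest a
    high-noise tail; a quarter of models are contiguously truncated to
    50-95% coverage.
    """

    n_targets: int = 30
    sequence_length: tuple = (30, 60)
    models_per_target: int = 60
    noise_sigma: tuple = (0.25, 8.0)
    fraction_partial: float = 0.25
    cluster_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.models_per_target < 1:
            raise ValueError("counts must be >= 1")
        if self.sequence_length[0] < 10 or self.sequence_length[0] > self.sequence_length[1]:
            raise ValueError("invalid sequence_length range")
        if self.noise_sigma[0] < 0 or self.noise_sigma[0] > self.noise_sigma[1]:
            raise ValueError("invalid noise_sigma range")
        for frac in (self.fraction_partial, self.cluster_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _cb_direction(coords: np.ndarray, i: int) -> np.ndarray:
    """Unit vector for a dummy CB, roughly perpendicular to the backbone."""
    n = len(coords)
    if 0 < i < n - 1:
        b1 = coords[i] - coords[i - 1]
        b2 = coords[i + 1] - coords[i]
        v = np.cross(b1, b2)
    else:
        b1 = coords[min(i + 1, n - 1)] - coords[max(i - 1, 0)]
        v = np.cross(b1, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(v) < 1e-8:
            v = np.cross(b1, np.array([0.0, 1.0, 0.0]))
    norm = np.linalg.norm(v)
    if norm < 1e-8:
        return np.array([1.0, 0.0, 0.0])
    return v / norm


def _trace_to_model(
    coords: np.ndarray,
    sequence: str,
    positions: np.ndarray,
    model_id: str,
    target_id: str,
) -> ModelStructure:
    """Build a ModelStructure with CA atoms plus dummy CB carbons."""
    residues = []
    for k, pos in enumerate(positions):
        aa = sequence[pos - 1]
        ca = coords[k]
        atoms = [("CA", "C", ca)]
        if aa != "G":
            atoms.append(("CB", "C", ca + CB_DISTANCE * _cb_direction(coords, k)))
        residues.append(Residue(int(pos), aa, atoms, ca))
    return ModelStructure(model_id=model_id, target_id=target_id, residues=residues)


def make_reference(length: int, seed, target_id: str = "ref") -> tuple[ModelStructure, str]:
    """Self-avoiding CA trace plus random sequence; returns (model, sequence).

    Consecutive CA distances are 3.8 +/- 0.1 A and no nonconsecutive pair
    comes closer than 3.5 A.  Deterministic per seed.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list(STANDARD_AA), size=length))
    for _attempt in range(50):
        coords = np.zeros((length, 3))
        ok = True
        for i in range(1, length):
            placed = False
            for _retry in range(200):
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                cand = coords[i - 1] + step * rng.uniform(
                    CA_DISTANCE - CA_JITTER, CA_DISTANCE + CA_JITTER
                )
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if dists.min() < MIN_NONCONSECUTIVE:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            positions = np.arange(1, length + 1)
            return _trace_to_model(coords, sequence, positions, "native", target_id), sequence
    raise RuntimeError(f"failed to place a {length}-residue trace after 50 restarts")


def make_decoy(
    reference: ModelStructure,
    sequence: str,
    sigma: float,
    coverage_fraction: float,
    seed,
    model_id: str = "decoy",
) -> tuple[ModelStructure, float]:
    """Perturbed (optionally truncated) copy of the reference, plus its label.

    The label is GDT_TS of the decoy against the reference with the full
    target length as denominator, so truncation caps the label at the
    coverage fraction.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    positions, coords = reference.ca_trace()
    n = len(positions)
    keep_len = max(3, int(round(coverage_fraction * n)))
    if keep_len < n:
        start = int(rng.integers(0, n - keep_len + 1))
        sl = slice(start, start + keep_len)
    else:
        sl = slice(0, n)
    noisy = coords[sl] + rng.normal(scale=sigma, size=(keep_len if keep_len < n else n, 3))
    decoy = _trace_to_model(
        noisy, sequence, positions[sl], model_id, reference.target_id
    )
    label = gdt_ts(decoy, reference, denominator_length=len(sequence))
    return decoy, float(min(1.0, max(0.0, label)))


def make_target_set(
    target_id: str,
    config: DecoyConfig,
    seed_seq: np.random.SeedSequence,
    misleading: bool = False,
) -> tuple[TargetSet, pd.DataFrame]:
    """One synthetic target pool plus its per-model manifest rows.

    ``misleading`` generates an "out-of-context" target: the model pool
    clusters around an *unrelated* reference structure, so consensus (and
    basic) features disagree with the labels — the situation the
    training-set filtering flag exists for.
    """
    child = seed_seq.spawn(3 + config.models_per_target)
    rng = np.random.default_rng(child[0])
    length = int(rng.integers(config.sequence_length[0], config.sequence_length[1] + 1))
    native, sequence = make_reference(length, child[1], target_id=target_id)
    pool_center = native
    if misleading:
        decoy_ref, _ = make_reference(length, child[2], target_id=target_id)
        pool_center = replace(decoy_ref, model_id="pool_center")

    s_lo, s_hi = config.noise_sigma
    cluster_cut = s_lo + min(1.0, s_hi - s_lo)
    n_cluster = int(round(config.cluster_fraction * config.models_per_target))
    models, rows = [], []
    for j in range(config.models_per_target):
        in_cluster = j < n_cluster
        sigma = (
            rng.uniform(s_lo, cluster_cut)
            if in_cluster
            else rng.uniform(cluster_cut, s_hi)
        )
        cov = rng.uniform(0.5, 0.95) if rng.random() < config.fraction_partial else 1.0
        model, _ = make_decoy(
            pool_center, sequence, sigma, cov, child[3 + j], model_id=f"M{j:03d}"
        )
        label = float(min(1.0, max(0.0, gdt_ts(model, native, denominator_length=length))))
        models.append(model)
        rows.append(
            {
                "target_id": target_id,
                "model_id": model.model_id,
                "sigma": sigma,
                "coverage_fraction": cov,
                "label": label,
                "filtered": misleading,
            }
        )
    ts = TargetSet(
        target_id=target_id,
        sequence=sequence,
        models=models,
        native=native,
        filtered_flag=misleading,
    )
    return ts, pd.DataFrame(rows)


def make_dataset(
    config: DecoyConfig, n_misleading: int = 0
) -> tuple[list, pd.DataFrame]:
    """Generate a labeled benchmark: list of TargetSet plus a manifest.

    The last ``n_misleading`` targets are out-of-context targets with
    ``filtered_flag`` set.  Fully deterministic per ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_targets)
    datasets, manifests = [], []
    for t in range(config.n_targets):
        misleading = t >= config.n_targets - n_misleading
        ts, manifest = make_target_set(
            f"T{t + 1:04d}", config, children[t], misleading=misleading
        )
        datasets.append(ts)
        manifests.append(manifest)
    return datasets, pd.concat(manifests, ignore_index=True)


# ---------------------------------------------------------------------------
# On-disk layout (exercises the real I/O path):
#   <root>/manifest.tsv
#   <root>/<target_id>/<target_id>.fasta
#   <root>/<target_id>/native.pdb
#   <root>/<target_id>/models/<model_id>.pdb


def write_dataset(datasets: list, manifest: pd.DataFrame, root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(root / "manifest.tsv", sep="\t", index=False)
    for ts in datasets:
        tdir = root / ts.target_id
        (tdir / "models").mkdir(parents=True, exist_ok=True)
        write_fasta_target(ts.target_id, ts.sequence, tdir / f"{ts.target_id}.fasta")
        if ts.native is not None:
            write_pdb_model(ts.native, ts.sequence, tdir / "native.pdb")
        for m in ts.models:
            write_pdb_model(m, ts.sequence, tdir / "models" / f"{m.model_id}.pdb")


def load_dataset(root) -> list:
    """Re-read a written dataset into TargetSets (native included)."""
    root = Path(root)
    manifest_path = root / "manifest.tsv"
    filtered_ids: set = set()
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, sep="\t")
        if "filtered" in manifest.columns:
            filtered_ids = set(
                manifest.loc[manifest["filtered"].astype(bool), "target_id"]
            )
    datasets = []
    for tdir in sorted(p for p in root.iterdir() if p.is_dir()):
        fastas = list(tdir.glob("*.fasta"))
        if not fastas:
            continue
        target_id, sequence = read_fasta_target(fastas[0])
        native = None
        native_path = tdir / "native.pdb"
        if native_path.exists():
            native = read_pdb_model(
                native_path, sequence, model_id="native", target_id=target_id
            )
        models = []
        for pdb in sorted((tdir / "models").glob("*.pdb")):
            try:
                models.append(
                    read_pdb_model(pdb, sequence, model_id=pdb.stem, target_id=target_id)
                )
            except ValueError as exc:
                logger.warning("skipping unparseable model %s: %s", pdb, exc)
        datasets.append(
            TargetSet(
                target_id=target_id,
                sequence=sequence,
                models=models,
                native=native,
                filtered_flag=target_id in filtered_ids,
            )
        )
    if not datasets:
        raise ValueError(f"no targets found under {root}")
    return datasets
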