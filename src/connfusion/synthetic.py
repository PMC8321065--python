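"""Synthetic two-group BOLD cohorts with known connectivity structure.

The generator emulates the statistical structure the classifier assumes:
each region has a latent Gaussian time series; the latents of the two
diagnostic groups differ in their inter-regional correlations on chosen
*effect pairs*; every voxel's signal is its region's latent plus
independent Gaussian noise.  Ground truth (which pairs and regions carry
the group difference) is persisted so explanation tests can check that
saliency localises where the signal actually is.

Two kinds of effects are supported, controlled by ``modality_split``:

* *coarse* effects change the latent correlation of a pair, so they are
  visible both in the ROI-pair connectivity vector and in the voxel-
  level fingerprint;
* *fine* effects modulate only sub-regional voxel structure: within the
  pair's first region, one half of the voxels adds +c times the partner
  region's latent and the other half adds -c, with the sign of c
  flipped between groups.  The halves cancel in the region mean, so the
  ROI-pair vector carries no trace of the effect, while the voxel-to-ROI
  fingerprint shows a group-dependent spatial pattern — signal that only
  the 3D image branch can exploit.

Group correlation matrices are projected to the nearest valid
correlation matrix (eigenvalue clipping, then re-normalisation to unit
diagonal) so the latent Gaussian is always well defined.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dataio import (CLASS_NAMES, ParcellationAtlas, SubjectRecord, Volume4D,
                     write_atlas, write_manifest, write_volume4d)
from .errors import ValidationError


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one simulated cohort.

    Defaults describe the strong-effect desk-scale cohort: a 16^3 grid
    tiled into 8 regions, 120 frames, 20 subjects per group, baseline
    inter-regional correlation 0.2, and a correlation difference of 0.6
    between groups on four disjoint region pairs, with voxel noise at
    half the latent signal's standard deviation.
    """

    grid: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 8
    T: int = 120
    n_per_group: int = 20
    base_corr: float = 0.2
    effect_pairs: list[tuple[int, int]] | None = None
    effect_delta: float = 0.6
    voxel_noise_sd: float = 0.5
    modality_split: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.base_corr < 1):
            raise ValidationError("base_corr must be in [0, 1)")
        if self.voxel_noise_sd < 0:
            raise ValidationError("voxel_noise_sd must be >= 0")
        if not (0 <= self.modality_split <= 1):
            raise ValidationError("modality_split must be in [0, 1]")
        if self.n_regions > int(np.prod(self.grid)):
            raise ValidationError("more regions than voxels")
        if self.effect_pairs is None:
            # disjoint pairs over consecutive labels: (1,2), (3,4), ...
            self.effect_pairs = [
                (2 * i + 1, 2 * i + 2) for i in range(self.n_regions // 2)
            ]
        self.effect_pairs = [tuple(int(x) for x in p) for p in self.effect_pairs]
        for a, b in self.effect_pairs:
            if not (1 <= a <= self.n_regions and 1 <= b <= self.n_regions) or a == b:
                raise ValidationError(f"invalid effect pair ({a}, {b})")

    def split_pairs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(fine_pairs, coarse_pairs) per modality_split; fine pairs first."""
        n_fine = int(round(self.modality_split * len(self.effect_pairs)))
        return list(self.effect_pairs[:n_fine]), list(self.effect_pairs[n_fine:])

    @property
    def effect_regions(self) -> list[int]:
        return sorted({r for pair in self.effect_pairs for r in pair})


def _balanced_factors(n: int, grid: tuple[int, int, int]) -> tuple[int, int, int]:
    """Factor n into (na, nb, nc) with na<=H, nb<=W, nc<=D, as cubic as possible."""
    best = None
    for na in range(1, n + 1):
        if n % na:
            continue
        for nb in range(1, n // na + 1):
            if (n // na) % nb:
                continue
            nc = n // (na * nb)
            if na <= grid[0] and nb <= grid[1] and nc <= grid[2]:
                spread = max(na, nb, nc) - min(na, nb, nc)
                key = (spread, abs(na - nb) + abs(nb - nc))
                if best is None or key < best[0]:
                    best = (key, (na, nb, nc))
    if best is None:
        raise ValidationError(
            f"cannot tile grid {grid} into {n} contiguous blocks")
    return best[1]


def _axis_edges(length: int, parts: int) -> np.ndarray:
    return np.round(np.linspace(0, length, parts + 1)).astype(int)


def make_atlas(grid: tuple[int, int, int], n_regions: int, seed: int = 0
               ) -> ParcellationAtlas:
    """Tile the grid into contiguous blocky regions labelled 1..n_regions.

    The partition is deterministic; the seed only permutes which block
    gets which label.
    """
    grid = tuple(int(g) for g in grid)
    if n_regions > int(np.prod(grid)):
        raise ValidationError("more regions than voxels")
    na, nb, nc = _balanced_factors(n_regions, grid)
    ea, eb, ec = (_axis_edges(grid[0], na), _axis_edges(grid[1], nb),
                  _axis_edges(grid[2], nc))
    if min(np.diff(ea).min(), np.diff(eb).min(), np.diff(ec).min()) < 1:
        raise ValidationError(
            f"cannot tile grid {grid} into {n_regions} nonempty blocks")
    rng = np.random.default_rng(seed)
    label_order = rng.permutation(n_regions) + 1
    labels = np.zeros(grid, dtype=np.int32)
    for idx, (i, j, k) in enumerate(itertools.product(range(na), range(nb),
                                                      range(nc))):
        labels[ea[i]:ea[i + 1], eb[j]:eb[j + 1], ec[k]:ec[k + 1]] = label_order[idx]
    return ParcellationAtlas(labels=labels)


def nearest_correlation_matrix(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clip to PSD, then re-normalise to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    clipped = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    out = clipped / np.outer(d, d)
    out = (out + out.T) / 2.0  # kill floating-point asymmetry
    np.fill_diagonal(out, 1.0)
    return out


def group_correlation(spec: SyntheticCohortSpec, group: str) -> np.ndarray:
    """Latent correlation matrix for one group (coarse effects only)."""
    if group not in CLASS_NAMES:
        raise ValidationError(f"unknown group {group!r}")
    n = spec.n_regions
    sigma = np.full((n, n), spec.base_corr)
    np.fill_diagonal(sigma, 1.0)
    sign = 1.0 if group == "ASD" else -1.0
    _, coarse = spec.split_pairs()
    for a, b in coarse:
        i, j = a - 1, b - 1
        sigma[i, j] = sigma[j, i] = spec.base_corr + sign * spec.effect_delta / 2.0
    sigma = nearest_correlation_matrix(np.clip(sigma, -0.999, 0.999))
    if np.linalg.eigvalsh(sigma).min() < -1e-8:
        raise ValidationError("group correlation matrix is not PSD")
    return sigma


def _fine_modulation(spec: SyntheticCohortSpec, atlas: ParcellationAtlas,
                     group: str) -> list[tuple[np.ndarray, int, np.ndarray]]:
    """Per fine pair: (voxel indices of region a, partner index, signed coefs).

    Half the voxels (in flat C-order) get +c, half -c; an odd middle
    voxel gets 0 so the region mean is exactly unmodulated.
    """
    sign = 1.0 if group == "ASD" else -1.0
    c = sign * spec.effect_delta / 2.0
    fine, _ = spec.split_pairs()
    flat = atlas.labels.reshape(-1)
    mods = []
    for a, b in fine:
        vox = np.flatnonzero(flat == a)
        coefs = np.zeros(vox.size)
        half = vox.size // 2
        coefs[:half] = c
        coefs[vox.size - half:] = -c
        mods.append((vox, b - 1, coefs))
    return mods


def simulate_subject(spec: SyntheticCohortSpec, atlas: ParcellationAtlas,
                     group: str, rng: np.random.Generator) -> Volume4D:
    """Draw one subject's 4D BOLD volume from the group's latent model."""
    if tuple(atlas.grid) != tuple(spec.grid):
        raise ValidationError("atlas grid does not match spec grid")
    if atlas.n_regions != spec.n_regions:
        raise ValidationError("atlas region count does not match spec")
    sigma = group_correlation(spec, group)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(spec.n_regions))
    latents = chol @ rng.standard_normal((spec.n_regions, spec.T))
    flat_labels = atlas.labels.reshape(-1)
    region_index = {rid: i for i, rid in enumerate(atlas.region_ids)}
    row_of_voxel = np.array([region_index[l] for l in flat_labels])
    signal = latents[row_of_voxel]  # (n_vox, T)
    for vox, partner, coefs in _fine_modulation(spec, atlas, group):
        signal[vox] = signal[vox] + coefs[:, None] * latents[partner][None, :]
    if spec.voxel_noise_sd > 0:
        signal = signal + spec.voxel_noise_sd * rng.standard_normal(signal.shape)
    data = signal.reshape(*spec.grid, spec.T).astype(np.float32)
    return Volume4D(data=data, voxel_dims=(3.0, 3.0, 3.0))


@dataclass
class CohortGroundTruth:
    effect_pairs: list[tuple[int, int]]
    fine_pairs: list[tuple[int, int]]
    coarse_pairs: list[tuple[int, int]]
    effect_regions: list[int]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(effect_pairs=[tuple(p) for p in d["effect_pairs"]],
                   fine_pairs=[tuple(p) for p in d["fine_pairs"]],
                   coarse_pairs=[tuple(p) for p in d["coarse_pairs"]],
                   effect_regions=list(d["effect_regions"]))


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    atlas: ParcellationAtlas
    records: list[SubjectRecord]
    volumes: dict[str, Volume4D]
    ground_truth: CohortGroundTruth


def simulate_cohort(spec: SyntheticCohortSpec,
                    out_dir: str | Path | None = None) -> Cohort:
    """Simulate a balanced two-group cohort; optionally write it to disk
    in the pipeline's standard formats (NIfTI volumes, CSV manifest,
    ground-truth JSON)."""
    atlas = make_atlas(spec.grid, spec.n_regions, seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    volumes: dict[str, Volume4D] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    for group in ("ASD", "control"):
        for i in range(spec.n_per_group):
            sid = f"{group.lower()}_{i:03d}"
            vol = simulate_subject(spec, atlas, group, rng)
            rel = f"volumes/{sid}.nii.gz"
            volumes[sid] = vol
            if out_dir is not None:
                write_volume4d(out_dir / rel, vol)
            records.append(SubjectRecord(subject_id=sid, volume_path=rel,
                                         label=group))
    fine, coarse = spec.split_pairs()
    truth = CohortGroundTruth(effect_pairs=list(spec.effect_pairs),
                              fine_pairs=fine, coarse_pairs=coarse,
                              effect_regions=spec.effect_regions)
    if out_dir is not None:
        write_atlas(out_dir / "atlas.nii.gz", atlas, voxel_dims=(3.0, 3.0, 3.0))
        write_manifest(out_dir / "manifest.csv", records)
        truth.to_json(out_dir / "ground_truth.json")
        (out_dir / "cohort_spec.json").write_text(
            json.dumps(asdict(spec), indent=2, default=list) + "\n")
    return Cohort(spec=spec, atlas=atlas, records=records, volumes=volumes,
                  ground_truth=truth)
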