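"""Synthetic two-modality single-cell data with shared latent clusters.

Cells live in a d-dimensional latent space around cluster centroids placed
on a Delta-scaled simplex.  Each modality observes the latent state through
its own linear loading matrix (the target's loadings are a distorted copy
of the source's), plus an optional constant latent shift for the target,
additive Gaussian noise, a softplus to keep values nonnegative (standing in
for the nonnegativity of counts/activities), and Bernoulli dropout.  Novel
clusters can be restricted to the target, and an exact-pairing mode emits
matched source/target cells for FOSCTTM-style evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import SOURCE, TARGET, FeatureMatrix, LabelSet

__all__ = ["SimScenario", "simulate", "scenario_presets"]


@dataclass
class SimScenario:
    n_src: int = 300
    n_tgt: int = 300
    n_clusters: int = 3
    latent_dim: int = 10
    n_features: int = 100
    separation: float = 10.0       # Delta: centroid scale on the simplex
    modality_shift: float = 0.0    # constant latent offset of the target
    loading_distortion: float = 0.2  # relative perturbation of target loadings
    noise_sd: float = 0.5
    dropout: float = 0.0
    novel_target_clusters: int = 0
    proportions: np.ndarray | None = None  # cluster mix; None -> uniform
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least two clusters")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.novel_target_clusters < self.n_clusters:
            raise ValueError("novel clusters must leave shared clusters")
        if self.latent_dim < self.n_clusters:
            raise ValueError("latent_dim must be >= n_clusters")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate(
    scn: SimScenario,
) -> tuple[FeatureMatrix, LabelSet, FeatureMatrix, LabelSet, np.ndarray | None]:
    """Generate (source, source labels, target, target truth, pairing).

    Pairing is an index array (target cell i matches source cell i) in
    paired mode, else None.  A fixed seed yields bit-identical output.
    """
    rng = np.random.default_rng(scn.seed)
    g, d, m = scn.n_clusters, scn.latent_dim, scn.n_features

    centroids = np.zeros((g, d))
    centroids[:, :g] = scn.separation * np.eye(g)  # simplex vertices

    loadings_src = rng.normal(size=(d, m)) / np.sqrt(d)
    loadings_tgt = loadings_src + scn.loading_distortion * rng.normal(
        size=(d, m)
    ) / np.sqrt(d)
    shift_dir = rng.normal(size=d)
    shift_dir /= np.linalg.norm(shift_dir)

    shared = g - scn.novel_target_clusters  # clusters 0..shared-1 exist in both
    if scn.proportions is None:
        p_src = np.full(shared, 1.0 / shared)
        p_tgt = np.full(g, 1.0 / g)
    else:
        p = np.asarray(scn.proportions, dtype=float)
        if p.shape != (g,) or np.any(p <= 0):
            raise ValueError("proportions must be positive, one per cluster")
        p_tgt = p / p.sum()
        p_src = p[:shared] / p[:shared].sum()

    src_assign = rng.choice(shared, size=scn.n_src, p=p_src)
    if scn.paired:
        if scn.n_src != scn.n_tgt:
            raise ValueError("paired mode needs n_src == n_tgt")
        tgt_assign = src_assign.copy()
    else:
        tgt_assign = rng.choice(g, size=scn.n_tgt, p=p_tgt)

    lat_src = centroids[src_assign] + rng.normal(size=(scn.n_src, d))
    if scn.paired:
        lat_tgt = lat_src.copy()
    else:
        lat_tgt = centroids[tgt_assign] + rng.normal(size=(scn.n_tgt, d))
    lat_tgt = lat_tgt + scn.modality_shift * shift_dir

    x_src = lat_src @ loadings_src + scn.noise_sd * rng.normal(size=(scn.n_src, m))
    x_tgt = lat_tgt @ loadings_tgt + scn.noise_sd * rng.normal(size=(scn.n_tgt, m))
    x_src, x_tgt = _softplus(x_src), _softplus(x_tgt)

    if scn.dropout > 0:
        x_src = x_src * (rng.random(x_src.shape) >= scn.dropout)
        x_tgt = x_tgt * (rng.random(x_tgt.shape) >= scn.dropout)

    feat_ids = [f"gene_{j}" for j in range(m)]
    src_ids = [f"src_{i}" for i in range(scn.n_src)]
    tgt_ids = [f"tgt_{i}" for i in range(scn.n_tgt)]
    src_fm = FeatureMatrix(x_src, src_ids, feat_ids, SOURCE)
    tgt_fm = FeatureMatrix(x_tgt, tgt_ids, feat_ids, TARGET)
    src_lab = LabelSet({c: f"type_{a}" for c, a in zip(src_ids, src_assign)})
    tgt_lab = LabelSet({c: f"type_{a}" for c, a in zip(tgt_ids, tgt_assign)})
    pairing = np.arange(scn.n_src) if scn.paired else None
    return src_fm, src_lab, tgt_fm, tgt_lab, pairing


_PRESETS: dict[str, SimScenario] = {
    # high separation, no distributional gap beyond the loading distortion
    "easy": SimScenario(separation=10.0, modality_shift=0.0, dropout=0.0),
    # heavy sparsity, as in low-coverage accessibility data
    "noisy": SimScenario(separation=10.0, dropout=0.6),
    # strong systematic latent offset between modalities
    "shifted": SimScenario(separation=10.0, modality_shift=3.0),
    # one cluster present only among target cells
    "novel-type": SimScenario(separation=10.0, novel_target_clusters=1),
}


def scenario_presets() -> dict[str, SimScenario]:
    """Named reference scenarios: easy, noisy, shifted, novel-type."""
    return {name: replace(scn) for name, scn in _PRESETS.items()}


def get_preset(name: str, seed: int | None = None) -> SimScenario:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset '{name}'; options: {sorted(presets)}")
    scn = presets[name]
    return replace(scn, seed=seed) if seed is not None else scn
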