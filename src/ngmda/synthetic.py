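"""Synthetic microbe-drug datasets with planted low-rank structure.

The method's working premise is that drugs with similar treatment
functions tend to interact with similar microbes.  The generator encodes
exactly that: every drug and microbe gets a non-negative latent loading
vector with one dominant factor, associations are Bernoulli draws whose
probabilities are proportional to the drug-microbe loading inner
products (rescaled to the requested density), the drug similarity matrix
is the [0, 1]-rescaled cosine similarity of the drug loadings plus
truncated noise, and microbe attributes are the noisy microbe loadings
(so the cosine-similarity map applied to them yields a similarity
correlated with the planted factors).

Setting ``sim_noise`` to infinity produces the null dataset: loadings are
ignored entirely, associations are independent Bernoulli draws and the
similarity matrices are structureless symmetric noise.  Everything is
deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heterograph import AssociationMatrix, SimilarityMatrix, microbe_cosine_similarity

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "DEFAULT_FIXTURE"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 60
    n_microbes: int = 30
    latent_rank: int = 4
    assoc_density: float = 0.08
    sim_noise: float = 0.1
    seed: int = 7

    def __post_init__(self):
        if self.n_drugs < 1 or self.n_microbes < 1:
            raise ValueError("need at least one drug and one microbe")
        if self.latent_rank > min(self.n_drugs, self.n_microbes):
            raise ValueError("latent_rank must be <= min(n_drugs, n_microbes)")
        if not 0.0 < self.assoc_density < 1.0:
            raise ValueError("assoc_density must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_drugs": self.n_drugs, "n_microbes": self.n_microbes,
            "latent_rank": self.latent_rank, "assoc_density": self.assoc_density,
            "sim_noise": self.sim_noise, "seed": self.seed,
        }


DEFAULT_FIXTURE = SyntheticConfig()


@dataclass
class SyntheticDataset:
    assoc: AssociationMatrix
    drug_sim: SimilarityMatrix
    microbe_sim: SimilarityMatrix
    microbe_attributes: np.ndarray
    config: SyntheticConfig
    # planted ground truth kept for diagnostics/tests
    latent: dict = field(default_factory=dict)


_ACTIVITY_SIGMA = 1.5  # log-sd of per-entity activity (hub skew)


def _dominant_loadings(rng: np.random.Generator, n: int, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative loadings: a dominant-factor direction times a heavy-tailed activity.

    The direction (one strong factor plus a small uniform background) makes
    cosine similarities informative about factor membership; the lognormal
    activity magnitude mimics hub drugs/microbes with many associations and
    spreads association probabilities over orders of magnitude, so held-out
    pairs are rankable.
    """
    dominant = rng.integers(rank, size=n)
    direction = 0.2 * rng.random((n, rank))
    direction[np.arange(n), dominant] += 1.0
    activity = rng.lognormal(0.0, _ACTIVITY_SIGMA, size=n)
    return direction, activity, dominant


def _calibrate_probabilities(affinity: np.ndarray, density: float,
                             cap: float = 0.98) -> np.ndarray:
    """Scale affinities so that mean(min(c*A, cap)) equals the target density."""
    if affinity.max() <= 0:
        raise ValueError("degenerate affinity matrix")
    if density >= cap:
        raise ValueError("infeasible association density")
    lo, hi = 0.0, float(density / affinity.mean() * 1e6)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * affinity, cap).mean() < density:
            lo = mid
        else:
            hi = mid
    return np.minimum(lo * affinity, cap)


def _noisy_similarity(base: np.ndarray, noise_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, noise_sd, size=base.shape)
    noise = 0.5 * (noise + noise.T)
    out = np.clip(base + noise, 0.0, 1.0)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Sample one dataset; see the module docstring for the construction."""
    rng = np.random.default_rng(cfg.seed)
    ids_d = [f"drug_{i:03d}" for i in range(cfg.n_drugs)]
    ids_m = [f"microbe_{j:03d}" for j in range(cfg.n_microbes)]

    if not np.isfinite(cfg.sim_noise):
        # null dataset: no planted structure anywhere
        b_values = (rng.random((cfg.n_drugs, cfg.n_microbes)) < cfg.assoc_density).astype(int)
        raw = rng.random((cfg.n_drugs, cfg.n_drugs))
        k_drug = _noisy_similarity(0.5 * (raw + raw.T), 0.0, rng)
        attributes = rng.random((cfg.n_microbes, max(cfg.latent_rank, 2)))
        k_micr = microbe_cosine_similarity(attributes, ids_m)
        return SyntheticDataset(
            assoc=AssociationMatrix(b_values, ids_d, ids_m),
            drug_sim=SimilarityMatrix(k_drug, "drug", ids=ids_d),
            microbe_sim=k_micr,
            microbe_attributes=attributes,
            config=cfg,
            latent={"null": True},
        )

    dir_d, act_d, dom_d = _dominant_loadings(rng, cfg.n_drugs, cfg.latent_rank)
    dir_m, act_m, dom_m = _dominant_loadings(rng, cfg.n_microbes, cfg.latent_rank)
    u = dir_d * act_d[:, None]
    v = dir_m * act_m[:, None]

    # association probabilities proportional to loading inner products,
    # calibrated so the expected density matches the request
    probs = _calibrate_probabilities(u @ v.T, cfg.assoc_density)
    b_values = (rng.random(probs.shape) < probs).astype(int)

    # similarities depend on the direction only (activity cancels in cosine)
    unit = dir_d / np.linalg.norm(dir_d, axis=1, keepdims=True)
    base_drug_sim = 0.5 * (np.clip(unit @ unit.T, -1.0, 1.0) + 1.0)
    k_drug = _noisy_similarity(base_drug_sim, cfg.sim_noise, rng)

    # attributes reflect microbe identity (direction), not association activity
    attributes = dir_m + rng.normal(0.0, cfg.sim_noise, size=dir_m.shape)
    norms = np.linalg.norm(attributes, axis=1)
    attributes[norms == 0] += 1e-6  # keep the cosine map defined
    k_micr = microbe_cosine_similarity(attributes, ids_m)

    return SyntheticDataset(
        assoc=AssociationMatrix(b_values, ids_d, ids_m),
        drug_sim=SimilarityMatrix(k_drug, "drug", ids=ids_d),
        microbe_sim=k_micr,
        microbe_attributes=attributes,
        config=cfg,
        latent={"U": u, "V": v, "dominant_drug": dom_d, "dominant_microbe": dom_m,
                "activity_drug": act_d, "activity_microbe": act_m, "probs": probs},
    )
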