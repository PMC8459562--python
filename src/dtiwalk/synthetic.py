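"""Seeded synthetic interaction datasets with planted block structure.

The generator emulates the statistical regularity the whole pipeline relies
on — similar drugs tend to interact with similar targets — by assigning drugs
and targets to latent blocks: interactions are dense within a block and rare
across blocks, and similarity scores are elevated for same-block pairs.  A
repair pass guarantees every drug and target has at least one interaction, as
the random CV setting requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dtiwalk.data_io import DrugTargetNetwork, SimilarityMatrix

#: smallest similarity kept on a synthetic edge; similarity-edge weights must
#: lie in (0, 1], so exact zeros are excluded
_MIN_SIM = np.nextafter(0.0, 1.0)


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class SyntheticConfig:
    """Parameters of the block-structured generator.

    ``pi_in``/``pi_out`` are the within-/cross-block interaction
    probabilities; ``sim_base``/``sim_bonus`` give cross-block and same-block
    expected similarity, jittered with Gaussian noise of scale
    ``sim_noise_sd`` and clipped into (0, 1].
    """

    m: int = 60
    n: int = 60
    B: int = 4
    pi_in: float = 0.5
    pi_out: float = 0.01
    sim_base: float = 0.2
    sim_bonus: float = 0.6
    sim_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ConfigError("m and n must be >= 1")
        if not (0 <= self.pi_out <= self.pi_in <= 1):
            raise ConfigError("need 0 <= pi_out <= pi_in <= 1")
        if self.B < 1 or self.B > min(self.m, self.n):
            raise ConfigError("need 1 <= B <= min(m, n)")
        if not (0 <= self.sim_base and self.sim_base + self.sim_bonus <= 1):
            raise ConfigError("need sim_base >= 0 and sim_base + sim_bonus <= 1")
        if self.sim_noise_sd < 0:
            raise ConfigError("sim_noise_sd must be >= 0")


@dataclass
class DatasetSummary:
    """Interaction-count statistics of a network."""

    m: int
    n: int
    known: int
    unknown: int
    sparsity_ratio: float

    def format(self) -> str:
        return (
            f"drugs\t{self.m}\n"
            f"targets\t{self.n}\n"
            f"known\t{self.known}\n"
            f"unknown\t{self.unknown}\n"
            f"sparsity_ratio\t{self.sparsity_ratio:.3f}\n"
        )


def _block_similarity(
    blocks: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    same = blocks[:, None] == blocks[None, :]
    S = cfg.sim_base + cfg.sim_bonus * same.astype(float)
    if cfg.sim_noise_sd > 0:
        noise = rng.normal(0.0, cfg.sim_noise_sd, size=S.shape)
        noise = (noise + noise.T) / 2.0  # keep the matrix symmetric
        S = S + noise
    S = np.clip(S, _MIN_SIM, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_block_dataset(
    cfg: SyntheticConfig,
) -> tuple[DrugTargetNetwork, SimilarityMatrix, SimilarityMatrix]:
    """Generate (network, drug similarity, target similarity) from ``cfg``.

    Drugs and targets are assigned to the ``B`` blocks round-robin; the
    interaction label of a (drug, target) pair is Bernoulli(``pi_in``) when
    the two share a block and Bernoulli(``pi_out``) otherwise.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    drug_blocks = np.arange(cfg.m) % cfg.B
    target_blocks = np.arange(cfg.n) % cfg.B
    same = drug_blocks[:, None] == target_blocks[None, :]
    prob = np.where(same, cfg.pi_in, cfg.pi_out)
    Y = (rng.random((cfg.m, cfg.n)) < prob).astype(np.int8)

    # repair pass: every drug row and target column needs at least one 1,
    # planted on a same-block pair so it is consistent with the signal
    for i in np.flatnonzero(Y.sum(axis=1) == 0):
        candidates = np.flatnonzero(same[i])
        j = candidates[rng.integers(len(candidates))] if len(candidates) else int(
            rng.integers(cfg.n)
        )
        Y[i, j] = 1
    for j in np.flatnonzero(Y.sum(axis=0) == 0):
        candidates = np.flatnonzero(same[:, j])
        i = candidates[rng.integers(len(candidates))] if len(candidates) else int(
            rng.integers(cfg.m)
        )
        Y[i, j] = 1

    drug_ids = [f"d{i:04d}" for i in range(cfg.m)]
    target_ids = [f"t{j:04d}" for j in range(cfg.n)]
    dd = SimilarityMatrix(drug_ids, _block_similarity(drug_blocks, cfg, rng))
    tt = SimilarityMatrix(target_ids, _block_similarity(target_blocks, cfg, rng))
    net = DrugTargetNetwork(drug_ids, target_ids, Y)
    return net, dd, tt


def summarize_dataset(net: DrugTargetNetwork) -> DatasetSummary:
    """Count known/unknown pairs and their sparsity ratio (known/unknown).

    Raises
    ------
    ValueError
        If the matrix is complete (no unknown pairs), where the ratio is
        undefined.
    """
    known = net.n_known
    unknown = net.n_drugs * net.n_targets - known
    if unknown == 0:
        raise ValueError(
            "sparsity ratio undefined: interaction matrix is complete"
        )
    ratio = 0.0 if known == 0 else known / unknown
    return DatasetSummary(
        m=net.n_drugs, n=net.n_targets, known=known, unknown=unknown,
        sparsity_ratio=ratio,
    )
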