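"""Synthetic multimodal cohorts with known ground truth.

The generator emulates the statistical structure the two-level pipeline
assumes in real multimodal studies: several feature channels of very
different dimensionality that all express one shared latent trait plus
channel-unique signal components, twin pairs with correlated traits, a
head-size confounder correlated with both features and response, and
demographic mediators. Feature-level matrices only — no images, time series
or diffusion signal.

Generative model (per subject i, channel k):

    y_i = a·g_i + Σ_k √(b_k)·u_ki + confounders + √(1 − a² − Σ b_k)·ε_i
    X_k = √(s_k)·g·p_kᵀ + u_k·q_kᵀ + noise_sd·E_k

with g, u_k, ε independent standard normals, a² = max_k s_k (the shared
trait is one latent; each channel expresses it with amplitude √s_k), and
p_k, q_k sparse loading vectors (10 % nonzero by default). Twin pairs draw
their g from a bivariate normal with the configured correlation. The
variance fractions describe the confounder-free response core; confounder
effects add on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import FeatureChannel, ResponseVector

__all__ = [
    "ConfounderEffects",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "plant_confounders",
    "realistic_confounders",
]


@dataclass(frozen=True)
class ConfounderEffects:
    """Linear confounder slopes (all on centered confounder values)."""

    volume_response: float = 0.0   # response units per litre of ICV
    volume_feature: float = 0.0    # added to every feature column per litre
    age_response: float = 0.0      # per year
    sex_response: float = 0.0      # male-vs-female shift
    education_response: float = 0.0  # per ordinal education level


def realistic_confounders() -> ConfounderEffects:
    """Slopes sized so demographics out-predict single imaging channels.

    Education dominates (its contribution alone explains roughly 15–20 % of
    the response variance on the default cohort), with smaller head-size,
    age and sex effects — the ordering observed when a demographic channel
    is stacked against imaging channels in large young-adult cohorts.
    """
    return ConfounderEffects(
        volume_response=1.0,
        volume_feature=0.1,
        age_response=0.02,
        sex_response=0.2,
        education_response=0.25,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one synthetic study.

    ``shared_loading_fraction[k]`` is the response-variance share carried by
    the shared latent trait as expressed in channel k (the trait itself is a
    single latent; its response share is the maximum over channels);
    ``unique_loading_fraction[k]`` is the share carried by channel k's
    unique component. Shares refer to the confounder-free response core and
    must satisfy max(shared) + Σ unique ≤ 1.
    """

    n_subjects: int = 400
    channel_dims: tuple[int, ...] = (400, 360, 360, 65, 500)
    shared_loading_fraction: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15, 0.15)
    unique_loading_fraction: tuple[float, ...] = (0.05, 0.04, 0.02, 0.01, 0.05)
    noise_sd: float = 1.0
    twin_fraction: float = 0.4
    twin_trait_correlation: float = 0.6
    loading_sparsity: float = 0.1   # fraction of nonzero generative loadings
    confounder_effects: ConfounderEffects = field(default_factory=ConfounderEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if any(d < 1 for d in self.channel_dims):
            raise ValueError("channel_dims must all be >= 1")
        k = len(self.channel_dims)
        if len(self.shared_loading_fraction) != k or len(self.unique_loading_fraction) != k:
            raise ValueError("one shared and one unique fraction per channel required")
        for f in (*self.shared_loading_fraction, *self.unique_loading_fraction,
                  self.twin_fraction, self.twin_trait_correlation, self.loading_sparsity):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        total = max(self.shared_loading_fraction, default=0.0) + sum(self.unique_loading_fraction)
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"variance shares sum to {total:.3f} > 1 (max shared + sum unique)"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_dims)


@dataclass
class SyntheticCohort:
    """A generated study: channels, response, metadata, and the truth."""

    channels: list[FeatureChannel]
    response: ResponseVector
    metadata: pd.DataFrame
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.response)


def _twin_structure(config: SimulationConfig, rng: np.random.Generator):
    """Family labels and the shared latent trait g (twin-correlated)."""
    n = config.n_subjects
    n_pairs = int(round(config.twin_fraction * n / 2))
    family = np.empty(n, dtype=object)
    g = np.empty(n)
    rho = config.twin_trait_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    for p in range(n_pairs):
        pair = rng.multivariate_normal([0.0, 0.0], cov)
        g[2 * p], g[2 * p + 1] = pair
        family[2 * p] = family[2 * p + 1] = f"fam{p:05d}"
    n_single = n - 2 * n_pairs
    g[2 * n_pairs:] = rng.standard_normal(n_single)
    for s in range(n_single):
        family[2 * n_pairs + s] = f"solo{s:05d}"
    return family, g


def _sparse_loadings(p: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    v = np.zeros(p)
    k = max(1, int(round(sparsity * p)))
    idx = rng.choice(p, size=k, replace=False)
    v[idx] = rng.standard_normal(k)
    return v


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, config.n_channels

    family, g = _twin_structure(config, rng)
    u = rng.standard_normal((n, K))
    eps = rng.standard_normal(n)

    a = float(np.sqrt(max(config.shared_loading_fraction, default=0.0)))
    b = np.sqrt(np.asarray(config.unique_loading_fraction))
    resid_var = 1.0 - a**2 - float(np.sum(b**2))
    y_core = a * g + u @ b + np.sqrt(max(resid_var, 0.0)) * eps

    subject_ids = np.array([f"sub{i:05d}" for i in range(n)])
    channels, p_load, q_load = [], [], []
    for k, p_dim in enumerate(config.channel_dims):
        p_k = _sparse_loadings(p_dim, config.loading_sparsity, rng)
        q_k = _sparse_loadings(p_dim, config.loading_sparsity, rng)
        s_k = np.sqrt(config.shared_loading_fraction[k])
        X = (
            s_k * np.outer(g, p_k)
            + np.outer(u[:, k], q_k)
            + config.noise_sd * rng.standard_normal((n, p_dim))
        )
        channels.append(FeatureChannel(
            name=f"channel{k}", values=X, subject_ids=subject_ids,
            feature_labels=[f"channel{k}_f{j}" for j in range(p_dim)],
        ))
        p_load.append(p_k)
        q_load.append(q_k)

    icv = np.maximum(rng.normal(1.5, 0.15, size=n), 0.8)   # litres
    age = rng.integers(22, 38, size=n).astype(float)        # years
    sex = rng.choice(["F", "M"], size=n)
    education = rng.integers(11, 18, size=n).astype(float)  # ordinal years
    metadata = pd.DataFrame({
        "subject_id": subject_ids,
        "family_group": family,
        "intracranial_volume": icv,
        "age": age,
        "sex": sex,
        "education": education,
    })

    cohort = SyntheticCohort(
        channels=channels,
        response=ResponseVector(name="score", values=y_core),
        metadata=metadata,
        truth={
            "g": g, "u": u, "eps": eps,
            "shared_coefficient": a,
            "unique_coefficients": b,
            "residual_sd": float(np.sqrt(max(resid_var, 0.0))),
            "shared_loadings": p_load,
            "unique_loadings": q_load,
            "config": asdict(config),
        },
    )
    return plant_confounders(cohort, config)


def plant_confounders(cohort: SyntheticCohort, config: SimulationConfig) -> SyntheticCohort:
    """Add configured confounder effects to response and features (in place).

    Head size shifts the response by ``slope · (icv − mean(icv))`` and every
    feature column by the feature slope times the same centered volume;
    demographic slopes act on centered age, sex indicator and education.
    With all slopes zero the cohort is returned unchanged (metadata columns
    are always present).
    """
    eff = config.confounder_effects
    meta = cohort.metadata
    y = cohort.response.values
    icv_c = meta["intracranial_volume"].to_numpy() - meta["intracranial_volume"].mean()
    if eff.volume_response:
        y = y + eff.volume_response * icv_c
    if eff.age_response:
        age = meta["age"].to_numpy(dtype=float)
        y = y + eff.age_response * (age - age.mean())
    if eff.sex_response:
        male = (meta["sex"].to_numpy() == "M").astype(float)
        y = y + eff.sex_response * (male - male.mean())
    if eff.education_response:
        edu = meta["education"].to_numpy(dtype=float)
        y = y + eff.education_response * (edu - edu.mean())
    if eff.volume_feature:
        for ch in cohort.channels:
            ch.values = ch.values + eff.volume_feature * icv_c[:, None]
    cohort.response = ResponseVector(cohort.response.name, y)
    return cohort
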