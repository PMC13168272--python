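"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a morphometry study cohort: ~62 subjects, ~600
cortical parcels per measure, spatially correlated parcels (equicorrelated
blocks standing in for neighbourhoods on the cortical sheet), heterogeneous
parcel variances, a gender difference in trait empathy of about 2.2 TEQ
points, and integer TEQ sum scores clipped to the 0-28 range of the 7-item
questionnaire.  Optional linear and quadratic parcel effects plant a
recoverable signal for power/recovery experiments; the defaults carry no
parcel signal, matching a cohort where morphometry does not predict the
trait.

Parcel values are drawn as ``baseline + sd_j * (sqrt(rho) z_block +
sqrt(1-rho) eps)``; effects act on the centered parcel deviations so the
intercept stays on the TEQ scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .tables import MorphometryTable, PhenotypeTable, MEASURES, TEQ_MAX, TEQ_MIN

#: Plausible parcel-mean baselines per measure (mm for thickness/depth,
#: dimensionless for gyrification); cosmetic, the analysis standardizes.
_BASELINES = {"thickness": 2.5, "gyrification": 25.0, "depth": 10.0}
_BASELINE_SPREAD = {"thickness": 0.3, "gyrification": 2.0, "depth": 2.0}

_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")


def _parcel_labels(n_parcels: int) -> list[str]:
    """Schaefer-style labels: hemisphere_network_index."""
    labels = []
    for j in range(n_parcels):
        hemi = "LH" if j < n_parcels // 2 else "RH"
        net = _NETWORKS[j % len(_NETWORKS)]
        labels.append(f"{hemi}_{net}_{j + 1}")
    return labels


@dataclass
class SimulationSpec:
    """Generative description of one synthetic cohort.

    Defaults describe the emulated study conditions: n=62 adults aged 18-85,
    56.45% female, 600 parcels in 60 correlation blocks, a +2.19-point TEQ
    effect of female gender, residual latent SD 2.6 (overall TEQ SD ~2.9
    after the gender mixture), and no parcel effects.
    """

    n_subjects: int = 62
    n_parcels: int = 600
    n_blocks: int = 60
    within_block_correlation: float = 0.4
    parcel_sd_range: tuple[float, float] = (0.08, 0.25)
    measure: str = "thickness"
    informative_parcels: tuple[int, ...] = ()
    linear_effect_size: float | tuple[float, ...] = 0.0
    quadratic_roi: tuple[int, float, float] | None = None  # (parcel, lin, quad)
    gender_effect: float = 2.19
    age_effect: float = 0.0
    noise_sd: float = 2.6
    intercept: float = 21.90
    age_range: tuple[float, float] = (18.0, 85.0)
    female_proportion: float = 0.5645
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if self.n_blocks > self.n_parcels or self.n_blocks < 1:
            raise ValueError("need 1 <= n_blocks <= n_parcels")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.parcel_sd_range[0] <= 0 or self.parcel_sd_range[1] < self.parcel_sd_range[0]:
            raise ValueError("parcel_sd_range must be positive and ordered")
        bad = [j for j in self.informative_parcels if not 0 <= j < self.n_parcels]
        if bad:
            raise ValueError(f"informative parcel indices out of range: {bad}")
        if self.quadratic_roi is not None and not 0 <= self.quadratic_roi[0] < self.n_parcels:
            raise ValueError("quadratic_roi parcel index out of range")
        if not 0.0 <= self.female_proportion <= 1.0:
            raise ValueError("female_proportion must lie in [0, 1]")

    @property
    def linear_effects(self) -> np.ndarray:
        b = np.asarray(self.linear_effect_size, dtype=float)
        if b.ndim == 0:
            b = np.full(len(self.informative_parcels), float(b))
        if b.size != len(self.informative_parcels):
            raise ValueError(
                "linear_effect_size must be scalar or match informative_parcels"
            )
        return b

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_cohort(spec: SimulationSpec) -> tuple[MorphometryTable, PhenotypeTable]:
    """Draw one cohort under ``spec``; identical seed gives identical tables.

    The latent trait is

        intercept + sum_j b_j d_j + (lin*d_r + quad*d_r^2) + gender_effect*female
        + age_effect*(age - mean age) + N(0, noise_sd^2)

    with ``d_j`` the centered parcel deviation; the observed TEQ is the
    latent rounded to the nearest integer and clipped to [0, 28].
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_parcels
    rho = spec.within_block_correlation

    # block-equicorrelated deviations: same block shares a latent factor
    block_of = np.arange(p) % spec.n_blocks
    z_block = rng.normal(size=(n, spec.n_blocks))
    eps = rng.normal(size=(n, p))
    dev = np.sqrt(rho) * z_block[:, block_of] + np.sqrt(1.0 - rho) * eps
    sds = rng.uniform(*spec.parcel_sd_range, size=p)
    dev *= sds

    baselines = _BASELINES[spec.measure] + rng.normal(
        scale=_BASELINE_SPREAD[spec.measure], size=p
    )
    values = baselines + dev

    age = rng.uniform(*spec.age_range, size=n)
    female = (rng.random(n) < spec.female_proportion).astype(float)

    latent = np.full(n, spec.intercept, dtype=float)
    if len(spec.informative_parcels):
        idx = np.asarray(spec.informative_parcels, dtype=int)
        latent += dev[:, idx] @ spec.linear_effects
    if spec.quadratic_roi is not None:
        j, b1, b2 = spec.quadratic_roi
        d = dev[:, int(j)]
        latent += b1 * d + b2 * d * d
    latent += spec.gender_effect * female
    latent += spec.age_effect * (age - age.mean())
    if spec.noise_sd > 0:
        latent += rng.normal(scale=spec.noise_sd, size=n)

    teq = np.clip(np.round(latent), TEQ_MIN, TEQ_MAX).astype(int)

    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    morph = MorphometryTable(spec.measure, ids, _parcel_labels(p), values)
    pheno = PhenotypeTable(
        ids, teq, age, ["female" if f else "male" for f in female]
    )
    return morph, pheno


def inject_outliers(
    phenotypes: PhenotypeTable,
    k: int,
    magnitude: float,
    seed: int | None = None,
) -> tuple[PhenotypeTable, np.ndarray]:
    """Return a copy with k subjects' TEQ shifted by ``magnitude``, plus indices.

    The shift sign is picked per subject so that the clipped result lands as
    far from the cohort median as possible (i.e. away from the median, towards
    the bound with more headroom), making a sufficiently large magnitude
    detectable by MAD screening; results stay in the valid [0, 28] range.
    """
    n = phenotypes.n_subjects
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    teq = phenotypes.teq.astype(float).copy()
    med = float(np.median(teq))
    for i in idx:
        up = np.clip(round(teq[i] + magnitude), TEQ_MIN, TEQ_MAX)
        down = np.clip(round(teq[i] - magnitude), TEQ_MIN, TEQ_MAX)
        teq[i] = up if abs(up - med) > abs(down - med) else down
    out = PhenotypeTable(
        list(phenotypes.subject_ids),
        teq.astype(int),
        phenotypes.age.copy(),
        list(phenotypes.gender),
    )
    return out, idx
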