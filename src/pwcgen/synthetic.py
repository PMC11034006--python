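"""Synthetic multi-site connectome cohorts with controlled sex, age and site effects.

The generator emulates a multi-dataset resting-state study: several
"datasets" (sites) with distinct age ranges, sample sizes and site
effects, sharing one biological effect structure — a localized sex
difference in the connectivity of a chosen set of *signal parcels* plus a
linear age trend.

Generation operates in Fisher-z space, where effects are additive:

    z_subject = site_scale * ( base
                               + (±delta/2) * sex_mask          # F: +, M: -
                               + age_slope * (age - midpoint) * age_mask )
                + site_offset + N(0, noise_sd) per edge (symmetric)

and the per-subject connectome is tanh(z) with unit diagonal, so every
entry is a valid correlation. The symmetric ±delta/2 coding keeps the
pooled mean at ``base`` regardless of the sex ratio. The age effect
defaults to the edges incident to the signal parcels, which deliberately
confounds age with the sex signal whenever sites differ in age range —
the situation the CV-consistent confound regression has to neutralize.

A time-series path is also provided: parcel series drawn from a
multivariate normal whose correlation matches a target connectome, mixed
with nuisance signals (WM/CSF analogs) of known loadings so that
nuisance cleaning can be verified exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import NuisanceSignals, ParcelTimeSeries
from .errors import ConfigurationError

__all__ = [
    "DatasetSpec",
    "EffectSpec",
    "Cohort",
    "StudyData",
    "generate_cohort",
    "generate_parcel_timeseries",
    "make_multisite_study",
    "subseed",
]

DEFAULT_BASE_Z = 0.3


def subseed(master_seed: int, name: str) -> int:
    """Stable 31-bit per-dataset seed derived from the master seed.

    Uses SHA-256 of ``"seed|name"`` so that adding or reordering datasets
    never perturbs another dataset's random draws.
    """
    digest = hashlib.sha256(f"{int(master_seed)}|{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset/site: sample composition plus site-effect parameters.

    ``site_offset`` (additive, Fisher-z units), ``site_scale``
    (multiplicative) and ``noise_sd`` (subject-level edge noise SD,
    Fisher-z units) carry the dataset-level heterogeneity attributable to
    scanner, acquisition and preprocessing differences.
    """

    name: str
    n_subjects: int
    age_range: tuple[float, float]
    female_fraction: float = 0.5
    site_offset: float = 0.0
    site_scale: float = 1.0
    noise_sd: float = 0.5
    unseen: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError(
                f"{self.name}: need n_subjects >= 2, got {self.n_subjects}"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(
                f"{self.name}: empty age range {self.age_range}"
            )
        if self.site_scale <= 0:
            raise ConfigurationError(
                f"{self.name}: site_scale must be > 0, got {self.site_scale}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"{self.name}: noise_sd must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError(
                f"{self.name}: female_fraction must be in [0, 1]"
            )


@dataclass(frozen=True, eq=False)
class EffectSpec:
    """Shared biology across sites: sex effect, age trend, mean structure.

    ``sex_effect_size`` (delta) is the female-minus-male Fisher-z
    difference on edges incident to the signal parcels; it is applied as
    ±delta/2 per sex. ``age_slope`` is Fisher-z change per year of age on
    the designated edge subset (default: the same edges).
    """

    n_parcels: int
    signal_parcels: tuple[int, ...]
    sex_effect_size: float = 0.4
    age_slope: float = 0.004
    base_connectivity: np.ndarray | None = None
    age_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_parcels < 2:
            raise ConfigurationError("n_parcels must be >= 2")
        object.__setattr__(
            self, "signal_parcels", tuple(int(i) for i in self.signal_parcels)
        )
        s = self.signal_parcels
        if len(set(s)) != len(s):
            raise ConfigurationError("signal_parcels contains duplicates")
        if len(s) > self.n_parcels:
            raise ConfigurationError("more signal parcels than parcels")
        if any(not 0 <= i < self.n_parcels for i in s):
            raise ConfigurationError("signal parcel index out of range")
        if not np.isfinite(self.sex_effect_size):
            raise ConfigurationError("sex_effect_size must be finite")
        if not np.isfinite(self.age_slope):
            raise ConfigurationError("age_slope must be finite")
        if self.base_connectivity is not None:
            b = np.asarray(self.base_connectivity, dtype=float)
            if b.shape != (self.n_parcels, self.n_parcels):
                raise ConfigurationError("base_connectivity has wrong shape")
            if not np.allclose(b, b.T, atol=1e-12):
                raise ConfigurationError("base_connectivity must be symmetric")
            object.__setattr__(self, "base_connectivity", b)
        if self.age_edges is not None:
            m = np.asarray(self.age_edges, dtype=bool)
            if m.shape != (self.n_parcels, self.n_parcels):
                raise ConfigurationError("age_edges mask has wrong shape")
            if not (m == m.T).all():
                raise ConfigurationError("age_edges mask must be symmetric")
            object.__setattr__(self, "age_edges", m)

    def base(self) -> np.ndarray:
        """Fisher-z mean matrix (constant off-diagonal by default)."""
        if self.base_connectivity is not None:
            return np.array(self.base_connectivity, dtype=float)
        b = np.full((self.n_parcels, self.n_parcels), DEFAULT_BASE_Z)
        np.fill_diagonal(b, 0.0)
        return b

    def _incident_mask(self) -> np.ndarray:
        p = self.n_parcels
        m = np.zeros((p, p), dtype=bool)
        idx = list(self.signal_parcels)
        m[idx, :] = True
        m[:, idx] = True
        np.fill_diagonal(m, False)
        return m

    def sex_mask(self) -> np.ndarray:
        """Off-diagonal edges incident to a signal parcel."""
        return self._incident_mask()

    def age_mask(self) -> np.ndarray:
        if self.age_edges is not None:
            m = self.age_edges.copy()
            np.fill_diagonal(m, False)
            return m
        return self._incident_mask()


@dataclass
class Cohort:
    """Demographics plus one connectome per subject (n, P, P)."""

    demographics: pd.DataFrame
    connectomes: np.ndarray


@dataclass
class StudyData:
    """Keyed collection of cohorts for a multi-site study."""

    cohorts: dict[str, Cohort]
    unseen: str
    effects: EffectSpec
    specs: tuple[DatasetSpec, ...]
    seed: int

    @property
    def training_eligible(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs if not s.unseen)

    def demographics(self) -> pd.DataFrame:
        return pd.concat(
            [c.demographics for c in self.cohorts.values()], ignore_index=True
        )


def generate_cohort(
    dataset: DatasetSpec, effects: EffectSpec, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate demographics and per-subject connectomes for one dataset.

    Returns
    -------
    demographics : DataFrame with columns subject_id, dataset, sex, age.
    connectomes : array (n_subjects, P, P) of valid correlation matrices.
    """
    p = effects.n_parcels
    n = dataset.n_subjects
    rng = np.random.default_rng(seed)

    lo, hi = dataset.age_range
    ages = rng.uniform(lo, hi, size=n)
    n_f = int(round(dataset.female_fraction * n))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    sign = np.where(sex == "F", 1.0, -1.0)

    base = effects.base()
    sex_m = effects.sex_mask().astype(float)
    age_m = effects.age_mask().astype(float)
    midpoint = (lo + hi) / 2.0

    z = (
        base[None, :, :]
        + (sign * effects.sex_effect_size / 2.0)[:, None, None] * sex_m
        + (effects.age_slope * (ages - midpoint))[:, None, None] * age_m
    )
    z = dataset.site_scale * z + dataset.site_offset

    iu = np.triu_indices(p, 1)
    if dataset.noise_sd > 0:
        noise_flat = rng.normal(0.0, dataset.noise_sd, size=(n, iu[0].size))
        noise = np.zeros((n, p, p))
        noise[:, iu[0], iu[1]] = noise_flat
        noise += noise.transpose(0, 2, 1)
        z = z + noise

    c = np.tanh(z)
    c[:, np.arange(p), np.arange(p)] = 1.0

    width = max(4, len(str(n - 1)))
    demo = pd.DataFrame(
        {
            "subject_id": [f"{dataset.name}-{i:0{width}d}" for i in range(n)],
            "dataset": dataset.name,
            "sex": sex,
            "age": ages,
        }
    )
    return demo, c


def generate_parcel_timeseries(
    connectome_z: np.ndarray,
    n_timepoints: int,
    seed: int,
    nuisance_strength: float = 0.4,
) -> tuple[ParcelTimeSeries, NuisanceSignals]:
    """Draw parcel time series whose correlation approaches a target.

    The target correlation is ``tanh`` of the supplied Fisher-z matrix,
    repaired to the nearest positive-semidefinite matrix by clipping
    negative eigenvalues (strongly indefinite targets are rejected, naming
    the offending eigenvalue). Series are zero-mean multivariate normal;
    two nuisance series are mixed in with known loadings (recorded on the
    returned :class:`NuisanceSignals`) so that cleaning recovers the
    latent series' residual structure exactly.
    """
    if n_timepoints < 3:
        raise ConfigurationError(f"need T >= 3 timepoints, got {n_timepoints}")
    z = np.asarray(connectome_z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ConfigurationError("connectome_z must be square")
    p = z.shape[0]
    r = np.tanh((z + z.T) / 2.0)
    np.fill_diagonal(r, 1.0)

    w, v = np.linalg.eigh(r)
    if w.min() < -1e-2:
        raise ConfigurationError(
            "target correlation matrix is not repairable to PSD: "
            f"eigenvalue {w.min():.6g}"
        )
    w = np.clip(w, 0.0, None)
    # rescale so the repaired matrix keeps a unit diagonal
    r_psd = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(r_psd), 1e-12, None))
    factor = (v * np.sqrt(w)) / d[:, None]

    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_timepoints, p)) @ factor.T
    nuis = rng.standard_normal((n_timepoints, 2))
    loadings = nuisance_strength * rng.uniform(0.5, 1.5, size=(2, p))
    observed = latent + nuis @ loadings
    return (
        ParcelTimeSeries(observed),
        NuisanceSignals(nuis, names=("wm", "csf"), loadings=loadings),
    )


def make_multisite_study(
    specs: list[DatasetSpec] | tuple[DatasetSpec, ...],
    effects: EffectSpec,
    seed: int,
) -> StudyData:
    """Generate all cohorts of a multi-site study.

    Exactly one spec must be flagged ``unseen`` (the external test
    dataset); all cohorts share the same :class:`EffectSpec` — the sex
    effect is the common biology, only site parameters differ. Each
    dataset draws from its own sub-seed derived from the master seed, so
    adding a dataset never perturbs the others.
    """
    specs = tuple(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate dataset names in {names}")
    unseen = [s.name for s in specs if s.unseen]
    if len(unseen) != 1:
        raise ConfigurationError(
            f"exactly one dataset must be flagged unseen, got {unseen}"
        )
    cohorts: dict[str, Cohort] = {}
    for spec in specs:
        demo, conn = generate_cohort(spec, effects, subseed(seed, spec.name))
        cohorts[spec.name] = Cohort(demo, conn)
    return StudyData(
        cohorts=cohorts,
        unseen=unseen[0],
        effects=effects,
        specs=specs,
        seed=int(seed),
    )
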