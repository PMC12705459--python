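"""Synthetic cohort generation.

Everything downstream of preprocessing is exercised on data produced here:
a modular weighted connectome, state-switching regional time series driven
by a Markov chain over planted centroids, and a covariate table with family
history (FH) groups and family-history density (FHD) scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: Canonical network names: seven cortical resting-state networks plus
#: subcortex and cerebellum.
NETWORKS = ("VIS", "SOM", "DAT", "VAT", "LIM", "FPN", "DMN", "SUB", "CER")

# Region counts per network for the default 86-region parcellation
# (68 cortical + 18 subcortical/cerebellar split, roughly proportional to
# the FreeSurfer86/Yeo assignment).
_DEFAULT_SIZES = {
    "VIS": 12, "SOM": 10, "DAT": 8, "VAT": 10, "LIM": 8,
    "FPN": 10, "DMN": 10, "SUB": 14, "CER": 4,
}

#: Priority order in which networks receive planted anticorrelated
#: centroid pairs (first pair lives on DMN, second on VIS, ...).
_PAIR_ORDER = ("DMN", "VIS", "SOM", "DAT", "VAT", "LIM", "FPN", "SUB", "CER")

FH_POS = "FH+"
FH_NEG = "FH-"
FH_MIXED = "FH+/-"

#: Cohort FH-group proportions used as the sampling default (FH+, FH-, FH+/-).
DEFAULT_FH_PROBS = (0.231, 0.623, 0.146)


@dataclass(frozen=True)
class ParcellationScheme:
    """Assignment of contiguous region ids 0..N-1 to named networks."""

    region_names: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.region_names) != len(self.networks):
            raise ValueError("region_names and networks must have equal length")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names must be unique")
        unknown = set(self.networks) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown network names: {sorted(unknown)}")
        if self.n_regions >= len(NETWORKS):
            missing = set(NETWORKS) - set(self.networks)
            if missing:
                raise ValueError(
                    f"parcellation with N={self.n_regions} must populate all "
                    f"{len(NETWORKS)} networks; empty: {sorted(missing)}"
                )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def present_networks(self) -> tuple[str, ...]:
        """Networks with at least one region, in canonical order."""
        present = set(self.networks)
        return tuple(n for n in NETWORKS if n in present)

    def indicator(self, network: str) -> np.ndarray:
        """Binary (0/1 float) membership vector for ``network``."""
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return np.asarray([1.0 if n == network else 0.0 for n in self.networks])

    def regions_of(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.indicator(network) > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions, dtype=int),
                "region_name": list(self.region_names),
                "network": list(self.networks),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParcellationScheme":
        required = {"region_id", "region_name", "network"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        frame = frame.sort_values("region_id")
        ids = frame["region_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("region ids must be contiguous 0..N-1")
        return cls(
            region_names=tuple(frame["region_name"].astype(str)),
            networks=tuple(frame["network"].astype(str)),
        )

    @classmethod
    def default(cls, n_regions: int = 86) -> "ParcellationScheme":
        """Default parcellation with network sizes proportional to the
        86-region layout; uses largest-remainder apportionment so every
        network stays nonempty for n_regions >= 9."""
        if n_regions < len(NETWORKS):
            raise ValueError(f"default parcellation needs n_regions >= {len(NETWORKS)}")
        total = sum(_DEFAULT_SIZES.values())
        quotas = {k: n_regions * v / total for k, v in _DEFAULT_SIZES.items()}
        counts = {k: max(1, int(np.floor(q))) for k, q in quotas.items()}
        remainder = n_regions - sum(counts.values())
        order = sorted(NETWORKS, key=lambda k: quotas[k] - np.floor(quotas[k]), reverse=True)
        i = 0
        while remainder != 0:
            k = order[i % len(order)]
            if remainder > 0:
                counts[k] += 1
                remainder -= 1
            elif counts[k] > 1:
                counts[k] -= 1
                remainder += 1
            i += 1
        names, nets = [], []
        for net in NETWORKS:
            for j in range(counts[net]):
                names.append(f"{net}_{j:02d}")
                nets.append(net)
        return cls(region_names=tuple(names), networks=tuple(nets))


@dataclass(frozen=True)
class Pedigree:
    """Counts of biological parents / grandparents with an SUD history."""

    n_parents_sud: int
    n_grandparents_sud: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_parents_sud <= 2:
            raise ValueError("n_parents_sud must be in 0..2")
        if not 0 <= self.n_grandparents_sud <= 4:
            raise ValueError("n_grandparents_sud must be in 0..4")


def classify_family_history(p: Pedigree) -> str:
    """FH+ with >=1 affected parent or >=2 affected grandparents; FH- with
    none; FH+/- with exactly one affected grandparent and no parents."""
    if p.n_parents_sud >= 1 or p.n_grandparents_sud >= 2:
        return FH_POS
    if p.n_grandparents_sud == 1:
        return FH_MIXED
    return FH_NEG


def compute_fhd(p: Pedigree) -> float:
    """Family-history density: +1 per affected parent, +0.5 per affected
    grandparent; ranges from 0 to 4."""
    return 1.0 * p.n_parents_sud + 0.5 * p.n_grandparents_sud


@dataclass(frozen=True)
class SubjectTimeSeries:
    """Demeaned regional time series, frames x regions."""

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1:
            raise ValueError("data must be a frames x regions matrix with >=1 frame")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted generative model for one cohort draw.

    group_effect maps (sex, fh_group) to {network: scale} applied
    multiplicatively to centroid entries of that network before series
    generation; missing keys mean scale 1 (no effect).
    """

    true_centroids: np.ndarray
    dwell_matrix: np.ndarray
    noise_sd: float
    seed: int
    group_effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.true_centroids, dtype=float)
        d = np.asarray(self.dwell_matrix, dtype=float)
        if c.ndim != 2:
            raise ValueError("true_centroids must be k x N")
        if d.shape != (c.shape[0], c.shape[0]):
            raise ValueError("dwell_matrix must be k x k")
        if np.any(d < 0) or not np.allclose(d.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("dwell_matrix rows must be nonnegative and sum to 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        object.__setattr__(self, "true_centroids", c)
        object.__setattr__(self, "dwell_matrix", d)

    @property
    def k(self) -> int:
        return self.true_centroids.shape[0]


def default_dwell_matrix(k: int, stay: float = 0.7) -> np.ndarray:
    """Row-stochastic matrix with self-transition probability ``stay`` and
    the remainder spread uniformly. A convention, not calibrated to data."""
    if not 0 <= stay <= 1:
        raise ValueError("stay must be in [0, 1]")
    off = (1.0 - stay) / (k - 1) if k > 1 else 0.0
    d = np.full((k, k), off)
    np.fill_diagonal(d, stay if k > 1 else 1.0)
    return d


def generate_connectome(
    n_regions: int,
    n_modules: int,
    density: float,
    weight_scale: float = 1.0,
    seed: int = 0,
    max_retries: int = 20,
) -> np.ndarray:
    """Weighted stochastic-block-model connectome.

    Regions are split into ``n_modules`` contiguous blocks; within-module
    edges are both denser and heavier (log-normal weights) than
    between-module edges. Output is symmetric, nonnegative, zero-diagonal
    and connected; a disconnected draw is retried a bounded number of times.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")

    module = np.concatenate(
        [np.full(len(block), i) for i, block in enumerate(np.array_split(np.arange(n_regions), n_modules))]
    )
    iu, ju = np.triu_indices(n_regions, k=1)
    within = module[iu] == module[ju]

    if n_modules == 1 or not within.any() or within.all():
        p_within = p_between = density
    else:
        f_in = within.mean()
        p_between = density / 2.0
        p_within = min(1.0, (density - (1.0 - f_in) * p_between) / f_in)

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        p_edge = np.where(within, p_within, p_between)
        present = rng.random(iu.size) < p_edge
        w = rng.lognormal(mean=0.0, sigma=0.75, size=iu.size) * weight_scale
        w *= np.where(within, 2.0, 1.0)
        w = np.where(present, w, 0.0)
        sc = np.zeros((n_regions, n_regions))
        sc[iu, ju] = w
        sc += sc.T
        n_comp, _ = connected_components(csr_matrix(sc > 0), directed=False)
        if n_comp == 1:
            return sc
    raise RuntimeError(
        f"could not draw a connected connectome after {max_retries} retries (seed={seed}); "
        "increase density or change the seed"
    )


def generate_state_centroids(
    parcellation: ParcellationScheme,
    k: int,
    amplitude: float,
    seed: int = 0,
    background_frac: float = 0.05,
) -> np.ndarray:
    """Planted k x N state centroids organised as anticorrelated pairs.

    Pair ``i`` sets exactly +/-``amplitude`` on the regions of the ``i``-th
    network in priority order (DMN first, then VIS, ...), with small seeded
    background values elsewhere. If ``k`` is odd the final centroid is an
    unpaired positive pattern on the next network.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    nets = [n for n in _PAIR_ORDER if n in parcellation.present_networks]
    if k > 2 * len(nets):
        raise ValueError(f"k={k} exceeds twice the number of populated networks ({len(nets)})")
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    centroids = np.empty((k, n))
    n_patterns = (k + 1) // 2
    for i in range(n_patterns):
        base = rng.normal(0.0, background_frac * amplitude, size=n)
        mask = parcellation.indicator(nets[i]) > 0
        base[mask] = amplitude
        centroids[2 * i] = base
        if 2 * i + 1 < k:
            centroids[2 * i + 1] = -base
    return centroids


@dataclass(frozen=True)
class SubjectSeriesDraw:
    """One simulated subject: demeaned series, chain labels, and the raw
    (pre-demeaning) frames plus the perturbed centroids actually used."""

    series: SubjectTimeSeries
    labels: np.ndarray
    raw: np.ndarray
    centroids_used: np.ndarray


def _simulate_chain(dwell: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    k = dwell.shape[0]
    labels = np.empty(n_frames, dtype=int)
    cum = np.cumsum(dwell, axis=1)
    state = int(rng.integers(k))
    for t in range(n_frames):
        labels[t] = state
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        state = min(state, k - 1)
    return labels


def generate_subject_series(
    truth: SyntheticTruth,
    n_frames: int,
    subject_perturbation_sd: float,
    seed: int | np.random.Generator,
    subject_id: str = "sub-0000",
    centroids: np.ndarray | None = None,
) -> SubjectSeriesDraw:
    """Simulate one subject's regional series.

    A Markov chain over states is drawn from ``truth.dwell_matrix``; each
    frame is the subject's perturbed centroid of the current state plus
    i.i.d. Gaussian noise. The stored series is demeaned per region.
    """
    if n_frames < truth.k:
        raise ValueError("n_frames must be >= number of states")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = truth.true_centroids if centroids is None else np.asarray(centroids, float)
    perturbed = base + rng.normal(0.0, subject_perturbation_sd, size=base.shape)
    labels = _simulate_chain(truth.dwell_matrix, n_frames, rng)
    raw = perturbed[labels] + rng.normal(0.0, truth.noise_sd, size=(n_frames, base.shape[1]))
    data = raw - raw.mean(axis=0, keepdims=True)
    series = SubjectTimeSeries(subject_id=subject_id, data=data)
    return SubjectSeriesDraw(series=series, labels=labels, raw=raw, centroids_used=perturbed)


def _draw_pedigree(group: str, rng: np.random.Generator) -> Pedigree:
    if group == FH_NEG:
        return Pedigree(0, 0)
    if group == FH_MIXED:
        return Pedigree(0, 1)
    # FH+: either >=1 affected parent (any grandparent count) or
    # no affected parent but >=2 affected grandparents.
    if rng.random() < 0.75:
        parents = int(rng.choice([1, 2], p=[0.8, 0.2]))
        grandparents = int(rng.integers(0, 5))
    else:
        parents = 0
        grandparents = int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1]))
    return Pedigree(parents, grandparents)


RACE_LEVELS = ("white", "black", "hispanic", "asian", "other")
SCANNER_LEVELS = ("GE_MR750", "Siemens_Prisma", "Siemens_Prisma_Fit")


def generate_covariates(
    n_subjects: int,
    seed: int | np.random.Generator,
    fh_probs: tuple[float, float, float] = DEFAULT_FH_PROBS,
) -> tuple[pd.DataFrame, list[Pedigree]]:
    """Draw a covariate table (one row per subject) and matching pedigrees.

    Marginal distributions are loosely modeled on a large developmental
    cohort: ~53% female, age ~ N(120, 7.5) months, 3-level income,
    5-level parental education, 3 scanner models, small mean FD.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    p = np.asarray(fh_probs, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("fh_probs must be three nonnegative values summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    groups = rng.choice([FH_POS, FH_NEG, FH_MIXED], size=n_subjects, p=p)
    pedigrees = [_draw_pedigree(g, rng) for g in groups]
    for g, ped in zip(groups, pedigrees):
        assert classify_family_history(ped) == g  # generator consistency

    rows = {
        "subject_id": [f"sub-{i:04d}" for i in range(n_subjects)],
        "sex": rng.choice(["female", "male"], size=n_subjects, p=[0.53, 0.47]),
        "fh_group": groups,
        "fhd": [compute_fhd(ped) for ped in pedigrees],
        "age_months": np.clip(rng.normal(120.0, 7.5, n_subjects), 100.0, 140.0),
        "income_level": rng.choice([1, 2, 3], size=n_subjects, p=[0.23, 0.30, 0.47]),
        "parental_education": rng.choice(
            [1, 2, 3, 4, 5], size=n_subjects, p=[0.03, 0.07, 0.10, 0.40, 0.40]
        ),
        "race_ethnicity": rng.choice(
            list(RACE_LEVELS), size=n_subjects, p=[0.62, 0.08, 0.18, 0.03, 0.09]
        ),
        "parental_mental_health": rng.choice([0, 1], size=n_subjects, p=[0.48, 0.52]),
        "prenatal_exposure": rng.choice([0, 1], size=n_subjects, p=[0.93, 0.07]),
        "scanner_model": rng.choice(list(SCANNER_LEVELS), size=n_subjects, p=[0.28, 0.36, 0.36]),
        "mean_fd": np.abs(rng.normal(0.12, 0.08, n_subjects)),
        "puberty_stage": rng.choice([1, 2, 3], size=n_subjects, p=[0.55, 0.25, 0.20]),
    }
    return pd.DataFrame(rows), pedigrees


def validate_covariates(table: pd.DataFrame) -> None:
    """Check the CovariateTable invariants (FH partition vs FHD agreement)."""
    fhd = table["fhd"].to_numpy(dtype=float)
    group = table["fh_group"].to_numpy()
    if not np.all((fhd == 0) == (group == FH_NEG)):
        raise ValueError("fhd == 0 must hold exactly for FH- subjects")
    if not set(np.unique(group)) <= {FH_POS, FH_NEG, FH_MIXED}:
        raise ValueError("fh_group levels must partition into FH+/FH-/FH+/-")


@dataclass(frozen=True)
class CohortDraw:
    series: list[SubjectTimeSeries]
    covariates: pd.DataFrame
    labels: dict[str, np.ndarray]
    truth: SyntheticTruth
    parcellation: ParcellationScheme


def _scaled_centroids(
    truth: SyntheticTruth, parcellation: ParcellationScheme, sex: str, fh_group: str
) -> np.ndarray:
    scales = truth.group_effect.get((sex, fh_group), {})
    c = truth.true_centroids.copy()
    for network, factor in scales.items():
        mask = parcellation.indicator(network) > 0
        c[:, mask] *= float(factor)
    return c


def generate_cohort(
    n_subjects: int,
    truth: SyntheticTruth,
    parcellation: ParcellationScheme,
    seed: int,
    n_frames: int = 200,
    subject_perturbation_sd: float = 0.05,
    fh_probs: tuple[float, float, float] = DEFAULT_FH_PROBS,
) -> CohortDraw:
    """Generate a full synthetic cohort.

    Covariates and per-subject series use independent child streams of the
    cohort seed, so with ``group_effect`` all 1 the series are independent
    of the planted group labels by construction.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if truth.true_centroids.shape[1] != parcellation.n_regions:
        raise ValueError("truth centroids and parcellation disagree on N")
    ss = np.random.SeedSequence(entropy=seed)
    cov_ss, series_ss = ss.spawn(2)
    covariates, _ = generate_covariates(
        n_subjects, np.random.default_rng(cov_ss), fh_probs=fh_probs
    )
    validate_covariates(covariates)

    series: list[SubjectTimeSeries] = []
    labels: dict[str, np.ndarray] = {}
    for i, child in enumerate(series_ss.spawn(n_subjects)):
        row = covariates.iloc[i]
        centroids = _scaled_centroids(truth, parcellation, row["sex"], row["fh_group"])
        draw = generate_subject_series(
            truth,
            n_frames=n_frames,
            subject_perturbation_sd=subject_perturbation_sd,
            seed=np.random.default_rng(child),
            subject_id=row["subject_id"],
            centroids=centroids,
        )
        series.append(draw.series)
        labels[row["subject_id"]] = draw.labels
    return CohortDraw(
        series=series, covariates=covariates, labels=labels, truth=truth, parcellation=parcellation
    )
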