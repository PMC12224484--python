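"""Synthetic connectome cohort generator.

Produces case-control cohorts with the statistical structure the downstream
classification pipeline assumes: six overlapping depression phenotype
definitions driven by a latent liability, an abbreviated childhood-trauma
(CTQ) score in [0, 1] whose conventional thresholds 0.2/0.4/0.6 fall near the
50th/70th/80th percentile of the case distribution, and per-subject
connectomes (functional full/partial correlation, Fisher-z; six structural
weighting channels) with a case-control effect planted in designated
subnetwork blocks and optionally amplified by trauma burden.

The functional generative model: each subject has a block-structured
correlation matrix over the node partition (higher within-subnetwork than
between), perturbed by a per-block subject-level random effect on the
Fisher-z scale; for case subjects the target blocks shift by
``delta * (1 + ctq_slope * ctq)`` on the z scale. Observed matrices are the
sample (and ridge-regularised partial) correlations of a finite
multivariate-normal time series, so realistic sampling noise is present by
construction.

Fixed seeds give bit-identical cohorts. Connectome simulation is seeded per
subject, so simulating any subset of subjects yields the same matrices as
simulating the whole cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PHENOTYPES",
    "SUBNETWORKS",
    "SubjectRecord",
    "CohortConfig",
    "ConfigurationError",
    "GenerationError",
    "generate_covariates",
    "assign_phenotypes",
    "generate_cohort",
    "simulate_functional",
    "simulate_structural",
    "functional_rng",
    "structural_rng",
    "shared_structural_topology",
    "phenotype_overlap_table",
    "OverlapTable",
    "cohort_to_frame",
    "frame_to_cohort",
]

#: The six case definitions, from medication-based to narrow questionnaire MDD.
PHENOTYPES = ("drug", "ever", "ever_severe", "current", "recurrent", "mdd_narrow")

#: Canonical six-way functional subnetwork labels: sensorimotor, visual,
#: executive-control/attention, cingulo-opercular, default-mode, extended DMN.
SUBNETWORKS = ("SMN", "VN", "EC_AN", "CON", "DMN", "eDMN")


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class GenerationError(RuntimeError):
    """The configured generator cannot produce a valid cohort."""


@dataclass
class SubjectRecord:
    """Covariates, trauma score and phenotype flags for one subject."""

    id: str
    index: int                       # position in the cohort; seeds the connectome streams
    age: float                       # years
    sex: str                         # "female" | "male"
    icv: float                       # intracranial volume, mm^3
    ctq: float                       # abbreviated CTQ, mean of the five items below
    ctq_items: tuple[float, ...]     # five item scores, each in [0, 1]
    liability: float = 0.0           # latent severity, approximately z-scaled
    current_symptoms: bool = False
    n_episodes: int = 0
    drug: bool = False
    ever: bool = False
    ever_severe: bool = False
    current: bool = False
    recurrent: bool = False
    mdd_narrow: bool = False
    excluded: bool = False           # comorbid-disorder exclusion flag

    def has_flag(self, phenotype: str) -> bool:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return bool(getattr(self, phenotype))

    def any_flag(self) -> bool:
        return any(getattr(self, p) for p in PHENOTYPES)


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    Defaults are calibrated so that, at large n: overall case prevalence for
    the broad ``ever`` definition is ~23% with a ~2:1 female-to-male case
    ratio; the CTQ thresholds 0.2/0.4/0.6 sit near the 50th/70th/80th
    percentile of the case CTQ distribution (so a 0.2 threshold retains
    roughly half the cases); and the severe definitions (``current``,
    ``ever_severe``) are nested inside ``ever``.
    """

    n_subjects: int = 1000
    seed: int = 0

    # --- node spaces -------------------------------------------------------
    functional_nodes: int = 55
    structural_nodes: int = 85
    subnetwork_sizes: tuple[int, ...] = (10, 9, 12, 8, 8, 8)
    subnetwork_names: tuple[str, ...] = SUBNETWORKS

    # --- planted effect ----------------------------------------------------
    #: unordered (subnetwork, subnetwork) pairs carrying the case effect
    target_blocks: tuple[tuple[str, str], ...] = (("VN", "VN"),)
    delta: float = 0.5               # case-control shift on the Fisher-z scale
    ctq_slope: float = 0.5           # multiplicative amplification per CTQ unit
    effect_phenotype: str = "current"

    # --- functional connectome model --------------------------------------
    ts_length: int = 200             # simulated time points
    within_corr: float = 0.30        # base within-subnetwork correlation
    between_corr: float = 0.05       # base between-subnetwork correlation
    block_jitter_sd: float = 0.15    # subject-level per-block SD, Fisher-z scale
    partial_rho: float = 0.5         # ridge strength for partial correlations

    # --- structural connectome model ---------------------------------------
    structural_channels: int = 6
    edge_prob: float = 0.6           # shared base topology density
    reliability: float = 0.9         # per-subject edge retention probability
    delta_s: float = 0.3             # case log-weight shift on target edges
    structural_target_nodes: int = 10  # effect on edges among the first k nodes
    log_weight_sd: float = 0.4       # per-edge latent factor shared by channels
    channel_noise_sd: float = 0.4    # channel-specific log-weight noise

    # --- covariates --------------------------------------------------------
    age_range: tuple[float, float] = (45.0, 80.0)
    female_fraction: float = 0.5
    icv_mean: dict = field(default_factory=lambda: {"female": 1.34e6, "male": 1.50e6})
    icv_sd: dict = field(default_factory=lambda: {"female": 1.1e5, "male": 1.2e5})
    exclusion_prob: float = 0.02

    # --- CTQ (zero-inflated Beta on the item mean; see docs/methods.md) ----
    ctq_zero_prob: float = 0.27
    ctq_beta_a: float = 0.43
    ctq_beta_b: float = 1.57
    ctq_item_concentration: float = 25.0

    # --- liability and phenotype thresholds --------------------------------
    sex_liability_shift: float = 0.28   # +shift for female, -shift for male
    ctq_liability_coef: float = 1.5
    liability_noise_sd: float = 0.9
    ever_threshold: float = 0.74        # t1: liability cut for "ever"
    severe_threshold: float = 1.70      # t2: liability cut for current/ever-severe
    p_current_symptoms: float = 0.274
    episode_rate: float = 0.868         # extra episodes ~ Poisson(rate) among ever
    drug_intercept: float = -3.895
    drug_slope: float = 1.5
    narrow_intercept: float = -3.579
    narrow_slope: float = 1.5

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be a positive integer")
        if sum(self.subnetwork_sizes) != self.functional_nodes:
            raise ConfigurationError(
                f"subnetwork_sizes {self.subnetwork_sizes} must sum to "
                f"functional_nodes={self.functional_nodes}"
            )
        if self.delta < 0:
            raise ConfigurationError("delta must be non-negative")
        for name, p in [("edge_prob", self.edge_prob),
                        ("exclusion_prob", self.exclusion_prob),
                        ("ctq_zero_prob", self.ctq_zero_prob)]:
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not 0.0 < self.reliability <= 1.0:
            raise ConfigurationError("reliability must lie in (0, 1]")
        if self.effect_phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown effect_phenotype {self.effect_phenotype!r}")
        names = self.subnetwork_names
        for a, b in self.target_blocks:
            if a not in names or b not in names:
                raise ConfigurationError(f"target block ({a}, {b}) not in {names}")

    @property
    def node_labels(self) -> np.ndarray:
        """Subnetwork label of every functional node, in block order."""
        return np.repeat(self.subnetwork_names, self.subnetwork_sizes)

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# covariates and phenotypes
# ---------------------------------------------------------------------------

def generate_covariates(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Draw ids, age, sex, ICV, CTQ items and the exclusion flag.

    Ages are uniform on the configured range; ICV is normal per sex; the CTQ
    score is the mean of five item scores drawn around a zero-inflated-Beta
    latent severity. Phenotype flags are assigned separately by
    :func:`assign_phenotypes`.
    """
    n = config.n_subjects
    age = rng.uniform(*config.age_range, size=n)
    female = rng.random(n) < config.female_fraction
    sex = np.where(female, "female", "male")
    icv = np.where(
        female,
        rng.normal(config.icv_mean["female"], config.icv_sd["female"], n),
        rng.normal(config.icv_mean["male"], config.icv_sd["male"], n),
    )
    # latent CTQ severity: zero-inflated Beta
    m = rng.beta(config.ctq_beta_a, config.ctq_beta_b, n)
    m[rng.random(n) < config.ctq_zero_prob] = 0.0
    kappa = config.ctq_item_concentration
    items = np.zeros((n, 5))
    pos = m > 0
    if pos.any():
        items[pos] = rng.beta(kappa * m[pos, None], kappa * (1.0 - m[pos, None]))
    ctq = items.mean(axis=1)
    excluded = rng.random(n) < config.exclusion_prob

    width = max(6, len(str(n)))
    return [
        SubjectRecord(
            id=f"S{i:0{width}d}",
            index=i,
            age=float(age[i]),
            sex=str(sex[i]),
            icv=float(icv[i]),
            ctq=float(ctq[i]),
            ctq_items=tuple(float(x) for x in items[i]),
            excluded=bool(excluded[i]),
        )
        for i in range(n)
    ]


def assign_phenotypes(
    subjects: list[SubjectRecord], config: CohortConfig, rng: np.random.Generator
) -> list[SubjectRecord]:
    """Assign the six overlapping depression phenotype flags in place.

    A latent liability (approximately standard normal, shifted up for female
    sex and high CTQ) drives all definitions:

    * ``ever``        — liability above t1 (broad definition);
    * ``current``     — liability above t2 and current symptoms present;
    * ``ever_severe`` — liability above t2 and current symptoms absent;
    * ``recurrent``   — ever with at least two lifetime episodes;
    * ``drug`` / ``mdd_narrow`` — liability-dependent Bernoulli draws.

    Excluded (comorbid) subjects carry no flag. Raises
    :class:`GenerationError` naming the phenotype if any definition yields
    zero cases in a cohort of at least 1000 subjects.
    """
    n = len(subjects)
    ctq = np.array([s.ctq for s in subjects])
    female = np.array([s.sex == "female" for s in subjects])
    liability = (
        config.sex_liability_shift * np.where(female, 1.0, -1.0)
        + config.ctq_liability_coef * (ctq - ctq.mean())
        + config.liability_noise_sd * rng.standard_normal(n)
    )
    current_symptoms = rng.random(n) < config.p_current_symptoms
    extra_episodes = rng.poisson(config.episode_rate, n)
    drug_draw = rng.random(n) < expit(config.drug_intercept + config.drug_slope * liability)
    narrow_draw = rng.random(n) < expit(config.narrow_intercept + config.narrow_slope * liability)

    ever = liability > config.ever_threshold
    severe = liability > config.severe_threshold
    for i, s in enumerate(subjects):
        s.liability = float(liability[i])
        s.current_symptoms = bool(current_symptoms[i])
        s.n_episodes = int(1 + extra_episodes[i]) if ever[i] else 0
        if s.excluded:
            continue
        s.ever = bool(ever[i])
        s.current = bool(severe[i] and current_symptoms[i])
        s.ever_severe = bool(severe[i] and not current_symptoms[i])
        s.recurrent = bool(ever[i] and s.n_episodes >= 2)
        s.drug = bool(drug_draw[i])
        s.mdd_narrow = bool(narrow_draw[i])

    if n >= 1000:
        for p in PHENOTYPES:
            if not any(s.has_flag(p) for s in subjects):
                raise GenerationError(
                    f"phenotype {p!r} has zero cases in a cohort of {n} subjects; "
                    "check the liability thresholds"
                )
    return subjects


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Covariates plus phenotypes, seeded from ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    subjects = generate_covariates(config, rng)
    return assign_phenotypes(subjects, config, rng)


# ---------------------------------------------------------------------------
# functional connectomes
# ---------------------------------------------------------------------------

_FUNC_STREAM = 1
_STRUCT_STREAM = 2
_TOPOLOGY_STREAM = 3


def functional_rng(config: CohortConfig, subject: SubjectRecord) -> np.random.Generator:
    """Per-subject generator for the functional stream (subset-stable)."""
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, _FUNC_STREAM, subject.index))
    )


def structural_rng(config: CohortConfig, subject: SubjectRecord) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, _STRUCT_STREAM, subject.index))
    )


def _base_z_matrix(config: CohortConfig) -> np.ndarray:
    """Block-constant Fisher-z connectivity template (diagonal untouched)."""
    labels = config.node_labels
    same = labels[:, None] == labels[None, :]
    z = np.where(same, np.arctanh(config.within_corr), np.arctanh(config.between_corr))
    np.fill_diagonal(z, 0.0)
    return z


def _block_mask(config: CohortConfig, a: str, b: str) -> np.ndarray:
    labels = config.node_labels
    in_a = labels == a
    in_b = labels == b
    mask = np.outer(in_a, in_b) | np.outer(in_b, in_a)
    np.fill_diagonal(mask, False)
    return mask


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(r)
    if w.min() > 1e-8:
        return r
    w = np.clip(w, 1e-6, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def subject_correlation(
    subject: SubjectRecord, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """The subject's population correlation matrix (before sampling noise)."""
    z = _base_z_matrix(config)
    labels = list(dict.fromkeys(config.node_labels))  # unique, in order
    # subject-level random effect: one z-shift per unordered block pair
    for i, a in enumerate(labels):
        for b in labels[i:]:
            jitter = rng.normal(0.0, config.block_jitter_sd)
            z = z + jitter * _block_mask(config, a, b)
    if subject.has_flag(config.effect_phenotype):
        shift = config.delta * (1.0 + config.ctq_slope * subject.ctq)
        for a, b in config.target_blocks:
            z = z + shift * _block_mask(config, a, b)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return _nearest_correlation(r)


def simulate_functional(
    subject: SubjectRecord, config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one subject's (full, partial) functional connectomes.

    Draws ``ts_length`` multivariate-normal samples from the subject's
    correlation structure. The full matrix is the Fisher-z of the sample
    correlation; the partial matrix is the Fisher-z of partial correlations
    from the Tikhonov-regularised inverse sample correlation (ridge strength
    ``partial_rho``). Both are symmetric with zero diagonal.
    """
    if rng is None:
        rng = functional_rng(config, subject)
    base = np.tanh(_base_z_matrix(config))
    np.fill_diagonal(base, 1.0)
    if np.linalg.eigvalsh(base).min() <= 0:
        raise GenerationError("base block covariance is not positive definite")

    sigma = subject_correlation(subject, config, rng)
    chol = np.linalg.cholesky(sigma)
    ts = (chol @ rng.standard_normal((config.functional_nodes, config.ts_length))).T

    corr = np.corrcoef(ts, rowvar=False)
    full_z = np.arctanh(np.clip(corr, -0.999999, 0.999999))
    np.fill_diagonal(full_z, 0.0)

    prec = np.linalg.inv(corr + config.partial_rho * np.eye(config.functional_nodes))
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    partial_z = np.arctanh(np.clip(pcorr, -0.999999, 0.999999))
    np.fill_diagonal(partial_z, 0.0)

    full_z = (full_z + full_z.T) / 2.0
    partial_z = (partial_z + partial_z.T) / 2.0
    return full_z, partial_z


# ---------------------------------------------------------------------------
# structural connectomes
# ---------------------------------------------------------------------------

def shared_structural_topology(config: CohortConfig) -> np.ndarray:
    """Cohort-wide base edge-presence mask (symmetric boolean, zero diagonal)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _TOPOLOGY_STREAM)))
    n = config.structural_nodes
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < config.edge_prob
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = present
    return mask | mask.T


def simulate_structural(
    subject: SubjectRecord,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    topology: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the subject's six structural weighting channels.

    Returns an array of shape ``(structural_channels, n, n)``. A shared base
    topology defines which edges can exist; per subject each is retained with
    probability ``reliability`` (absent edges are exact zeros). Weights are
    log-normal with a per-edge latent factor shared across channels, so
    channels are positively correlated. For case subjects the log-weights of
    edges among the first ``structural_target_nodes`` nodes shift by
    ``delta_s * (1 + ctq_slope * ctq)``.
    """
    if not 0.0 < config.reliability <= 1.0:
        raise ConfigurationError("reliability must lie in (0, 1]")
    if rng is None:
        rng = structural_rng(config, subject)
    if topology is None:
        topology = shared_structural_topology(config)
    n = config.structural_nodes
    iu = np.triu_indices(n, 1)
    base = topology[iu]
    kept = base & (rng.random(len(base)) < config.reliability)

    shared = rng.normal(0.0, config.log_weight_sd, len(base))
    noise = rng.normal(0.0, config.channel_noise_sd, (config.structural_channels, len(base)))
    logw = shared[None, :] + noise  # (channels, edges)

    if subject.has_flag(config.effect_phenotype):
        k = config.structural_target_nodes
        in_target = (iu[0] < k) & (iu[1] < k)
        logw[:, in_target] += config.delta_s * (1.0 + config.ctq_slope * subject.ctq)

    weights = np.exp(logw) * kept[None, :]
    out = np.zeros((config.structural_channels, n, n))
    for c in range(config.structural_channels):
        m = np.zeros((n, n))
        m[iu] = weights[c]
        out[c] = m + m.T
    return out


# ---------------------------------------------------------------------------
# overlap table
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """Pairwise case-overlap counts and column percentages.

    ``counts[i, j]`` (i != j) is the number of subjects who are cases under
    both phenotype i and phenotype j; the diagonal holds the number of cases
    unique to that phenotype. ``percent`` divides each column by that
    column's total case count (x100); the printed convention rounds to one
    decimal.
    """

    phenotypes: tuple[str, ...]
    counts: pd.DataFrame
    percent: pd.DataFrame
    totals: pd.Series

    def formatted(self) -> pd.DataFrame:
        out = self.counts.astype(str)
        for i in self.counts.index:
            for j in self.counts.columns:
                out.loc[i, j] = f"{self.counts.loc[i, j]} ({self.percent.loc[i, j]:.1f}%)"
        return out


def overlap_percentage(overlap: int, column_total: int) -> float:
    """Column-relative overlap on the printed percent scale (e.g. 460/703 -> 65.4)."""
    from .stability import round_half_up

    if column_total == 0:
        return 0.0
    return round_half_up(100.0 * overlap / column_total, 1)


def phenotype_overlap_table(
    subjects: Iterable[SubjectRecord], phenotypes: Sequence[str] = PHENOTYPES
) -> OverlapTable:
    subjects = list(subjects)
    case_sets = {p: {s.id for s in subjects if s.has_flag(p)} for p in phenotypes}
    k = len(phenotypes)
    counts = np.zeros((k, k), dtype=int)
    percent = np.zeros((k, k))
    totals = np.array([len(case_sets[p]) for p in phenotypes])
    for i, pi in enumerate(phenotypes):
        for j, pj in enumerate(phenotypes):
            if i == j:
                others = set().union(*(case_sets[q] for q in phenotypes if q != pi))
                counts[i, j] = len(case_sets[pi] - others)
            else:
                counts[i, j] = len(case_sets[pi] & case_sets[pj])
            percent[i, j] = overlap_percentage(counts[i, j], totals[j])
    idx = list(phenotypes)
    return OverlapTable(
        phenotypes=tuple(phenotypes),
        counts=pd.DataFrame(counts, index=idx, columns=idx),
        percent=pd.DataFrame(percent, index=idx, columns=idx),
        totals=pd.Series(totals, index=idx),
    )


# ---------------------------------------------------------------------------
# tabular round trip
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = [
    "id", "index", "age", "sex", "icv", "ctq", "liability", "current_symptoms",
    "n_episodes", *PHENOTYPES, "excluded",
]


def cohort_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {c: getattr(s, c) for c in _SCALAR_COLUMNS}
        for k in range(5):
            row[f"ctq_item{k + 1}"] = s.ctq_items[k]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    subjects = []
    for _, row in frame.iterrows():
        kwargs = {c: row[c] for c in _SCALAR_COLUMNS}
        kwargs["index"] = int(kwargs["index"])
        kwargs["n_episodes"] = int(kwargs["n_episodes"])
        for c in ("current_symptoms", *PHENOTYPES, "excluded"):
            kwargs[c] = bool(kwargs[c])
        kwargs["ctq_items"] = tuple(float(row[f"ctq_item{k + 1}"]) for k in range(5))
        subjects.append(SubjectRecord(**kwargs))
    return subjects
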