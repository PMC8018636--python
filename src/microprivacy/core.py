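"""Membership-inference risk assessment for microbiome summary statistics.

Human microbiome association studies (HMAS) routinely publish per-group mean
OTU frequencies.  Those summary statistics leak membership: given a target
individual's binary presence/absence profile ``y`` over the same ``t`` OTUs
and the mean-frequency vectors ``r`` (reference group, size ``n_R``) and ``c``
(case group, size ``n_C``), the per-OTU distance

    d_j = |y_j - r_j| - |y_j - c_j|

is, on average, negative when the individual contributed to ``r`` and
positive when they contributed to ``c``.  Because ``t`` is large, the
standardized mean

    Z = (d_bar - mu_0) / (s / sqrt(t))

is approximately standard normal for an individual drawn from the common
source population (the null), so the three-way decision H0 (outsider) /
HR (member of R) / HC (member of C) is a pair of one-sided z-tests.

This module contains, in the order the method runs:

1. configuration, error types and seeded named RNG substreams;
2. the Beta-Bernoulli population model and group samplers used to measure
   the attack (per-OTU presence probabilities ``p_j ~ Beta(pi1, pi2)``,
   individuals ``y ~ Bernoulli(p)``, summaries as sample column means or,
   equivalently in distribution, ``Binomial(n, p)/n``);
3. the membership test itself plus two analytic diagnostics: the effective
   number of independent OTUs ``t_e = t / (1 + rho*(t-1))`` under average
   distance correlation ``rho``, and the shifted null mean
   ``mu0* = E(Delta) - 2 E(Delta) E(p)`` when the groups' source populations
   differ systematically by ``Delta`` in summary means;
4. the power-simulation machinery: null (Z^P) and true-positive
   (Z^{R+}, Z^{C+}) statistic draws, empirical critical values from null
   percentiles, type-II error (beta) estimation with Monte-Carlo standard
   errors, Gaussian-KDE density curves, and the (n, t) power grid;
5. TSV/JSON input-output and provenance records used by the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    # errors
    "MicroprivacyError",
    "ParameterError",
    "InputError",
    "AlignmentError",
    "DegenerateVarianceError",
    "SmallOtuCountWarning",
    # population model
    "PopulationModel",
    "TaxonProfile",
    "GroupSummary",
    "SampleMatrix",
    "sample_population",
    "draw_microbiome",
    "draw_sample",
    "summarize_sample",
    "sample_summary_direct",
    "binarize",
    "default_otu_ids",
    # membership test
    "MembershipTestResult",
    "CorrelationAdjustment",
    "ShiftedNull",
    "compute_distances",
    "z_statistic",
    "decide",
    "effective_otus",
    "adjusted_variance",
    "shifted_null_mean",
    "run_membership_test",
    # power simulation
    "SimulationConfig",
    "ZDistributions",
    "PowerEstimate",
    "DensityCurve",
    "simulate_distributions",
    "empirical_critical_values",
    "estimate_beta",
    "estimate_power",
    "density_curve",
    "power_grid",
    "unequal_size_run",
    # I/O
    "read_profiles_tsv",
    "write_profiles_tsv",
    "read_taxon_profile",
    "read_group_summary",
    "write_group_summary",
    "write_z_draws_tsv",
    "read_z_draws_tsv",
    "write_density_curve_tsv",
    "write_power_grid_tsv",
    "write_provenance",
]

logger = logging.getLogger("microprivacy")

#: the central-limit argument behind the normal null needs a reasonably large
#: number of OTUs; below this count the z approximation is only advisory.
CLT_MIN_OTUS = 50

#: default number of null (Z^P) and true-positive (Z^{R+}, Z^{C+}) statistic
#: draws per replicate, matching the original simulation design.
DEFAULT_N_DRAWS = 100


# ---------------------------------------------------------------------------
# errors and RNG substreams
# ---------------------------------------------------------------------------


class MicroprivacyError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(MicroprivacyError, ValueError):
    """A parameter is outside its admissible domain."""


class InputError(MicroprivacyError, ValueError):
    """An input object (vector, matrix, file) is malformed or empty."""


class AlignmentError(InputError):
    """Query and summaries do not share length or OTU ordering."""


class DegenerateVarianceError(MicroprivacyError, ArithmeticError):
    """All per-OTU distances are identical, so the z-statistic is undefined.

    Typically the reference and case summaries coincide on every OTU; the
    query/summary combination carries no membership signal either way.
    """


class SmallOtuCountWarning(UserWarning):
    """The OTU count is too small for the normal approximation to be safe."""


def _substream(seed: int | np.random.Generator, *labels: str) -> np.random.Generator:
    """Return a named, order-independent RNG substream of a root seed.

    Every sampler in this module derives its generator through this helper,
    so e.g. changing how many null queries are drawn never perturbs the
    population or the group samples.  A ``Generator`` passed straight through
    lets internal callers chain draws on one stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(label.encode("utf-8")) for label in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def default_otu_ids(t: int) -> list[str]:
    """Positional synthetic OTU identifiers ``OTU_000001 ... OTU_<t>``."""
    return [f"OTU_{j + 1:06d}" for j in range(t)]


# ---------------------------------------------------------------------------
# population model: Beta-Bernoulli communities and group summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """A source population of microbiomes.

    The presence of OTU ``j`` in a random individual is Bernoulli(``p[j]``),
    independently across OTUs, with the presence probabilities themselves
    i.i.d. Beta(``pi1``, ``pi2``) across OTUs.
    """

    p: np.ndarray
    pi1: float
    pi2: float
    t: int
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1 or p.size != self.t:
            raise ParameterError(f"p must be a length-{self.t} vector, got shape {p.shape}")
        if np.any((p < 0) | (p > 1)):
            raise ParameterError("presence probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TaxonProfile:
    """One individual's binary presence/absence vector over ``t`` OTUs."""

    y: np.ndarray
    otu_ids: list[str] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 1:
            raise InputError("profile must be a 1-D vector")
        if not np.isin(y, (0, 1)).all():
            raise InputError("profile elements must be strictly binary (0/1)")
        object.__setattr__(self, "y", y.astype(np.uint8))
        if self.otu_ids is not None and len(self.otu_ids) != y.size:
            raise AlignmentError(
                f"{len(self.otu_ids)} OTU ids for a length-{y.size} profile"
            )

    @property
    def t(self) -> int:
        return int(self.y.size)


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary statistic: mean OTU frequencies.

    ``freq[j]`` is the fraction of the ``n`` group members carrying OTU ``j``
    (so frequencies from a real sample sit on the lattice 0, 1/n, ..., 1).
    """

    freq: np.ndarray
    n: int
    label: str
    otu_ids: list[str] | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        if freq.ndim != 1:
            raise InputError("summary frequencies must be a 1-D vector")
        if np.any((freq < 0) | (freq > 1)):
            raise InputError("summary frequencies must lie in [0, 1]")
        if self.n < 1:
            raise ParameterError("group size n must be a positive integer")
        if self.otu_ids is not None and len(self.otu_ids) != freq.size:
            raise AlignmentError(
                f"{len(self.otu_ids)} OTU ids for a length-{freq.size} summary"
            )

    @property
    def t(self) -> int:
        return int(self.freq.size)


@dataclass(frozen=True)
class SampleMatrix:
    """A materialized group sample: ``n`` stacked binary profiles (n x t)."""

    rows: np.ndarray
    label: str

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2 or rows.size == 0:
            raise InputError("sample matrix must be a non-empty n x t matrix")
        if not np.isin(rows, (0, 1)).all():
            raise InputError("sample matrix must be strictly binary")
        object.__setattr__(self, "rows", rows.astype(np.uint8))

    @property
    def n(self) -> int:
        return int(self.rows.shape[0])

    @property
    def t(self) -> int:
        return int(self.rows.shape[1])


def sample_population(
    t: int, pi1: float, pi2: float, seed: int | np.random.Generator
) -> PopulationModel:
    """Draw a population: ``t`` i.i.d. Beta(pi1, pi2) presence probabilities.

    Deterministic given ``seed``; the draw uses the dedicated "population"
    substream of the root seed.
    """
    if t < 1 or int(t) != t:
        raise ParameterError(f"OTU count t must be a positive integer, got {t!r}")
    if pi1 <= 0 or pi2 <= 0:
        raise ParameterError("Beta shape parameters must be strictly positive")
    rng = _substream(seed, "population")
    p = rng.beta(pi1, pi2, size=int(t))
    root = seed if isinstance(seed, int) else -1
    return PopulationModel(p=p, pi1=float(pi1), pi2=float(pi2), t=int(t), seed=root)


def draw_microbiome(
    pop: PopulationModel, seed: int | np.random.Generator
) -> TaxonProfile:
    """Draw one individual: element ``j`` is Bernoulli(``p_j``), independent."""
    rng = _substream(seed, "query")
    y = (rng.random(pop.t) < pop.p).astype(np.uint8)
    return TaxonProfile(y=y)


def draw_sample(
    pop: PopulationModel, n: int, label: str, seed: int | np.random.Generator
) -> SampleMatrix:
    """Draw a group sample of ``n`` independent individuals from ``pop``."""
    if n < 1 or int(n) != n:
        raise ParameterError(f"sample size n must be a positive integer, got {n!r}")
    rng = _substream(seed, f"sample-{label}")
    rows = (rng.random((int(n), pop.t)) < pop.p).astype(np.uint8)
    return SampleMatrix(rows=rows, label=label)


def summarize_sample(
    sample: SampleMatrix, otu_ids: list[str] | None = None
) -> GroupSummary:
    """Pool a sample into its published summary: column means and size.

    Marginally each frequency is Binomial(n, p_j)/n, the same law as
    :func:`sample_summary_direct`.
    """
    freq = sample.rows.mean(axis=0)
    return GroupSummary(freq=freq, n=sample.n, label=sample.label, otu_ids=otu_ids)


def sample_summary_direct(
    pop: PopulationModel, n: int, label: str, seed: int | np.random.Generator
) -> GroupSummary:
    """Draw a group summary directly as Binomial(n, p)/n per OTU.

    Distributionally identical to ``summarize_sample(draw_sample(...))`` but
    never materializes the individual profiles, so no true member can be
    extracted from it.  Use :func:`draw_sample` when member queries are
    needed.
    """
    if n < 1 or int(n) != n:
        raise ParameterError(f"sample size n must be a positive integer, got {n!r}")
    rng = _substream(seed, f"sample-{label}")
    freq = rng.binomial(int(n), pop.p) / float(n)
    return GroupSummary(freq=freq, n=int(n), label=label)


def binarize(
    freqs: Sequence[float] | np.ndarray,
    threshold: float = 0.0,
    otu_ids: list[str] | None = None,
) -> TaxonProfile:
    """Convert a relative-frequency profile to presence/absence.

    Presence means frequency strictly greater than ``threshold`` (default 0,
    i.e. any detection counts).  Idempotent: binarizing a binary vector with
    the default threshold returns it unchanged.
    """
    x = np.asarray(freqs, dtype=float)
    if x.ndim != 1:
        raise InputError("frequency profile must be a 1-D vector")
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise InputError("frequencies must be finite and lie in [0, 1]")
    return TaxonProfile(y=(x > threshold).astype(np.uint8), otu_ids=otu_ids)


# ---------------------------------------------------------------------------
# membership test: distances, Z, decision, analytic corrections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipTestResult:
    """Full record of one membership test."""

    d_mean: float
    d_sd: float
    t: int
    z: float
    mu0: float
    alpha: float
    decision: str
    crit_low: float
    crit_high: float
    null_source: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class CorrelationAdjustment:
    """Effective independent OTU count under average distance correlation.

    When per-OTU distances share an average pairwise correlation ``rho``,
    ``V(d_bar) = V(d)/t * (1 + rho*(t-1))``, i.e. the test behaves as if it
    had ``t_e = t / (1 + rho*(t-1))`` independent OTUs.
    """

    rho: float
    t: int
    t_e: float
    v_dbar_factor: float


@dataclass(frozen=True)
class ShiftedNull:
    """Corrected null mean when the groups' source populations diverge.

    If the summary difference has systematic expectation E(Delta) != 0, an
    outsider's expected distance is mu0* = E(Delta) - 2 E(Delta) E(p) rather
    than 0; it vanishes as the mean presence probability approaches 0.5.
    """

    e_delta: float
    e_p: float
    mu0_star: float


def _aligned_arrays(
    query: TaxonProfile, ref: GroupSummary, case: GroupSummary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = query.t
    if ref.t != t or case.t != t:
        raise AlignmentError(
            f"length mismatch: query t={t}, reference t={ref.t}, case t={case.t}"
        )
    ids = [v.otu_ids for v in (query, ref, case) if v.otu_ids is not None]
    for other in ids[1:]:
        if other != ids[0]:
            bad = next(
                (j for j, (a, b) in enumerate(zip(ids[0], other)) if a != b), None
            )
            raise AlignmentError(
                "OTU id mismatch between query and summaries"
                + (f" (first differing position {bad}: {ids[0][bad]!r} vs {other[bad]!r})" if bad is not None else "")
            )
    return query.y.astype(float), ref.freq, case.freq


def compute_distances(
    query: TaxonProfile, ref: GroupSummary, case: GroupSummary
) -> np.ndarray:
    """Per-OTU distance d_j = |y_j - r_j| - |y_j - c_j|.

    Negative values pull the query toward the reference group, positive
    values toward the case group.  For binary y this equals
    (1 - 2 y_j) * (r_j - c_j) elementwise.
    """
    y, r, c = _aligned_arrays(query, ref, case)
    return np.abs(y - r) - np.abs(y - c)


def z_statistic(
    d: Sequence[float] | np.ndarray, mu0: float = 0.0
) -> tuple[float, float, float]:
    """Standardized mean distance: z = (mean(d) - mu0) / (s / sqrt(t)).

    ``s`` is the sample standard deviation (t-1 denominator).  Returns
    ``(z, d_mean, d_sd)``.  Warns when t <= 50, where the central-limit
    normal approximation is shaky; raises :class:`DegenerateVarianceError`
    when every distance is identical.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise InputError("need at least two distances to form a z-statistic")
    t = d.size
    if t <= CLT_MIN_OTUS:
        warnings.warn(
            f"only t={t} OTUs; the normal approximation for Z assumes t > {CLT_MIN_OTUS}",
            SmallOtuCountWarning,
            stacklevel=2,
        )
    d_mean = float(d.mean())
    d_sd = float(d.std(ddof=1))
    # identical entries can leave a tiny nonzero sd through rounding in the mean
    if d_sd == 0.0 or d.max() == d.min():
        raise DegenerateVarianceError(
            "all per-OTU distances are identical (s = 0); "
            "reference and case summaries may coincide on every OTU"
        )
    z = (d_mean - mu0) / (d_sd / math.sqrt(t))
    return float(z), d_mean, d_sd


def decide(
    z: float, alpha: float, null_quantile_fn: Callable[[float], float]
) -> str:
    """Three-way decision from two one-sided level-``alpha`` tests.

    "HC" (member of the case group) when z exceeds the (1-alpha) null
    quantile, "HR" (member of the reference group) when z falls below the
    alpha quantile, else "H0" (outsider).  Each tail is tested at level
    alpha, so the total size against H0 is 2*alpha.
    """
    if not 0 < alpha < 0.5:
        raise ParameterError(f"alpha must lie in (0, 0.5), got {alpha}")
    crit_high = float(null_quantile_fn(1.0 - alpha))
    crit_low = float(null_quantile_fn(alpha))
    if z > crit_high:
        return "HC"
    if z < crit_low:
        return "HR"
    return "H0"


def effective_otus(t: int, rho: float) -> CorrelationAdjustment:
    """Effective number of independent OTUs t_e = t / (1 + rho*(t-1)).

    ``rho`` is the average pairwise correlation among per-OTU distances.
    Positive rho shrinks t_e (correlated OTUs carry less information, as
    with linkage disequilibrium among SNPs); negative rho inflates it, with
    t_e -> infinity as rho approaches its lower bound -1/(t-1).
    """
    if t < 2 or int(t) != t:
        raise ParameterError("t must be an integer >= 2")
    lower = -1.0 / (t - 1)
    if rho < lower or rho > 1:
        raise ParameterError(
            f"rho must satisfy -1/(t-1) = {lower:.6g} <= rho <= 1 "
            f"(variance of d_bar would be negative), got {rho}"
        )
    factor = 1.0 + rho * (t - 1)
    t_e = math.inf if factor == 0.0 else t / factor
    return CorrelationAdjustment(rho=float(rho), t=int(t), t_e=t_e, v_dbar_factor=factor)


def adjusted_variance(v_d: float, t: int, rho: float) -> float:
    """Variance of the mean distance under correlated OTUs.

    V(d_bar) = V(d)/t * (1 + rho*(t-1)) = V(d) / t_e.  Equals V(d)/t under
    independence (rho = 0), V(d) at rho = 1, and 0 at rho = -1/(t-1).
    """
    if v_d < 0:
        raise ParameterError("variance must be non-negative")
    adj = effective_otus(t, rho)
    return v_d * adj.v_dbar_factor / t


def shifted_null_mean(e_delta: float, e_p: float) -> ShiftedNull:
    """Null mean correction when the source populations are not identical.

    With a systematic summary difference of expectation ``e_delta`` between
    the groups' underlying populations and mean presence probability
    ``e_p``, an outsider's expected distance is
    mu0* = E(Delta) - 2 E(Delta) E(p), bounded in [-1, 1] and vanishing as
    e_p -> 0.5.
    """
    if not -1.0 <= e_delta <= 1.0:
        raise ParameterError("E(Delta) must lie in [-1, 1]")
    if not 0.0 < e_p <= 1.0:
        raise ParameterError("E(p) must lie in (0, 1]")
    return ShiftedNull(
        e_delta=float(e_delta),
        e_p=float(e_p),
        mu0_star=float(e_delta * (1.0 - 2.0 * e_p)),
    )


def _null_quantile_fn(
    null_spec: str | Sequence[float] | np.ndarray,
) -> tuple[Callable[[float], float], str]:
    """Resolve a null specification into a quantile function.

    ``"normal"`` uses exact N(0,1) quantiles.  A vector of simulated null
    statistics (Z^P draws) yields empirical percentiles, the preferred route
    when simulation context exists because the finite-sample null can
    diverge from N(0,1).
    """
    if isinstance(null_spec, str):
        if null_spec != "normal":
            raise ParameterError(f"unknown null specification {null_spec!r}")
        return (lambda q: float(stats.norm.ppf(q))), "normal"
    z_null = np.asarray(null_spec, dtype=float)
    if z_null.size < 20:
        raise InputError(
            f"need at least 20 null draws for empirical critical values, got {z_null.size}"
        )
    return (lambda q: float(np.quantile(z_null, q))), "empirical"


def run_membership_test(
    query: TaxonProfile,
    ref: GroupSummary,
    case: GroupSummary,
    alpha: float = 0.05,
    null_spec: str | Sequence[float] | np.ndarray = "normal",
    mu0: float = 0.0,
) -> MembershipTestResult:
    """Full membership test: distances -> z-statistic -> three-way decision.

    Swapping ``ref`` and ``case`` negates z exactly and maps HC <-> HR.
    """
    if not 0 < alpha < 0.5:
        raise ParameterError(f"alpha must lie in (0, 0.5), got {alpha}")
    d = compute_distances(query, ref, case)
    z, d_mean, d_sd = z_statistic(d, mu0=mu0)
    quantile_fn, null_source = _null_quantile_fn(null_spec)
    decision = decide(z, alpha, quantile_fn)
    return MembershipTestResult(
        d_mean=d_mean,
        d_sd=d_sd,
        t=int(d.size),
        z=z,
        mu0=float(mu0),
        alpha=float(alpha),
        decision=decision,
        crit_low=float(quantile_fn(alpha)),
        crit_high=float(quantile_fn(1.0 - alpha)),
        null_source=null_source,
    )


# ---------------------------------------------------------------------------
# power simulation: Z^P / Z^{R+} / Z^{C+}, beta estimation, the (n, t) grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one power-simulation experiment.

    ``n_null_draws`` outsider statistics (Z^P) and ``n_tp_draws``
    true-positive statistics per group (Z^{R+}, Z^{C+}) are computed per
    replicate; ``n_reps`` replicates, each with a fresh population and fresh
    samples, are pooled.
    """

    t: int
    n_R: int
    n_C: int
    pi1: float = 1.0
    pi2: float = 1.0
    alpha: float = 0.05
    n_null_draws: int = DEFAULT_N_DRAWS
    n_tp_draws: int = DEFAULT_N_DRAWS
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t", "n_R", "n_C", "n_null_draws", "n_tp_draws", "n_reps"):
            v = getattr(self, name)
            if v < 1 or int(v) != v:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.pi1 <= 0 or self.pi2 <= 0:
            raise ParameterError("Beta shape parameters must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ZDistributions:
    """Pooled statistic draws from a power simulation.

    ``n_degenerate`` counts draws dropped because every distance was
    identical (possible at tiny t); dropped draws shorten the vectors.
    """

    z_null: np.ndarray
    z_tp_R: np.ndarray
    z_tp_C: np.ndarray
    config: SimulationConfig
    n_degenerate: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PowerEstimate:
    """Type-II error estimates with their Monte-Carlo standard errors."""

    beta_R: float
    beta_C: float
    crit_low: float
    crit_high: float
    alpha: float
    mc_se_R: float
    mc_se_C: float


@dataclass(frozen=True)
class DensityCurve:
    """A Gaussian-KDE density evaluated on a grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    label: str


def _z_batch(
    rows: np.ndarray, w: np.ndarray, mu0: float = 0.0, chunk: int = 256
) -> tuple[np.ndarray, int]:
    """Vectorized z-statistics for many binary queries against one (r, c).

    ``w = r - c``; for binary y, d = (1 - 2y) * w row-wise.  Processes in
    chunks to bound memory at large t.  Returns the z values of the
    non-degenerate rows and the count of degenerate (s = 0) rows dropped.
    """
    t = w.size
    sqrt_t = math.sqrt(t)
    out: list[np.ndarray] = []
    n_degenerate = 0
    for start in range(0, rows.shape[0], chunk):
        d = (1.0 - 2.0 * rows[start : start + chunk]) * w
        d_mean = d.mean(axis=1)
        d_sd = d.std(axis=1, ddof=1)
        ok = d_sd > 0
        n_degenerate += int((~ok).sum())
        out.append((d_mean[ok] - mu0) / (d_sd[ok] / sqrt_t))
    return np.concatenate(out) if out else np.empty(0), n_degenerate


def simulate_distributions(cfg: SimulationConfig) -> ZDistributions:
    """Simulate null and true-positive membership statistics.

    Per replicate: draw a population p ~ Beta(pi1, pi2)^t, materialize
    samples R (n_R x t) and C (n_C x t), pool them into summaries, then

    * Z^P  — fresh outsiders y ~ Bernoulli(p), never members of either
      sample (the true null);
    * Z^{R+}, Z^{C+} — uniformly selected member rows of R and C (true
      positives; the member's profile contributed to the summary it is
      tested against).

    All statistics use mu0 = 0.  Degenerate draws are dropped and counted.
    """
    z_null_parts: list[np.ndarray] = []
    z_r_parts: list[np.ndarray] = []
    z_c_parts: list[np.ndarray] = []
    n_deg = {"null": 0, "tp_R": 0, "tp_C": 0}

    for rep in range(cfg.n_reps):
        tag = f"rep{rep:06d}"
        pop = sample_population(
            cfg.t, cfg.pi1, cfg.pi2, _substream(cfg.seed, tag, "population")
        )
        sample_r = draw_sample(pop, cfg.n_R, "R", _substream(cfg.seed, tag, "sample-R"))
        sample_c = draw_sample(pop, cfg.n_C, "C", _substream(cfg.seed, tag, "sample-C"))
        w = sample_r.rows.mean(axis=0) - sample_c.rows.mean(axis=0)

        rng_null = _substream(cfg.seed, tag, "null-queries")
        null_rows = (rng_null.random((cfg.n_null_draws, cfg.t)) < pop.p).astype(np.uint8)
        z, k = _z_batch(null_rows, w)
        z_null_parts.append(z)
        n_deg["null"] += k

        rng_pick = _substream(cfg.seed, tag, "tp-selection")
        idx_r = rng_pick.integers(0, cfg.n_R, size=cfg.n_tp_draws)
        idx_c = rng_pick.integers(0, cfg.n_C, size=cfg.n_tp_draws)
        z, k = _z_batch(sample_r.rows[idx_r], w)
        z_r_parts.append(z)
        n_deg["tp_R"] += k
        z, k = _z_batch(sample_c.rows[idx_c], w)
        z_c_parts.append(z)
        n_deg["tp_C"] += k

    total_dropped = sum(n_deg.values())
    if total_dropped:
        logger.warning(
            "dropped %d degenerate-variance draws (t=%d may be too small)",
            total_dropped,
            cfg.t,
        )
    return ZDistributions(
        z_null=np.concatenate(z_null_parts),
        z_tp_R=np.concatenate(z_r_parts),
        z_tp_C=np.concatenate(z_c_parts),
        config=cfg,
        n_degenerate=n_deg,
    )


def empirical_critical_values(
    z_null: Sequence[float] | np.ndarray, alpha: float
) -> tuple[float, float]:
    """Critical values as empirical percentiles of the simulated null.

    Returns ``(crit_low, crit_high)`` = the alpha and (1-alpha) quantiles of
    the Z^P draws, using the linear-interpolation (type-7) quantile
    definition.  Preferred over N(0,1) quantiles because the finite-sample
    null can diverge from the normal approximation.
    """
    z_null = np.asarray(z_null, dtype=float)
    if z_null.size < 20:
        raise InputError(
            f"need at least 20 null draws for stable percentiles, got {z_null.size}"
        )
    if not 0 < alpha < 0.5:
        raise ParameterError(f"alpha must lie in (0, 0.5), got {alpha}")
    return (
        float(np.quantile(z_null, alpha)),
        float(np.quantile(z_null, 1.0 - alpha)),
    )


def estimate_beta(
    z_tp: Sequence[float] | np.ndarray, crit: float, side: str
) -> tuple[float, float]:
    """Type-II error from true-positive draws against one critical value.

    ``side="upper"`` (case-group members, rejected when Z > crit): beta is
    the fraction of draws below ``crit``.  ``side="lower"`` (reference-group
    members, rejected when Z < crit): the fraction above.  Returns
    ``(beta, mc_se)`` with the binomial Monte-Carlo standard error
    sqrt(beta*(1-beta)/n).
    """
    z_tp = np.asarray(z_tp, dtype=float)
    if z_tp.size == 0:
        raise InputError("no true-positive draws supplied")
    if side == "upper":
        beta = float(np.mean(z_tp < crit))
    elif side == "lower":
        beta = float(np.mean(z_tp > crit))
    else:
        raise ParameterError(f"side must be 'upper' or 'lower', got {side!r}")
    mc_se = math.sqrt(beta * (1.0 - beta) / z_tp.size)
    return beta, mc_se


def estimate_power(dists: ZDistributions) -> PowerEstimate:
    """Empirical critical values and per-group beta from simulated draws."""
    alpha = dists.config.alpha
    crit_low, crit_high = empirical_critical_values(dists.z_null, alpha)
    beta_c, se_c = estimate_beta(dists.z_tp_C, crit_high, side="upper")
    beta_r, se_r = estimate_beta(dists.z_tp_R, crit_low, side="lower")
    return PowerEstimate(
        beta_R=beta_r,
        beta_C=beta_c,
        crit_low=crit_low,
        crit_high=crit_high,
        alpha=alpha,
        mc_se_R=se_r,
        mc_se_C=se_c,
    )


def unequal_size_run(cfg: SimulationConfig) -> tuple[ZDistributions, PowerEstimate]:
    """Run one simulation and report per-group power separately.

    The machinery is identical for equal and unequal group sizes; this
    wrapper exists because the asymmetric case (e.g. n_R = 1000, n_C = 10)
    is the scenario where the per-group betas diverge: the larger group's
    members approach the null while the smaller group stays detectable.
    """
    dists = simulate_distributions(cfg)
    return dists, estimate_power(dists)


def density_curve(
    values: Sequence[float] | np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
    bandwidth: str | float = "auto",
    label: str = "",
) -> DensityCurve:
    """Gaussian kernel density estimate of a statistic's distribution.

    ``bandwidth="auto"`` applies Scott's rule; a positive float is used as
    the kernel standard deviation directly.  When ``grid`` is omitted, the
    curve is evaluated on 512 points spanning the data range extended by
    four bandwidths on each side, so it integrates to ~1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or values.std(ddof=1) == 0:
        raise InputError("need at least two distinct values for a density estimate")
    if bandwidth == "auto":
        kde = stats.gaussian_kde(values)  # Scott's rule
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ParameterError("bandwidth must be positive")
        kde = stats.gaussian_kde(values, bw_method=bw / values.std(ddof=1))
    h = float(kde.factor * values.std(ddof=1))
    if grid is None:
        grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, 512)
    else:
        grid = np.asarray(grid, dtype=float)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h, label=label)


def power_grid(
    n_values: Sequence[int],
    t_values: Sequence[int],
    pi1: float,
    pi2: float,
    alpha: float = 0.05,
    seed: int = 0,
    n_null_draws: int = DEFAULT_N_DRAWS,
    n_tp_draws: int = DEFAULT_N_DRAWS,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Sweep beta over an (n, t) grid with n_R = n_C = n.

    One row per (n, t) combination, in deterministic order, each cell on its
    own named substream of ``seed`` so the grid shape never changes any
    cell's draws.  Cells that fail (e.g. all draws degenerate) are flagged
    rather than aborting the sweep.  Returns a DataFrame with columns
    n, t, pi1, pi2, alpha, beta_R, beta_C, mc_se_R, mc_se_C, crit_low,
    crit_high, n_draws, failures, failed, seed.
    """
    if len(n_values) == 0 or len(t_values) == 0:
        raise ParameterError("grid axes must be non-empty")
    records = []
    for n in n_values:
        for t in t_values:
            cell_seed = _substream(seed, f"grid-cell-n{n}-t{t}").integers(0, 2**31)
            row: dict = {
                "n": int(n),
                "t": int(t),
                "pi1": float(pi1),
                "pi2": float(pi2),
                "alpha": float(alpha),
                "n_draws": int(n_tp_draws * n_reps),
                "seed": int(seed),
            }
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SmallOtuCountWarning)
                    cfg = SimulationConfig(
                        t=int(t),
                        n_R=int(n),
                        n_C=int(n),
                        pi1=pi1,
                        pi2=pi2,
                        alpha=alpha,
                        n_null_draws=n_null_draws,
                        n_tp_draws=n_tp_draws,
                        n_reps=n_reps,
                        seed=int(cell_seed),
                    )
                    dists, power = unequal_size_run(cfg)
                row.update(
                    beta_R=power.beta_R,
                    beta_C=power.beta_C,
                    mc_se_R=power.mc_se_R,
                    mc_se_C=power.mc_se_C,
                    crit_low=power.crit_low,
                    crit_high=power.crit_high,
                    failures=sum(dists.n_degenerate.values()),
                    failed=False,
                )
            except MicroprivacyError as exc:
                logger.error("grid cell (n=%d, t=%d) failed: %s", n, t, exc)
                row.update(
                    beta_R=np.nan,
                    beta_C=np.nan,
                    mc_se_R=np.nan,
                    mc_se_C=np.nan,
                    crit_low=np.nan,
                    crit_high=np.nan,
                    failures=-1,
                    failed=True,
                )
            records.append(row)
    columns = [
        "n", "t", "pi1", "pi2", "alpha", "beta_R", "beta_C", "mc_se_R",
        "mc_se_C", "crit_low", "crit_high", "n_draws", "failures", "failed",
        "seed",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


# ---------------------------------------------------------------------------
# file I/O: TSV profiles and summaries, draw tables, provenance
# ---------------------------------------------------------------------------


def write_profiles_tsv(
    path,
    matrix: SampleMatrix | np.ndarray,
    otu_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> None:
    """Write profiles as TSV: rows = individuals, columns = OTUs.

    First column is the sample id; the header row carries OTU ids.  Values
    may be binary or relative frequencies in [0, 1].
    """
    rows = matrix.rows if isinstance(matrix, SampleMatrix) else np.asarray(matrix)
    if rows.ndim != 2:
        raise InputError("profile matrix must be 2-D")
    n, t = rows.shape
    if otu_ids is None:
        otu_ids = default_otu_ids(t)
    if sample_ids is None:
        prefix = matrix.label if isinstance(matrix, SampleMatrix) else "S"
        sample_ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=otu_ids)
    df.to_csv(path, sep="\t")


def read_profiles_tsv(path) -> pd.DataFrame:
    """Read a profile matrix TSV (samples x OTUs, values in [0, 1])."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise InputError(f"{path}: no OTU columns found")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any((values < 0) | (values > 1)):
        bad = df.columns[np.argmax(~((values >= 0) & (values <= 1)).all(axis=0))]
        raise InputError(f"{path}: values outside [0, 1] (e.g. column {bad!r})")
    return df

def read_taxon_profile(
    path,
    sample_id: str | None = None,
    binarize_threshold: float | None = None,
) -> TaxonProfile:
    """Load one query profile from a profile TSV.

    Picks the row named ``sample_id`` (default: the first row).  Binary
    values are taken as-is; relative frequencies require
    ``binarize_threshold`` (presence iff frequency strictly above it).
    """
    df = read_profiles_tsv(path)
    if sample_id is None:
        row = df.iloc[0]
    else:
        if sample_id not in df.index:
            raise InputError(f"{path}: sample id {sample_id!r} not found")
        row = df.loc[sample_id]
    values = row.to_numpy(dtype=float)
    otu_ids = list(df.columns)
    if binarize_threshold is not None:
        return binarize(values, threshold=binarize_threshold, otu_ids=otu_ids)
    if not np.isin(values, (0.0, 1.0)).all():
        raise InputError(
            f"{path}: profile {row.name!r} is not binary; pass a binarize threshold"
        )
    return TaxonProfile(y=values.astype(np.uint8), otu_ids=otu_ids)


def write_group_summary(path, summary: GroupSummary) -> None:
    """Write a group summary TSV with '#group=' / '#n=' metadata headers."""
    otu_ids = summary.otu_ids or default_otu_ids(summary.t)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#group={summary.label}\n")
        fh.write(f"#n={summary.n}\n")
        fh.write("otu_id\tfreq\n")
        for otu, f in zip(otu_ids, summary.freq):
            fh.write(f"{otu}\t{f:.10g}\n")


def read_group_summary(path) -> GroupSummary:
    """Read a group summary TSV written by :func:`write_group_summary`."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if "n" not in meta or "group" not in meta:
        raise InputError(f"{path}: missing '#group=' or '#n=' metadata header")
    if list(df.columns) != ["otu_id", "freq"]:
        raise InputError(f"{path}: expected columns otu_id, freq, got {list(df.columns)}")
    return GroupSummary(
        freq=df["freq"].to_numpy(dtype=float),
        n=int(meta["n"]),
        label=meta["group"],
        otu_ids=[str(x) for x in df["otu_id"]],
    )


def write_z_draws_tsv(path, dists: ZDistributions) -> None:
    """Write simulated statistic draws as a long TSV (label, z)."""
    frames = [
        pd.DataFrame({"label": lab, "z": arr})
        for lab, arr in (
            ("Z_P", dists.z_null),
            ("Z_R+", dists.z_tp_R),
            ("Z_C+", dists.z_tp_C),
        )
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_z_draws_tsv(path, label: str | None = None) -> np.ndarray:
    """Read statistic draws; optionally filter to one label (e.g. "Z_P")."""
    df = pd.read_csv(path, sep="\t")
    if "z" not in df.columns:
        raise InputError(f"{path}: expected a 'z' column")
    if label is not None and "label" in df.columns:
        df = df[df["label"] == label]
    if df.empty:
        raise InputError(f"{path}: no draws found" + (f" for label {label!r}" if label else ""))
    return df["z"].to_numpy(dtype=float)


def write_density_curve_tsv(path, curve: DensityCurve) -> None:
    pd.DataFrame({"z": curve.grid, "density": curve.density}).to_csv(
        path, sep="\t", index=False
    )


def write_power_grid_tsv(path, grid: pd.DataFrame) -> None:
    grid.to_csv(path, sep="\t", index=False)


def write_provenance(out_path, command: str, params: dict, seed: int | None) -> str:
    """Write a provenance record (resolved config, version, seed) next to an output.

    Returns the provenance file path.  Every CLI run that produces a file
    gets one, so any output can be regenerated from its record alone.
    """
    from . import __version__

    record = {
        "package": "microprivacy",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    prov_path = f"{out_path}.provenance.json"
    with open(prov_path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return prov_path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


# ---------------------------------------------------------------------------
# optional plotting (convenience layer; TSV tables are canonical)
# ---------------------------------------------------------------------------


def plot_density_panel(dists: ZDistributions, path) -> None:
    """Render null/true-positive density curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for values, label, color in (
        (dists.z_tp_R, r"$Z^{R+}$", "tab:green"),
        (dists.z_tp_C, r"$Z^{C+}$", "tab:red"),
        (dists.z_null, r"$Z^{P}$", "black"),
    ):
        curve = density_curve(values, label=label)
        ax.plot(curve.grid, curve.density, color=color, label=label)
    grid = np.linspace(-4, 4, 401)
    ax.plot(grid, stats.norm.pdf(grid), color="gray", lw=1, label="N(0, 1)")
    cfg = dists.config
    ax.set_title(
        f"t={cfg.t}, $n_R$={cfg.n_R}, $n_C$={cfg.n_C}, "
        f"Beta({cfg.pi1:g}, {cfg.pi2:g})"
    )
    ax.set_xlabel("Z")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_power_contour(grid: pd.DataFrame, path, which: str = "beta_C") -> None:
    """Render a log-log contour of beta over the (n, t) grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.pivot(index="n", columns="t", values=which)
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(
        pivot.columns.to_numpy(float),
        pivot.index.to_numpy(float),
        pivot.to_numpy(),
        levels=np.linspace(0, 1, 11),
        cmap="viridis_r",
    )
    fig.colorbar(cs, ax=ax, label=which)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("number of OTUs (t)")
    ax.set_ylabel("sample size (n)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
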