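"""Synthetic cohorts with planted subgraph structure.

Every downstream stage of the pipeline is exercised against cohorts whose
answer is known: a nonnegative subgraph basis W* (edges x k) is planted on
one or two cognitive systems per subgraph, per-subject expression
coefficients H* follow two-state (high/low) Markov chains, and region
time series or edge-time matrices realizing W* H* (plus noise) are
rendered from them.

The two-state chain separates the two quantities the analysis is about:
the high-state level sets expression *energy* while the toggle
probability sets switching, hence histogram *entropy*.  A toggle window
passes through a silent transition state (coefficient 0) with probability
``transition_silence_prob`` -- expression briefly collapses while the
subgraph reconfigures.  Besides being a realistic feature of transient
network expression, these near-zero windows make the planted
factorization identifiable (coefficient vectors approach the coordinate
axes), so the decomposition can in principle recover W* and H* exactly.
One subgraph (the "executive-like" subgraph, spanning two systems)
carries a group effect: in the adult group its high state is scaled by
``energy_ratio`` and its toggle probability is raised by
``adult_switching_increment``, so both planted energy and planted entropy
are larger in adults.  Default state levels (high 1.0, low 0.3), base
switching probability 0.1, adult increment 0.15 and silence probability
0.3 were fixed by a design-stage power analysis; see the methods note.

An optional motion confound adds ``slope * motion`` to every edge of a
subject's connectivity, with motion drawn at the group means reported for
developmental cohorts (children moving more than adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .dynamics import entropy_rows
from .systems import SystemPartition

__all__ = [
    "GroundTruth", "SyntheticCohort", "make_partition", "make_ground_truth",
    "render_connectivity", "render_bold", "attach_motion_confound",
    "make_behavior", "simulate_cohort", "CANONICAL_SYSTEMS",
]

CANONICAL_SYSTEMS = [
    "frontoparietal", "salience", "visual", "somatomotor", "default_mode",
    "cingulo_opercular", "dorsal_attention", "ventral_attention", "auditory",
    "memory", "subcortical", "cerebellar", "uncertain",
]

# chain levels and transition-silence rate fixed at design time
HIGH_STATE = 1.0
LOW_STATE = 0.3
TRANSITION_SILENCE_PROB = 0.3
# weak subgraph weight on off-support edges: functional connectivity has
# no exactly-zero edges, and a zero floor would interact pathologically
# with the clip-at-zero steps downstream
BACKGROUND_WEIGHT = 0.05


@dataclass
class GroundTruth:
    """Planted factorization and the parameters that generated it."""

    basis_true: np.ndarray            # (E, k) nonnegative subgraph basis W*
    coeffs_true: np.ndarray           # (S, k, T) nonnegative coefficients H*
    effect_subgraph: int              # 0-based index of the executive-like one
    energy_ratio: float
    switching_prob: float
    adult_switching_increment: float
    seed: int
    subgraph_supports: list = field(default_factory=list)  # system tuples
    node_loadings: np.ndarray | None = None                # (N, k)
    group_labels: np.ndarray | None = None
    partition: SystemPartition | None = None

    def __post_init__(self):
        if (self.basis_true < 0).any() or (self.coeffs_true < 0).any():
            raise ValueError("planted basis and coefficients must be >= 0")
        if not 0 <= self.effect_subgraph < self.coeffs_true.shape[1]:
            raise ValueError("effect_subgraph out of range")

    @property
    def n_subjects(self) -> int:
        return self.coeffs_true.shape[0]

    @property
    def k_true(self) -> int:
        return self.coeffs_true.shape[1]

    @property
    def n_windows(self) -> int:
        return self.coeffs_true.shape[2]


@dataclass
class SyntheticCohort:
    """A generated cohort: signals and/or connectivity plus covariates."""

    partition: SystemPartition
    group_labels: np.ndarray
    ground_truth: GroundTruth
    series: list | None = None          # per-subject (N, n_samples)
    connectivity: list | None = None    # per-subject (E, T)
    age: np.ndarray | None = None
    motion: np.ndarray | None = None
    behavior: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.group_labels)


def make_partition(n_regions: int, n_systems: int,
                   labels=None) -> SystemPartition:
    """Contiguous near-equal partition of regions into labeled systems."""
    if n_systems < 1 or n_systems > n_regions:
        raise ValueError("need 1 <= n_systems <= n_regions")
    if labels is None:
        if n_systems <= len(CANONICAL_SYSTEMS):
            labels = CANONICAL_SYSTEMS[:n_systems]
        else:
            labels = [f"system_{i + 1}" for i in range(n_systems)]
    node_to_system = np.sort(np.arange(n_regions) % n_systems)
    return SystemPartition(labels=list(labels), node_to_system=node_to_system)


def default_supports(n_systems: int, k_true: int) -> list[tuple[int, ...]]:
    """System supports for the planted subgraphs.

    The first subgraph (the effect subgraph) spans the pair of systems
    (0, 1) -- executive-like integration between two systems.  Further
    subgraphs are within-system, starting from system 2 so their edge sets
    stay disjoint from the cross-system effect subgraph; any remaining
    slots take the remaining system pairs.
    """
    singles = [(s,) for s in list(range(2, n_systems)) + [0, 1]]
    pairs = [p for p in combinations(range(n_systems), 2) if p != (0, 1)]
    supports = [(0, 1)] + singles + pairs
    if k_true > len(supports):
        raise ValueError(
            f"k_true={k_true} exceeds the {len(supports)} available "
            f"single/pair system supports of a {n_systems}-system partition")
    return supports[:k_true]


def _simulate_chains(rng: np.random.Generator, n_subjects: int, T: int,
                     p: np.ndarray, high: np.ndarray, low: np.ndarray,
                     silence_prob: float) -> np.ndarray:
    """(S, T) coefficient series of symmetric two-state toggle chains.

    ``p`` is the per-subject toggle probability.  A window in which a
    toggle occurred passes through the silent transition state (value 0)
    with probability ``silence_prob``; with no toggles the series is
    constant.
    """
    states = np.zeros((n_subjects, T), dtype=bool)
    states[:, 0] = rng.random(n_subjects) < 0.5
    toggles = rng.random((n_subjects, T)) < p[:, None]
    toggles[:, 0] = False
    for t in range(1, T):
        states[:, t] = states[:, t - 1] ^ toggles[:, t]
    values = np.where(states, high[:, None], low[:, None])
    silent = toggles & (rng.random((n_subjects, T)) < silence_prob)
    return np.where(silent, 0.0, values)


def make_ground_truth(n_regions: int, k_true: int,
                      partition: SystemPartition | None = None,
                      n_windows: int = 51, n_subjects: int = 40,
                      group_labels=None, energy_ratio: float = 1.5,
                      switching_prob: float = 0.1,
                      adult_switching_increment: float = 0.15,
                      seed: int = 0, subgraph_scales=None,
                      subgraph_switching=None,
                      transition_silence_prob: float = TRANSITION_SILENCE_PROB,
                      background_weight: float = BACKGROUND_WEIGHT,
                      ) -> GroundTruth:
    """Plant a subgraph basis and two-state coefficient chains.

    ``subgraph_scales`` multiplies both chain states of a subgraph (pure
    expression scale); ``subgraph_switching`` overrides the per-subgraph
    toggle probability.  Coupling the two across subgraphs produces the
    energy-entropy relationship; leaving scales flat decouples them.
    The group effect applies on top, to the effect subgraph only.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if energy_ratio <= 0:
        raise ValueError("energy_ratio must be > 0")
    if partition is None:
        partition = make_partition(n_regions, min(4, n_regions))
    if partition.n_nodes != n_regions:
        raise ValueError("partition size does not match n_regions")
    if group_labels is None:
        half = n_subjects // 2
        group_labels = np.array(["child"] * half
                                + ["adult"] * (n_subjects - half))
    group_labels = np.asarray(group_labels)
    is_adult = group_labels == "adult"

    rng = np.random.default_rng(seed)
    supports = default_supports(partition.n_systems, k_true)
    scales = (np.ones(k_true) if subgraph_scales is None
              else np.asarray(subgraph_scales, dtype=float))
    switching = (np.full(k_true, switching_prob) if subgraph_switching is None
                 else np.asarray(subgraph_switching, dtype=float))
    if scales.size != k_true or switching.size != k_true:
        raise ValueError("per-subgraph arrays must have length k_true")

    # basis: loadings on support nodes; cross-system edges for pair
    # supports, within-system edges for singletons
    E = n_regions * (n_regions - 1) // 2
    iu = np.triu_indices(n_regions, k=1)
    sys_of = partition.node_to_system
    loadings = np.zeros((n_regions, k_true))
    basis = np.full((E, k_true), background_weight, dtype=float)
    for m, sup in enumerate(supports):
        nodes = np.isin(sys_of, sup)
        loadings[nodes, m] = rng.uniform(0.7, 1.0, size=int(nodes.sum()))
        gi, gj = loadings[iu[0], m], loadings[iu[1], m]
        if len(sup) == 2:
            cross = ((sys_of[iu[0]] == sup[0]) & (sys_of[iu[1]] == sup[1])) | \
                    ((sys_of[iu[0]] == sup[1]) & (sys_of[iu[1]] == sup[0]))
            basis[cross, m] = (gi * gj)[cross]
        else:
            within = (sys_of[iu[0]] == sup[0]) & (sys_of[iu[1]] == sup[0])
            basis[within, m] = (gi * gj)[within]

    effect = 0
    coeffs = np.zeros((n_subjects, k_true, n_windows))
    for m in range(k_true):
        p = np.full(n_subjects, switching[m])
        high = np.full(n_subjects, HIGH_STATE * scales[m])
        low = np.full(n_subjects, LOW_STATE * scales[m])
        if m == effect:
            high[is_adult] *= energy_ratio
            p[is_adult] = np.clip(p[is_adult] + adult_switching_increment,
                                  0.0, 1.0)
        coeffs[:, m, :] = _simulate_chains(rng, n_subjects, n_windows, p,
                                           high, low, transition_silence_prob)

    return GroundTruth(basis_true=basis, coeffs_true=coeffs,
                       effect_subgraph=effect, energy_ratio=energy_ratio,
                       switching_prob=switching_prob,
                       adult_switching_increment=adult_switching_increment,
                       seed=seed, subgraph_supports=supports,
                       node_loadings=loadings, group_labels=group_labels,
                       partition=partition)


def render_connectivity(gt: GroundTruth, noise_sd: float,
                        seed: int | None = None) -> list[np.ndarray]:
    """Per-subject edge-time matrices W* H*_s + clipped Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    W = gt.basis_true
    if W.shape[1] != gt.coeffs_true.shape[1]:
        raise ValueError("basis and coefficients disagree on k")
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    out = []
    for s in range(gt.n_subjects):
        C = W @ gt.coeffs_true[s]
        if noise_sd > 0:
            C = C + rng.normal(0.0, noise_sd, size=C.shape)
        out.append(np.maximum(C, 0.0))
    return out


def _bandlimited_noise(rng: np.random.Generator, n: int, dt: float,
                       band: tuple[float, float], size) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (Hz) by FFT mask."""
    shape = (size, n) if np.isscalar(size) else (*size, n)
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("band contains no resolvable frequency")
    spec = np.fft.rfft(white, axis=-1)
    spec[..., ~mask] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def render_bold(gt: GroundTruth, tr_seconds: float = 3.0,
                band: tuple[float, float] = (0.02, 0.08),
                noise_sd: float = 1.0, seed: int | None = None,
                window_len: int = 20,
                overlap_frac: float = 0.9) -> SyntheticCohort:
    """Region time series whose windowed in-band coherence follows H*.

    Each planted subgraph drives one band-limited latent oscillator per
    subject, shared by the subgraph's support nodes; a region's series is
    the loading-weighted sum of its subgraphs' latents with per-window
    amplitude sqrt(coefficient) (linearly interpolated between window
    centers), plus white observation noise.  Pairs sharing a strongly
    expressed subgraph are therefore coherent in the band, and the
    coherence rises monotonically with the planted coefficient.
    """
    nyq = 0.5 / tr_seconds
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band must lie inside (0, {nyq}) Hz")
    step = int(round(window_len * (1 - overlap_frac)))
    n_samples = window_len + step * (gt.n_windows - 1)
    if n_samples < window_len:
        raise ValueError("fewer samples than one window")
    rng = np.random.default_rng(gt.seed + 2 if seed is None else seed)
    n_regions = gt.node_loadings.shape[0]
    S, k, T = gt.coeffs_true.shape

    centers = np.arange(T) * step + (window_len - 1) / 2.0
    t_grid = np.arange(n_samples)
    series = []
    for s in range(S):
        latents = _bandlimited_noise(rng, n_samples, tr_seconds, band, k)
        amp = np.vstack([
            np.interp(t_grid, centers, np.sqrt(gt.coeffs_true[s, m]))
            for m in range(k)
        ])                                           # (k, n_samples)
        signal = gt.node_loadings @ (amp * latents)  # (N, n_samples)
        noise = noise_sd * rng.standard_normal((n_regions, n_samples))
        series.append(signal + noise)

    age = _draw_ages(rng, gt.group_labels)
    return SyntheticCohort(partition=gt.partition,
                           group_labels=gt.group_labels,
                           ground_truth=gt, series=series, age=age)


def _draw_ages(rng: np.random.Generator, group_labels: np.ndarray) -> np.ndarray:
    """Ages uniform over the two study age brackets (years)."""
    age = np.empty(group_labels.size)
    child = group_labels == "child"
    age[child] = rng.uniform(8.17, 11.42, size=int(child.sum()))
    age[~child] = rng.uniform(19.58, 22.58, size=int((~child).sum()))
    return age


def attach_motion_confound(cohort: SyntheticCohort, slope: float,
                           seed: int | None = None) -> SyntheticCohort:
    """Add a known motion confound to the cohort's connectivity.

    Motion scalars are drawn nonnegative at group-dependent means (children
    0.078, adults 0.060, sd 0.015 -- children move more); every edge value
    gets ``slope * motion`` added, then clips at zero.
    """
    if cohort.connectivity is None:
        raise ValueError("cohort has no rendered connectivity to confound")
    rng = np.random.default_rng(
        cohort.ground_truth.seed + 3 if seed is None else seed)
    labels = np.asarray(cohort.group_labels)
    mean = np.where(labels == "child", 0.078, 0.060)
    motion = np.maximum(rng.normal(mean, 0.015), 0.0)
    conf = [np.maximum(C + slope * m, 0.0)
            for C, m in zip(cohort.connectivity, motion)]
    return replace(cohort, connectivity=conf, motion=motion)


def make_behavior(cohort: SyntheticCohort, flex_coef: float = 1.0,
                  age_coef: float = 0.05, noise_sd: float = 0.1,
                  seed: int | None = None) -> SyntheticCohort:
    """Behavior score = flexibility + age effect + noise.

    Flexibility is the histogram entropy of each subject's planted
    effect-subgraph coefficients; the age effect is linear in years.
    Exercises the age-residualized association test with a known signal.
    """
    gt = cohort.ground_truth
    rng = np.random.default_rng(gt.seed + 4 if seed is None else seed)
    flex = entropy_rows(gt.coeffs_true[:, gt.effect_subgraph, :])
    age = cohort.age
    if age is None:
        age = _draw_ages(rng, cohort.group_labels)
    behavior = (flex_coef * flex + age_coef * age
                + noise_sd * rng.standard_normal(flex.size))
    return replace(cohort, age=age, behavior=behavior)


def simulate_cohort(n_regions: int = 40, n_systems: int = 4, k_true: int = 4,
                    n_windows: int = 51, n_subjects: int = 40,
                    energy_ratio: float = 1.5, switching_prob: float = 0.1,
                    adult_switching_increment: float = 0.15,
                    noise_sd: float = 0.05, motion_slope: float = 0.0,
                    render: str = "connectivity", bold_noise_sd: float = 1.0,
                    tr_seconds: float = 3.0, seed: int = 0,
                    subgraph_scales=None,
                    subgraph_switching=None) -> SyntheticCohort:
    """One-call cohort generation used by the CLI and the test suite.

    ``render`` is "connectivity" (edge-time matrices from W* H* + noise),
    "bold" (region time series), or "both".
    """
    partition = make_partition(n_regions, n_systems)
    gt = make_ground_truth(
        n_regions, k_true, partition, n_windows=n_windows,
        n_subjects=n_subjects, energy_ratio=energy_ratio,
        switching_prob=switching_prob,
        adult_switching_increment=adult_switching_increment, seed=seed,
        subgraph_scales=subgraph_scales, subgraph_switching=subgraph_switching)
    rng = np.random.default_rng(seed + 5)
    cohort = SyntheticCohort(partition=partition,
                             group_labels=gt.group_labels, ground_truth=gt,
                             age=_draw_ages(rng, gt.group_labels))
    if render in ("bold", "both"):
        bold = render_bold(gt, tr_seconds=tr_seconds, noise_sd=bold_noise_sd)
        cohort = replace(cohort, series=bold.series)
    if render in ("connectivity", "both"):
        cohort = replace(cohort,
                         connectivity=render_connectivity(gt, noise_sd))
    if motion_slope != 0.0 and cohort.connectivity is not None:
        cohort = attach_motion_confound(cohort, motion_slope)
    elif cohort.connectivity is not None:
        # draw motion anyway so downstream regression always has a value
        cohort = attach_motion_confound(cohort, 0.0)
    cohort = make_behavior(cohort)
    return cohort
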