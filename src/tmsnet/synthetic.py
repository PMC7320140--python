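"""Synthetic cohorts with planted connectivity-behavior coupling.

The generator emulates the statistical structure the analysis assumes, not
anatomy. A cohort consists of per-subject voxel BOLD matrices for three
conditions (rest, post-sham task, post-TMS task), hemisphere labels, nuisance
series, a trial-level behavioral table, per-subject covariates, and a
reference seed-connectivity map computed from an independent long run.

Generative model
----------------
Voxels are grouped into equally sized regions, half per hemisphere. Each
voxel series is a loading mixture of band-limited (0.01-0.1 Hz) unit-variance
latent signals:

    x_v = sqrt(g2_r) G + sqrt(h2_r) H_hemi + sqrt(c_r) S_region
          + sqrt(1 - g2 - h2 - c) E_v + sigma_w W_v + nuisance + trend

so pairwise correlations are controlled by the variance shares: within-region
r = g2 + h2 + c, same-hemisphere cross-region r = g2 + h2, cross-hemisphere
r = g2. Anticorrelated region pairs share a sign-flipped specific latent,
producing negative links that exercise negative-link deletion downstream.

A few "informative" left-hemisphere regions have subject-varying
within-region coupling c_ik in the post-TMS condition. The behavioral TMS
effect of subject i on bilateral-target accuracy is planted as
g_i = sum_k w_k (c_ik - c0) + eps_i and mapped into the bilateral success
probabilities of the two stimulation conditions, so the expected per-subject
accuracy difference equals g_i. Sham-condition coupling of the same regions
varies independently of behavior, and sham/rest sessions additionally carry a
subject-level common mode in hemispheric coupling, so that the sham and
TMS-minus-sham feature tables are (near-)uninformative about behavior,
mirroring the condition pattern the analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import bandpass_chebyshev
from .preselect import SeedConnectivityMap

__all__ = ["CohortConfig", "SubjectTimeSeries", "Cohort", "generate_cohort",
           "generate_seed_map", "CONDITIONS"]

CONDITIONS = ("rest", "sham", "tms")
STIMULI = ("left", "right", "bilateral")
DIFFICULTIES = ("easy", "difficult")
N_BLOCKS = 4
TRIALS_PER_CELL = 32          # per stimulus x difficulty x stimulation condition

# variance shares of the latent mixture (see module docstring)
G2_SEED = 0.50        # seed region: strong global coupling
G2_INF = 0.12         # informative regions
G2_NORMAL = 0.035
G2_WEAK = 0.01        # weakly connected regions (dropped by the seed filter)
H2_NORMAL = 0.025
H2_WEAK = 0.01
C_BASE = 0.20         # baseline within-region coupling
C_INF_BASE = 0.45     # informative-region mean within-region coupling
C_SD = 0.20           # between-subject SD of informative-region coupling
C_SD_BASELINE = 0.30  # sham/rest informative-coupling SD (behavior-independent)
RHO_SAME = 0.6        # coupling correlation between same-sign effect regions
RHO_OPPOSITE = -0.5   # and between opposite-sign effect regions
H2_STATE_SD = 0.12    # sham/rest subject common mode on hemispheric coupling
SIGMA_WHITE = 0.25    # broadband measurement noise
NUISANCE_SCALE = 0.15
TREND_SD = 0.2
BASE_ACC = {"bilateral": 0.475, "left": (0.46, 0.49), "right": (0.68, 0.65)}
DIFFICULTY_SHIFT = 0.15


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions and planted-effect settings.

    Defaults are the study conditions used throughout: 20 subjects, 400
    voxels in 20 regions, 527 resting / 781 task volumes at TR = 1.5 s, four
    informative left-hemisphere regions with effect signs (-, -, -, +).
    """

    n_subjects: int = 20
    n_voxels: int = 400
    n_regions: int = 20
    n_timepoints_rest: int = 527
    n_timepoints_task: int = 781
    tr: float = 1.5
    n_informative: int = 4
    effect_weights: tuple = (-0.4, -0.4, -0.4, 0.4)
    noise_sd_behavior: float = 0.02
    nuisance_amplitude: float = 1.0
    anticorrelated_pairs: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_voxels", "n_regions",
                     "n_timepoints_rest", "n_timepoints_task"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even (half per hemisphere)")
        if self.n_voxels % self.n_regions != 0:
            raise ValueError("n_voxels must divide evenly into n_regions")
        if self.n_voxels // self.n_regions < 2:
            raise ValueError("each region needs at least 2 voxels")
        if self.n_informative > self.n_regions:
            raise ValueError("n_informative must not exceed n_regions")
        if len(self.effect_weights) != self.n_informative:
            raise ValueError(
                f"effect_weights has length {len(self.effect_weights)}, "
                f"expected n_informative = {self.n_informative}"
            )
        if self.noise_sd_behavior < 0:
            raise ValueError("noise_sd_behavior must be >= 0")
        if self.nuisance_amplitude < 0:
            raise ValueError("nuisance_amplitude must be >= 0")
        if self.anticorrelated_pairs < 0:
            raise ValueError("anticorrelated_pairs must be >= 0")
        n_left = self.n_regions // 2
        # region 0 is plain background; informative regions start at 1 and the
        # anticorrelated (weak) regions occupy the tail of each hemisphere
        if self.n_informative + self.anticorrelated_pairs > n_left - 1:
            raise ValueError(
                "not enough left-hemisphere regions for informative and "
                "anticorrelated roles"
            )

    @property
    def voxels_per_region(self) -> int:
        return self.n_voxels // self.n_regions

    @property
    def region_of_voxel(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_regions), self.voxels_per_region)

    @property
    def hemisphere(self) -> np.ndarray:
        n_left = self.n_regions // 2
        return np.where(self.region_of_voxel < n_left, "left", "right")

    @property
    def informative_regions(self) -> np.ndarray:
        # left-hemisphere regions, skipping region 0
        n_left = self.n_regions // 2
        k = min(self.n_informative, n_left - 1)
        regions = list(range(1, 1 + k))
        regions += list(range(n_left, n_left + self.n_informative - k))
        return np.array(regions[: self.n_informative])

    @property
    def seed_region(self) -> int:
        return self.n_regions // 2   # first right-hemisphere region

    @property
    def seed_index(self) -> int:
        return self.seed_region * self.voxels_per_region

    @property
    def weak_region_pairs(self) -> list[tuple[int, int]]:
        """(left, right) region pairs with sign-flipped shared latents."""
        n_left = self.n_regions // 2
        return [
            (n_left - 1 - i, self.n_regions - 1 - i)
            for i in range(self.anticorrelated_pairs)
        ]


@dataclass
class SubjectTimeSeries:
    """One subject/condition BOLD matrix with labels and nuisance series."""

    bold: np.ndarray           # voxels x T
    hemisphere: np.ndarray     # per-voxel {left, right}
    nuisance: np.ndarray       # T x 13, motion columns first
    condition: str
    subject_id: str

    def __post_init__(self):
        if self.bold.ndim != 2:
            raise ValueError("bold must be 2-d (voxels x timepoints)")
        if not np.all(np.isfinite(self.bold)):
            raise ValueError(f"non-finite BOLD values for {self.subject_id}")
        if len(self.hemisphere) != self.bold.shape[0]:
            raise ValueError(
                f"{self.subject_id}: hemisphere labels ({len(self.hemisphere)}) "
                f"do not match voxel count ({self.bold.shape[0]})"
            )
        if self.nuisance.ndim != 2 or self.nuisance.shape[1] != 13:
            raise ValueError(
                f"{self.subject_id}: nuisance matrix must have 13 columns "
                f"(6 motion + 4 WM + 3 CSF), got shape {self.nuisance.shape}"
            )
        if self.nuisance.shape[0] != self.bold.shape[1]:
            raise ValueError(
                f"{self.subject_id}: nuisance rows ({self.nuisance.shape[0]}) "
                f"do not match timepoints ({self.bold.shape[1]})"
            )
        if not np.all(np.isfinite(self.nuisance)):
            raise ValueError(f"non-finite nuisance values for {self.subject_id}")

    @property
    def motion(self) -> np.ndarray:
        return self.nuisance[:, :6]


@dataclass
class Cohort:
    """Generated cohort: time series, behavior, covariates, seed map, truth."""

    config: CohortConfig
    timeseries: dict            # subject_id -> {condition -> SubjectTimeSeries}
    behavior: pd.DataFrame
    covariates: pd.DataFrame
    seed_map: SeedConnectivityMap
    ground_truth: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.timeseries)


def _region_shares(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-region global (g2) and hemispheric (h2) variance shares."""
    g2 = np.full(config.n_regions, G2_NORMAL)
    h2 = np.full(config.n_regions, H2_NORMAL)
    g2[config.informative_regions] = G2_INF
    g2[config.seed_region] = G2_SEED
    for a, b in config.weak_region_pairs:
        g2[[a, b]] = G2_WEAK
        h2[[a, b]] = H2_WEAK
    return g2, h2


def _bandlimited(rng: np.random.Generator, n_series: int, t: int,
                 tr: float) -> np.ndarray:
    """Unit-variance noise with power concentrated in 0.01-0.1 Hz."""
    raw = rng.standard_normal((n_series, t))
    filt = bandpass_chebyshev(raw, tr, band=(0.01, 0.1))
    sd = filt.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _nuisance_series(rng: np.random.Generator, t: int, tr: float) -> np.ndarray:
    """T x 13 nuisance matrix: 6 motion (mm / rad), 4 WM, 3 CSF series."""
    trans = np.cumsum(rng.normal(0.0, 0.02, (t, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 4e-4, (t, 3)), axis=0)
    physio = (0.8 * _bandlimited(rng, 7, t, tr).T
              + 0.6 * np.cumsum(rng.normal(0.0, 0.03, (t, 7)), axis=0))
    return np.column_stack([trans, rot, physio])


def _compose_bold(rng: np.random.Generator, config: CohortConfig, t: int,
                  g2: np.ndarray, h2_eff: np.ndarray, c_region: np.ndarray,
                  nuisance: np.ndarray) -> np.ndarray:
    """One subject/condition voxel matrix from the latent mixture."""
    v = config.n_voxels
    region = config.region_of_voxel
    hemi_idx = (config.hemisphere == "right").astype(int)
    n_lat = 3 + config.n_regions
    latents = _bandlimited(rng, n_lat, t, config.tr)
    glob, hemis, specific = latents[0], latents[1:3], latents[3:]
    for a, b in config.weak_region_pairs:
        specific[b] = -specific[a]
    e_band = _bandlimited(rng, v, t, config.tr)
    white = rng.standard_normal((v, t))

    g2v = g2[region]
    h2v = h2_eff[region]
    cv = c_region[region]
    resid = np.clip(1.0 - g2v - h2v - cv, 0.02, None)
    bold = (np.sqrt(g2v)[:, None] * glob[None, :]
            + np.sqrt(h2v)[:, None] * hemis[hemi_idx]
            + np.sqrt(cv)[:, None] * specific[region]
            + np.sqrt(resid)[:, None] * e_band
            + SIGMA_WHITE * white)
    # additive nuisance contamination (linear in the recorded columns, so the
    # cleaning GLM can remove it exactly) and a linear trend
    znuis = nuisance - nuisance.mean(axis=0)
    sd = znuis.std(axis=0)
    znuis = znuis / np.where(sd > 0, sd, 1.0)
    w = rng.normal(0.0, NUISANCE_SCALE * config.nuisance_amplitude, (v, 13))
    bold += w @ znuis.T
    slope = rng.normal(0.0, TREND_SD, v)
    bold += slope[:, None] * np.linspace(-1.0, 1.0, t)[None, :]
    return bold


def _coupling_correlation(weights: np.ndarray) -> np.ndarray:
    """Between-region correlation of the informative coupling draws.

    Same-sign effect regions covary positively (0.6), opposite-sign regions
    negatively (-0.5), so each region's coupling carries a strong marginal
    association with the summed behavioral effect - the regime in which a
    consistent multi-region selection is identifiable at small N. Shrunk
    toward identity if the sign pattern makes the matrix indefinite.
    """
    signs = np.where(np.asarray(weights, dtype=float) >= 0, 1.0, -1.0)
    same = signs[:, None] == signs[None, :]
    r = np.where(same, RHO_SAME, RHO_OPPOSITE)
    np.fill_diagonal(r, 1.0)
    for _ in range(20):
        if np.linalg.eigvalsh(r).min() > 1e-8:
            break
        off = ~np.eye(len(r), dtype=bool)
        r[off] *= 0.9
    return r


def _informative_coupling(rng: np.random.Generator, config: CohortConfig,
                          g2: np.ndarray, h2: np.ndarray,
                          sd: float, correlated: bool = True) -> np.ndarray:
    """Subject x informative-region coupling draws, clipped to the share budget.

    The post-TMS draws use the between-region correlation structure (see
    :func:`_coupling_correlation`); baseline sessions draw independently per
    region, emulating region-local state fluctuations that carry no joint
    structure.
    """
    inf = config.informative_regions
    hi = np.minimum(0.80, 0.96 - g2[inf] - h2[inf])
    z = rng.standard_normal((config.n_subjects, len(inf)))
    if correlated:
        r = _coupling_correlation(config.effect_weights)
        z = z @ np.linalg.cholesky(r).T
    draw = C_INF_BASE + sd * z
    return np.clip(draw, 0.05, hi[None, :])


def generate_seed_map(config: CohortConfig, t_ref: int = 12000) -> SeedConnectivityMap:
    """Reference seed-connectivity map from an independent long simulation.

    Emulates a seed map computed on a large independent dataset: one long run
    of the same latent mixture at baseline coupling, correlated voxel-by-voxel
    against the seed voxel (the first voxel of the seed region). The map is
    keyed to the cohort seed so it is reproducible but statistically
    independent of any subject's data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 977]))
    g2, h2 = _region_shares(config)
    c_region = np.full(config.n_regions, C_BASE)
    c_region[config.informative_regions] = C_INF_BASE
    nuis = _nuisance_series(rng, t_ref, config.tr)
    bold = _compose_bold(rng, config, t_ref, g2, h2, c_region, nuis * 0.0)
    seed_series = bold[config.seed_index]
    x = bold - bold.mean(axis=1, keepdims=True)
    s = seed_series - seed_series.mean()
    r = x @ s / (np.linalg.norm(x, axis=1) * np.linalg.norm(s))
    r[config.seed_index] = 1.0
    return SeedConnectivityMap(np.clip(r, -1.0, 1.0), config.seed_index)


def _behavior_tables(rng: np.random.Generator, config: CohortConfig,
                     subjects: list[str],
                     effect: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = config.n_subjects
    # draw all uniforms up front so outcomes couple monotonically to the
    # success probabilities under a fixed seed
    u = rng.random((n, 2, len(STIMULI), len(DIFFICULTIES), TRIALS_PER_CELL))
    rows = []
    block_of_trial = np.repeat(np.arange(1, N_BLOCKS + 1),
                               TRIALS_PER_CELL // N_BLOCKS)
    for i, sid in enumerate(subjects):
        for ci, cond in enumerate(("sham", "tms")):
            for si, stim in enumerate(STIMULI):
                for di, diff in enumerate(DIFFICULTIES):
                    if stim == "bilateral":
                        base = BASE_ACC["bilateral"]
                        p = base + (0.5 if cond == "tms" else -0.5) * effect[i]
                    else:
                        p = BASE_ACC[stim][ci]
                    p += DIFFICULTY_SHIFT if diff == "easy" else -DIFFICULTY_SHIFT
                    p = float(np.clip(p, 0.03, 0.97))
                    correct = (u[i, ci, si, di] < p).astype(int)
                    for trial in range(TRIALS_PER_CELL):
                        rows.append((sid, cond, int(block_of_trial[trial]),
                                     stim, diff, int(correct[trial])))
    behavior = pd.DataFrame(
        rows, columns=["subject_id", "tms_condition", "block", "stimulus",
                       "difficulty", "correct"])
    covariates = pd.DataFrame({
        "subject_id": subjects,
        "motor_threshold": np.round(
            np.clip(45.0 + 7.0 * rng.standard_normal(n), 30.0, 70.0), 1),
        "admin_order": ["tms_first" if i % 2 == 0 else "sham_first"
                        for i in range(n)],
    })
    return behavior, covariates


def generate_cohort(config: CohortConfig,
                    conditions: tuple[str, ...] = CONDITIONS) -> Cohort:
    """Generate a full synthetic cohort under ``config``.

    ``conditions`` may be restricted to a subset to save time when only some
    sessions are needed; the random stream consumed for each condition is
    independent of which others are generated, so the shared quantities
    (couplings, behavior, covariates, seed map) are identical across calls
    with the same config.
    """
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    root = np.random.SeedSequence([config.seed, 15485863])
    keys = {}
    streams = root.spawn(6)
    keys.update(zip(("couplings", "behavior", "rest", "sham", "tms", "state"),
                    streams))
    rng_c = np.random.default_rng(keys["couplings"])
    g2, h2 = _region_shares(config)
    inf = config.informative_regions
    weights = np.asarray(config.effect_weights, dtype=float)

    c_inf = {
        "tms": _informative_coupling(rng_c, config, g2, h2, C_SD),
        "sham": _informative_coupling(rng_c, config, g2, h2, C_SD_BASELINE,
                                      correlated=False),
        "rest": _informative_coupling(rng_c, config, g2, h2, C_SD_BASELINE,
                                      correlated=False),
    }
    eps = rng_c.normal(0.0, config.noise_sd_behavior, config.n_subjects)
    effect = (c_inf["tms"] - C_INF_BASE) @ weights + eps

    # subject-level common mode on hemispheric coupling in the baseline
    # sessions (behavior-independent state variability, one-sided so the
    # share budget stays valid)
    rng_s = np.random.default_rng(keys["state"])
    state = {
        "rest": np.abs(rng_s.normal(0.0, H2_STATE_SD, config.n_subjects)),
        "sham": np.abs(rng_s.normal(0.0, H2_STATE_SD, config.n_subjects)),
        "tms": np.zeros(config.n_subjects),
    }

    subjects = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    hemisphere = config.hemisphere
    timeseries: dict[str, dict] = {sid: {} for sid in subjects}
    for cond in conditions:
        rng = np.random.default_rng(keys[cond])
        t = (config.n_timepoints_rest if cond == "rest"
             else config.n_timepoints_task)
        for i, sid in enumerate(subjects):
            c_region = np.full(config.n_regions, C_BASE)
            c_region[inf] = c_inf[cond][i]
            h2_eff = h2.copy()
            strong = h2 > H2_WEAK
            h2_eff[strong] = np.clip(h2[strong] + state[cond][i], 0.005, 0.4)
            nuis = _nuisance_series(rng, t, config.tr)
            bold = _compose_bold(rng, config, t, g2, h2_eff, c_region, nuis)
            timeseries[sid][cond] = SubjectTimeSeries(
                bold=bold, hemisphere=hemisphere, nuisance=nuis,
                condition=cond, subject_id=sid)

    rng_b = np.random.default_rng(keys["behavior"])
    behavior, covariates = _behavior_tables(rng_b, config, subjects, effect)
    seed_map = generate_seed_map(config)

    vpr = config.voxels_per_region
    ground_truth = {
        "config": asdict(config),
        "informative_regions": inf.tolist(),
        "informative_voxels": [
            list(range(r * vpr, (r + 1) * vpr)) for r in inf
        ],
        "effect_weights": weights.tolist(),
        "coupling": {cond: c_inf[cond].tolist() for cond in c_inf},
        "coupling_base": C_INF_BASE,
        "behavioral_effect": effect.tolist(),
        "planted_linear_effect": ((c_inf["tms"] - C_INF_BASE) @ weights).tolist(),
        "seed_region": int(config.seed_region),
        "seed_index": int(config.seed_index),
        "subjects": subjects,
    }
    return Cohort(config, timeseries, behavior, covariates, seed_map,
                  ground_truth)
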