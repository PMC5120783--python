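"""Synthetic experience-sampling (ESM) data with severity-linked skew.

Generates long-format momentary-assessment datasets with the multilevel
structure typical of general-population ESM studies of mental states:
persons nested in (twin) families, up to ``n_days × beeps_per_day``
assessments per person, three states per beep — negative affect (NA, mean
of 5 Likert items), positive affect (PA, 4 items) and paranoia (PAR, a
single item), each on a 1–7 scale — plus one person-level severity score
(SCL-like, skewed, roughly 1–5).

The generative mechanism is a Gaussian latent VAR(1) per person-day,
discretized to Likert items through fixed thresholds.  This produces, on
purpose, the distributional signature that motivates the whole analysis:
NA and PAR are positively skewed with large floor masses, PA is close to
normal, and subgroup variances of NA/PAR grow with severity while PA's do
not.  The latent cross-lagged coefficient matrix can either be constant
across persons ("null" regime) or increase with latent severity
("staging" regime) via ``staging_gradient``.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = ("na", "pa", "par")
LIKERT_LEVELS = 7

__all__ = [
    "ConfigError",
    "SeverityShape",
    "GeneratorConfig",
    "EsmDataset",
    "generate_dataset",
    "likert_from_latent",
    "scale_score",
    "apply_validity_filter",
]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class SeverityShape:
    """Person-level severity (SCL-like) marginal: scaled lognormal.

    scl = 1 + scale * exp(log_sd * (t + noise)), capped at max_score,
    where t is the person's standard-normal latent severity with
    within-family correlation ``family_corr``.
    """

    scale: float = 0.30
    log_sd: float = 0.65
    noise_sd: float = 0.30
    family_corr: float = 0.30
    max_score: float = 5.0


def _default_cross_lag() -> np.ndarray:
    # order (na, pa, par); spectral radius ~ 0.36
    return np.array(
        [
            [0.30, -0.08, 0.08],
            [-0.08, 0.35, -0.04],
            [0.08, -0.04, 0.25],
        ]
    )


def _default_thresholds() -> dict[str, tuple[float, ...]]:
    # Calibrated once so that the default configuration reproduces the
    # qualitative Table-1-style pattern: NA floor ~2/3 of measurements,
    # PAR floor >0.9, PA near-normal around the scale midpoint.
    return {
        "na": (1.20, 2.05, 2.90, 3.75, 4.60, 5.45),
        "pa": (-2.85, -1.80, -0.95, 0.00, 1.00, 2.30),
        "par": (1.85, 2.50, 3.15, 3.80, 4.45, 5.10),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic ESM study.

    Defaults emulate the design of the motivating twin-family study:
    571 women, 10 beeps/day on 5 days (max 50 assessments), at least 17
    valid assessments required, skewed severity and floor-inflated NA/PAR.
    """

    n_persons: int = 571
    twin_fraction: float = 0.9
    n_days: int = 5
    beeps_per_day: int = 10
    response_prob: float = 0.85
    state_missing_prob: float = 0.005
    min_valid: int = 17
    item_counts: dict[str, int] = field(
        default_factory=lambda: {"na": 5, "pa": 4, "par": 1}
    )
    likert_levels: int = LIKERT_LEVELS
    severity_shape: SeverityShape = field(default_factory=SeverityShape)
    state_intercepts: dict[str, float] = field(
        default_factory=lambda: {"na": 0.0, "pa": 0.0, "par": 0.0}
    )
    cross_lag: np.ndarray = field(default_factory=_default_cross_lag)
    innovation_sd: dict[str, float] = field(
        default_factory=lambda: {"na": 1.0, "pa": 1.0, "par": 1.0}
    )
    severity_loading: dict[str, float] = field(
        default_factory=lambda: {"na": 0.75, "pa": -0.45, "par": 0.65}
    )
    severity_scale: dict[str, float] = field(
        default_factory=lambda: {"na": 0.0, "pa": 0.0, "par": 0.0}
    )
    staging_gradient: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    threshold_set: dict[str, tuple[float, ...]] = field(
        default_factory=_default_thresholds
    )
    item_noise_sd: float = 0.60
    family_intercept_sd: float = 0.25
    person_intercept_sd: float = 0.55
    person_slope_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_persons", "n_days", "beeps_per_day", "likert_levels"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if not (0.0 < self.response_prob <= 1.0):
            raise ConfigError("response_prob must lie in (0, 1]")
        if not (0.0 <= self.state_missing_prob < 1.0):
            raise ConfigError("state_missing_prob must lie in [0, 1)")
        if not (0.0 <= self.twin_fraction <= 1.0):
            raise ConfigError("twin_fraction must lie in [0, 1]")
        if self.min_valid < 0:
            raise ConfigError("min_valid must be non-negative")
        for state in STATES:
            if self.item_counts.get(state, 0) <= 0:
                raise ConfigError(f"item_counts[{state!r}] must be positive")
            thr = np.asarray(self.threshold_set[state], dtype=float)
            if thr.size != self.likert_levels - 1:
                raise ConfigError(
                    f"threshold_set[{state!r}] must have likert_levels-1 entries"
                )
            if np.any(np.diff(thr) <= 0):
                raise ConfigError(
                    f"threshold_set[{state!r}] must be strictly increasing"
                )
            if self.innovation_sd[state] <= 0:
                raise ConfigError(f"innovation_sd[{state!r}] must be positive")
        B = np.asarray(self.cross_lag, dtype=float)
        if B.shape != (3, 3):
            raise ConfigError("cross_lag must be a 3x3 matrix")
        if np.max(np.abs(np.linalg.eigvals(B))) >= 1.0:
            raise ConfigError(
                "cross_lag spectral radius must be < 1 (stationary process)"
            )
        if np.asarray(self.staging_gradient, dtype=float).shape != (3, 3):
            raise ConfigError("staging_gradient must be a 3x3 matrix")

    def digest(self) -> str:
        buf = io.StringIO()
        for key, value in sorted(self.__dict__.items()):
            buf.write(f"{key}={np.asarray(value) if hasattr(value, '__len__') else value!r};")
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


CSV_COLUMNS = ["family_id", "person_id", "day", "beep", "na", "pa", "par", "scl"]


@dataclass
class EsmDataset:
    """Long-format ESM table: one row per completed assessment.

    ``frame`` columns: family_id, person_id, day, beep, na, pa, par, scl.
    Scores are mean item scores in [1, 7] (NaN when a state was skipped);
    scl is constant within person.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame lacks columns {missing}")
        key = self.frame[["family_id", "person_id", "day", "beep"]]
        if key.duplicated().any():
            raise ValueError("duplicate (family, person, day, beep) rows")

    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def person_severity(self) -> pd.Series:
        """Person-level severity score (one value per person)."""
        return self.frame.groupby("person_id")["scl"].first()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def read_csv(cls, path) -> "EsmDataset":
        frame = pd.read_csv(path)
        return cls(frame=frame, provenance=str(path))


def likert_from_latent(latent_value: float, thresholds) -> int:
    """Map a latent value to a 1..k Likert rating via ordered cutpoints.

    rating = 1 + number of thresholds strictly below the latent value.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or np.any(np.diff(thr) <= 0):
        raise ConfigError("thresholds must be strictly increasing")
    return int(1 + np.sum(thr < latent_value))


def scale_score(item_ratings) -> float:
    """Mean item score of integer Likert ratings; lies in [1, likert max]."""
    ratings = np.asarray(item_ratings)
    if ratings.size == 0:
        raise ValueError("item_ratings must be non-empty")
    if not np.all((ratings >= 1) & (ratings <= LIKERT_LEVELS)):
        raise ValueError("ratings must lie in 1..7")
    return float(np.mean(ratings))


def _stationary_cov(B: np.ndarray, Q: np.ndarray, n_iter: int = 80) -> np.ndarray:
    """Batched fixed-point solve of Sigma = B Sigma B' + Q.

    B: (n, 3, 3); Q: (3, 3) diagonal. Converges geometrically since every
    B has spectral radius < 1.
    """
    sigma = np.broadcast_to(Q, B.shape).copy()
    for _ in range(n_iter):
        sigma = np.einsum("nij,njk,nlk->nil", B, sigma, B) + Q
    # enforce exact symmetry against accumulation error
    return 0.5 * (sigma + np.swapaxes(sigma, 1, 2))


def generate_dataset(config: GeneratorConfig) -> EsmDataset:
    """Draw one full synthetic ESM study from the latent VAR(1) model.

    Each person's three latent states follow, within each day,
    ``z_t = m_p + B_p (z_{t-1} - m_p) + eps_t`` started from the person's
    stationary distribution (days are independent runs; the lagged
    analysis never crosses days).  Latent values are discretized to
    Likert items through the configured thresholds and averaged into
    mean item scores.  Identical config (incl. seed) gives an identical
    dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    # --- family structure: twin pairs + singletons ---------------------
    n_pairs = int(round(n * config.twin_fraction / 2.0))
    n_pairs = min(n_pairs, n // 2)
    family_of_person = np.empty(n, dtype=int)
    family_of_person[: 2 * n_pairs] = np.repeat(np.arange(n_pairs), 2)
    family_of_person[2 * n_pairs :] = n_pairs + np.arange(n - 2 * n_pairs)
    n_families = n_pairs + (n - 2 * n_pairs)

    # --- person-level severity -----------------------------------------
    shape = config.severity_shape
    fam_sev = rng.standard_normal(n_families)
    t_person = (
        np.sqrt(shape.family_corr) * fam_sev[family_of_person]
        + np.sqrt(1.0 - shape.family_corr) * rng.standard_normal(n)
    )
    scl_noise = shape.noise_sd * rng.standard_normal(n)
    scl = 1.0 + shape.scale * np.exp(shape.log_sd * (t_person + scl_noise))
    scl = np.minimum(scl, shape.max_score)

    # --- person-level latent means and dynamics -------------------------
    intercepts = np.array([config.state_intercepts[s] for s in STATES])
    loadings = np.array([config.severity_loading[s] for s in STATES])
    fam_int = config.family_intercept_sd * rng.standard_normal((n_families, 3))
    pers_int = config.person_intercept_sd * rng.standard_normal((n, 3))
    means = intercepts + loadings * t_person[:, None] + fam_int[family_of_person] + pers_int

    B0 = np.asarray(config.cross_lag, dtype=float)
    grad = np.asarray(config.staging_gradient, dtype=float)
    slope_noise = config.person_slope_sd * rng.standard_normal((n, 3, 3))
    B = B0[None] + grad[None] * t_person[:, None, None] + slope_noise
    # keep every person's process stationary
    radii = np.max(np.abs(np.linalg.eigvals(B)), axis=1)
    too_big = radii >= 0.95
    if np.any(too_big):
        B[too_big] *= (0.95 / radii[too_big])[:, None, None]

    innov_sd = np.array([config.innovation_sd[s] for s in STATES])
    Q = np.diag(innov_sd**2)
    sigma0 = _stationary_cov(B, Q)
    chol0 = np.linalg.cholesky(sigma0 + 1e-10 * np.eye(3))

    # --- latent trajectories, all persons in lockstep -------------------
    # Each person's state deviations follow the shared-coupling VAR(1);
    # severity_scale multiplies the expressed amplitude per state
    # (variance grows with severity while the coupling stays constant).
    scale_load = np.array([config.severity_scale[s] for s in STATES])
    amplitude = np.exp(scale_load * t_person[:, None])
    latent = np.empty((n, config.n_days, config.beeps_per_day, 3))
    for day in range(config.n_days):
        dev = np.einsum("nij,nj->ni", chol0, rng.standard_normal((n, 3)))
        latent[:, day, 0] = means + amplitude * dev
        for t in range(1, config.beeps_per_day):
            eps = innov_sd * rng.standard_normal((n, 3))
            dev = np.einsum("nij,nj->ni", B, dev) + eps
            latent[:, day, t] = means + amplitude * dev

    # --- discretize to Likert items and average -------------------------
    scores = {}
    for k, state in enumerate(STATES):
        n_items = config.item_counts[state]
        thr = np.asarray(config.threshold_set[state], dtype=float)
        item_latent = (
            latent[..., k, None]
            + config.item_noise_sd * rng.standard_normal((n, config.n_days, config.beeps_per_day, n_items))
        )
        ratings = 1 + np.sum(thr < item_latent[..., None], axis=-1)
        scores[state] = ratings.mean(axis=-1).astype(float)

    # --- missingness -----------------------------------------------------
    completed = rng.random((n, config.n_days, config.beeps_per_day)) < config.response_prob
    if config.state_missing_prob > 0:
        state_present = (
            rng.random((n, config.n_days, config.beeps_per_day, 3))
            >= config.state_missing_prob
        )
    else:
        state_present = np.ones((n, config.n_days, config.beeps_per_day, 3), dtype=bool)
    # a completed beep must carry at least one state
    any_state = state_present.any(axis=-1)
    completed &= any_state

    p_idx, d_idx, b_idx = np.nonzero(completed)
    frame = pd.DataFrame(
        {
            "family_id": family_of_person[p_idx] + 1,
            "person_id": p_idx + 1,
            "day": d_idx + 1,
            "beep": b_idx + 1,
        }
    )
    for k, state in enumerate(STATES):
        vals = scores[state][p_idx, d_idx, b_idx]
        present = state_present[p_idx, d_idx, b_idx, k]
        frame[state] = np.where(present, vals, np.nan)
    frame["scl"] = scl[p_idx]
    frame = frame.sort_values(["family_id", "person_id", "day", "beep"]).reset_index(drop=True)
    return EsmDataset(frame=frame, provenance=f"generator:{config.digest()}")


def apply_validity_filter(dataset: EsmDataset, min_valid: int) -> tuple[EsmDataset, int]:
    """Drop persons with fewer than ``min_valid`` completed assessments.

    A completed assessment is a row carrying at least one of the three
    state scores.  Returns the filtered dataset and the number of persons
    removed.
    """
    if min_valid < 0:
        raise ValueError("min_valid must be non-negative")
    frame = dataset.frame
    if frame.empty:
        return EsmDataset(frame=frame.copy(), provenance=dataset.provenance), 0
    valid = frame[list(STATES)].notna().any(axis=1)
    counts = valid.groupby(frame["person_id"]).sum()
    keep = counts[counts >= min_valid].index
    removed = int(frame["person_id"].nunique() - len(keep))
    out = frame[frame["person_id"].isin(keep)].reset_index(drop=True)
    return EsmDataset(frame=out, provenance=dataset.provenance), removed
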