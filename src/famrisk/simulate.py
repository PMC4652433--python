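"""Seeded synthetic-data generators.

Two generators make every other module testable without any external data:

* :func:`gen_pedigree` draws random pedigrees with configurable per-role
  affection probabilities, a truncated-normal age-at-diagnosis
  distribution, and polyp/Lynch-spectrum flag probabilities.

* :func:`gen_study` emulates the usability study table: 90 participants
  assigned to two interface groups of 45 by a shuffled label pool, seven
  age bands with fixed counts, gaussian task times per group, 17
  Likert-scale satisfaction items generated from a one-factor latent model
  and discretised to 1..7, and item-level missingness injected into exactly
  21 participants.  Demographic marginals match the configuration exactly,
  not just in expectation.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ConfigError
from .pedigree import (
    DEFAULT_GROUP_CAP,
    GROUP_POOLS,
    CancerHistory,
    Pedigree,
    Relative,
    RelativeRole,
    UNIQUE_ROLES,
    validate,
)
from .stats import (
    AGE_BANDS,
    GROUPS,
    ITEM_COLUMNS,
    LIKERT_MAX,
    LIKERT_MIN,
    N_ITEMS,
    StudyDataset,
    WEB_USE_LEVELS,
)

__all__ = [
    "PedigreeSimConfig",
    "StudySimConfig",
    "gen_pedigree",
    "gen_study",
]


# ---------------------------------------------------------------------------
# Pedigree generator


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Configuration for random pedigrees.

    ``affection_prob`` is either a single probability applied to every
    role or a mapping role -> probability (roles absent from the mapping
    get 0).  Ages at diagnosis are drawn from a normal truncated to
    [age_min, age_max] and rounded to whole years; with probability
    ``1 - p_age_known`` the age is recorded as unknown.  Flag
    probabilities apply to affected relatives only.  Group-pool sizes
    (members asked about per pool) are drawn from ``group_size_probs``
    over 0..cap.
    """

    affection_prob: float | Mapping[RelativeRole, float] = 0.08
    age_mean: float = 62.0
    age_sd: float = 13.0
    age_min: int = 25
    age_max: int = 95
    p_age_known: float = 0.9
    p_polyps: float = 0.04
    p_other_cancers: float = 0.06
    p_multiple_crc: float = 0.03
    group_size_probs: tuple[float, ...] = (0.50, 0.20, 0.12, 0.08, 0.05, 0.03, 0.015, 0.005)
    group_cap: int = DEFAULT_GROUP_CAP
    seed: int = 0

    def __post_init__(self):
        probs = [self.p_age_known, self.p_polyps, self.p_other_cancers, self.p_multiple_crc]
        if isinstance(self.affection_prob, Mapping):
            probs += list(self.affection_prob.values())
        else:
            probs.append(self.affection_prob)
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability out of [0, 1]: {p}")
        if len(self.group_size_probs) != self.group_cap + 1:
            raise ConfigError(
                f"group_size_probs must have cap+1={self.group_cap + 1} entries"
            )
        if abs(sum(self.group_size_probs) - 1.0) > 1e-9:
            raise ConfigError("group_size_probs must sum to 1")
        if not (0 < self.age_min < self.age_max <= 120):
            raise ConfigError("age bounds must satisfy 0 < age_min < age_max <= 120")

    def prob_for(self, role: RelativeRole) -> float:
        if isinstance(self.affection_prob, Mapping):
            return float(self.affection_prob.get(role, 0.0))
        return float(self.affection_prob)


def _draw_age(rng: np.random.Generator, config: PedigreeSimConfig) -> int:
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    x = sps.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, random_state=rng)
    return int(np.clip(round(float(x)), config.age_min, config.age_max))


def _draw_history(rng: np.random.Generator, config: PedigreeSimConfig) -> CancerHistory:
    age = _draw_age(rng, config) if rng.random() < config.p_age_known else None
    return CancerHistory(
        affected=True,
        age_at_diagnosis=age,
        multiple_polyps=bool(rng.random() < config.p_polyps),
        other_related_cancers=bool(rng.random() < config.p_other_cancers),
        multiple_primary_crc=bool(rng.random() < config.p_multiple_crc),
    )


def gen_pedigree(config: PedigreeSimConfig | None = None) -> Pedigree:
    """Draw one random, validated pedigree (identical seed, identical pedigree).

    Unique roles are included iff an affection draw succeeds.  For each
    group pool a pool size is drawn, each potential member's role is chosen
    within the pool (aunt/uncle vs. their child for the side pools) and the
    member is included iff affected — matching the intake semantics, where
    only affected relatives are entered.
    """
    if config is None:
        config = PedigreeSimConfig()
    rng = np.random.default_rng(config.seed)
    relatives: list[Relative] = []
    for role in sorted(UNIQUE_ROLES, key=lambda r: r.value):
        if rng.random() < config.prob_for(role):
            relatives.append(Relative(role, 0, _draw_history(rng, config)))
    sizes = np.arange(config.group_cap + 1)
    for key in sorted(GROUP_POOLS):
        pool = GROUP_POOLS[key]
        k = int(rng.choice(sizes, p=config.group_size_probs))
        counters = {role: 0 for role in pool}
        for _ in range(k):
            role = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
            if rng.random() < config.prob_for(role):
                idx = counters[role]
                counters[role] += 1
                relatives.append(Relative(role, idx, _draw_history(rng, config)))
    ped = Pedigree(tuple(sorted(relatives, key=Relative.sort_key)))
    report = validate(ped, group_cap=config.group_cap)
    assert report.ok, report.violations
    return ped


# ---------------------------------------------------------------------------
# Study-table generator


@dataclass(frozen=True)
class StudySimConfig:
    """Configuration of the synthetic usability-study table.

    Defaults reproduce the study conditions: 90 participants split 45/45
    between the diagram and questionnaire interfaces; age-band counts
    (8, 9, 9, 29, 21, 9, 5); 41 male participants; web-use counts
    (11, 2, 7, 70) from least to most frequent; gaussian task times with
    the groups' published mean/SD; satisfaction totals with the groups'
    published mean/SD generated through a one-factor item model targeting
    a reliability (Cronbach's alpha) near 0.9; and exactly 21 participants
    with at least one missing item.
    """

    n_total: int = 90
    group_sizes: tuple[int, int] | None = None
    age_band_counts: tuple[int, ...] | None = None
    n_male: int | None = None
    web_use_counts: tuple[int, ...] | None = None
    task_time_diagram: tuple[float, float] = (89.2, 7.05)
    task_time_questionnaire: tuple[float, float] = (80.89, 5.19)
    satisfaction_diagram: tuple[float, float] = (101.12, 11.9)
    satisfaction_questionnaire: tuple[float, float] = (108.79, 9.08)
    alpha_target: float = 0.9
    satisfaction_skew: float = 0.0
    n_missing_participants: int | None = None
    max_missing_per_participant: int = 3
    seed: int = 0

    # reference study conditions (n = 90) the derived counts are scaled from
    _REF_N = 90
    _REF_AGE_BANDS = (8, 9, 9, 29, 21, 9, 5)
    _REF_WEB_USE = (11, 2, 7, 70)
    _REF_MALE = 41
    _REF_MISSING = 21

    @staticmethod
    def _scale_counts(ref: tuple[int, ...], ref_n: int, n: int) -> tuple[int, ...]:
        """Scale reference counts to n by largest remainder (sums exactly to n)."""
        quotas = np.array(ref, dtype=float) * n / ref_n
        counts = np.floor(quotas).astype(int)
        remainder = n - counts.sum()
        order = np.argsort(-(quotas - counts))
        counts[order[:remainder]] += 1
        return tuple(int(c) for c in counts)

    def __post_init__(self):
        n = self.n_total
        if self.group_sizes is None:
            object.__setattr__(self, "group_sizes", (n // 2, n - n // 2))
        if self.age_band_counts is None:
            object.__setattr__(
                self, "age_band_counts", self._scale_counts(self._REF_AGE_BANDS, self._REF_N, n)
            )
        if self.web_use_counts is None:
            object.__setattr__(
                self, "web_use_counts", self._scale_counts(self._REF_WEB_USE, self._REF_N, n)
            )
        if self.n_male is None:
            object.__setattr__(self, "n_male", round(self._REF_MALE * n / self._REF_N))
        if self.n_missing_participants is None:
            object.__setattr__(
                self, "n_missing_participants", round(self._REF_MISSING * n / self._REF_N)
            )
        if sum(self.group_sizes) != self.n_total:
            raise ConfigError(
                f"group sizes {self.group_sizes} must sum to n_total={self.n_total}"
            )
        if len(self.age_band_counts) != len(AGE_BANDS):
            raise ConfigError(f"age_band_counts must have {len(AGE_BANDS)} entries")
        if sum(self.age_band_counts) != self.n_total:
            raise ConfigError(
                f"age-band counts {self.age_band_counts} must sum to n_total={self.n_total}"
            )
        if len(self.web_use_counts) != len(WEB_USE_LEVELS):
            raise ConfigError(f"web_use_counts must have {len(WEB_USE_LEVELS)} entries")
        if sum(self.web_use_counts) != self.n_total:
            raise ConfigError("web-use counts must sum to n_total")
        if not (0 <= self.n_male <= self.n_total):
            raise ConfigError("n_male out of range")
        if not (0 <= self.n_missing_participants <= self.n_total):
            raise ConfigError("n_missing_participants out of range")
        if not (0.0 < self.alpha_target < 1.0):
            raise ConfigError("alpha_target must be in (0, 1)")
        for label, (mean, sd) in (
            ("task_time_diagram", self.task_time_diagram),
            ("task_time_questionnaire", self.task_time_questionnaire),
            ("satisfaction_diagram", self.satisfaction_diagram),
            ("satisfaction_questionnaire", self.satisfaction_questionnaire),
        ):
            if sd <= 0:
                raise ConfigError(f"{label}: SD must be positive")
        lo, hi = N_ITEMS * LIKERT_MIN, N_ITEMS * LIKERT_MAX
        for label, (mean, _) in (
            ("satisfaction_diagram", self.satisfaction_diagram),
            ("satisfaction_questionnaire", self.satisfaction_questionnaire),
        ):
            if not (lo < mean < hi):
                raise ConfigError(f"{label}: mean {mean} outside the attainable ({lo}, {hi})")


def _item_model(total_mean: float, total_sd: float, alpha_target: float):
    """Solve the one-factor item model for a target total mean/SD and alpha.

    For k parallel items with loading lam and noise sd sig_e, the average
    inter-item correlation is r = lam^2/(lam^2+sig_e^2) and
    alpha = k r / (1 + (k-1) r).  The latent per-item mean is calibrated by
    root-finding so that the *discretised* (rounded, clipped to 1..7) items
    hit total_mean / k in expectation.
    """
    k = N_ITEMS
    r = alpha_target / (k - alpha_target * (k - 1))
    item_var = total_sd**2 / (k * (1.0 + (k - 1) * r))
    lam = float(np.sqrt(r * item_var))
    sig_e = float(np.sqrt((1.0 - r) * item_var))
    marg_sd = float(np.sqrt(item_var))

    cats = np.arange(LIKERT_MIN, LIKERT_MAX + 1)

    def discretised_mean(mu: float) -> float:
        upper = np.where(cats == LIKERT_MAX, np.inf, cats + 0.5)
        lower = np.where(cats == LIKERT_MIN, -np.inf, cats - 0.5)
        probs = sps.norm.cdf(upper, mu, marg_sd) - sps.norm.cdf(lower, mu, marg_sd)
        return float((cats * probs).sum())

    target = total_mean / k
    mu = optimize.brentq(
        lambda m: discretised_mean(m) - target, LIKERT_MIN - 6.0, LIKERT_MAX + 6.0
    )
    return float(mu), lam, sig_e


def _gen_items(
    rng: np.random.Generator, n: int, total_mean: float, total_sd: float, config: StudySimConfig
) -> np.ndarray:
    mu, lam, sig_e = _item_model(total_mean, total_sd, config.alpha_target)
    if config.satisfaction_skew != 0.0:
        a = config.satisfaction_skew
        f = sps.skewnorm.rvs(a, size=n, random_state=rng)
        f = (f - sps.skewnorm.mean(a)) / sps.skewnorm.std(a)
    else:
        f = rng.standard_normal(n)
    eps = rng.standard_normal((n, N_ITEMS))
    latent = mu + lam * f[:, None] + sig_e * eps
    return np.clip(np.rint(latent), LIKERT_MIN, LIKERT_MAX)


def gen_study(config: StudySimConfig | None = None) -> StudyDataset:
    """Generate one synthetic usability-study dataset.

    Demographics are allocated deterministically so that the marginal
    counts match the configuration exactly; interface groups are assigned
    by drawing from a seeded, shuffled pool of prepared group labels (the
    2x45 label-draw scheme); task times are gaussian per group; the 17
    satisfaction items come from the calibrated one-factor model; and
    exactly ``n_missing_participants`` rows receive 1..max missing items.
    """
    if config is None:
        config = StudySimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_total

    # deterministic demographic allocation (exact marginals)
    age_band = np.repeat(AGE_BANDS, config.age_band_counts)
    gender = np.array(["male"] * config.n_male + ["female"] * (n - config.n_male))
    web_use = np.repeat(WEB_USE_LEVELS, config.web_use_counts)
    rng.shuffle(gender)
    rng.shuffle(web_use)

    # label-pool group assignment
    labels = np.repeat(GROUPS, config.group_sizes)
    rng.shuffle(labels)

    task_time = np.empty(n)
    items = np.empty((n, N_ITEMS))
    params = {
        "diagram": (config.task_time_diagram, config.satisfaction_diagram),
        "questionnaire": (config.task_time_questionnaire, config.satisfaction_questionnaire),
    }
    for group in GROUPS:
        idx = np.where(labels == group)[0]
        (tt_mean, tt_sd), (sat_mean, sat_sd) = params[group]
        task_time[idx] = rng.normal(tt_mean, tt_sd, size=len(idx))
        items[idx] = _gen_items(rng, len(idx), sat_mean, sat_sd, config)

    items = items.astype(float)
    if config.n_missing_participants:
        rows = rng.choice(n, size=config.n_missing_participants, replace=False)
        for i in rows:
            n_miss = int(rng.integers(1, config.max_missing_per_participant + 1))
            cols = rng.choice(N_ITEMS, size=n_miss, replace=False)
            items[i, cols] = np.nan

    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "group": labels,
            "gender": gender,
            "age_band": age_band,
            "web_use": web_use,
            "task_time_s": np.round(task_time, 2),
        }
    )
    for j, col in enumerate(ITEM_COLUMNS):
        frame[col] = items[:, j]
    return StudyDataset(frame)
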