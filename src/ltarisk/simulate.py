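"""Synthetic two-wave cohort generator.

Forward-simulates the data-generating process the latent transition model
assumes: a baseline latent risk class, class-conditionally independent
3-category indicators, a per-arm Markov transition to the follow-up class,
the same measurement model at both waves (measurement invariance), and
class-by-arm-dependent loss to follow-up.  The default configuration is
anchored at the published trial quantities (class mix, within-class item
percentages quoted in the text, the per-arm transition matrix, and the
differential attrition of the baseline high-risk class), so parameter
recovery on generated cohorts is a meaningful end-to-end check of every
downstream stage.

Categories are emitted as raw assessment responses (7-point Likert values,
partner counts) so that generated cohorts exercise the recoding stage
exactly like real data would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import recoding
from ._utils import MISSING

CLASS_LABELS = ("low", "equipment", "moderate", "high")
ARM_LABELS = ("control", "pei")

#: class-conditional item-response probabilities pi[k, j, c] in the item
#: order (syringe, cooker, cotton, water, divide, bleach, partners) and
#: class order (low, equipment, moderate, high).  Entries quoted in the
#: trial report: low-risk cooker (0.89, 0.11, 0); equipment cooker
#: (0.03, 0.57, 0.40) and no syringe sharing; moderate syringe
#: (0, 0.89, 0.11) with 29% always bleaching; high risk = frequent
#: equipment sharing, mixed syringe sharing, majority not bleaching.
#: Remaining cells are generator choices matching the qualitative class
#: descriptions (see docs/methods.md).
DEFAULT_PROFILES = np.array([
    # low risk
    [[1.00, 0.00, 0.00],
     [0.89, 0.11, 0.00],
     [0.92, 0.08, 0.00],
     [0.95, 0.05, 0.00],
     [0.75, 0.15, 0.10],
     [0.70, 0.10, 0.20],
     [0.90, 0.08, 0.02]],
    # equipment sharing
    [[1.00, 0.00, 0.00],
     [0.03, 0.57, 0.40],
     [0.20, 0.50, 0.30],
     [0.30, 0.45, 0.25],
     [0.40, 0.35, 0.25],
     [0.55, 0.20, 0.25],
     [0.85, 0.12, 0.03]],
    # moderate risk (low-frequency syringe sharing)
    [[0.00, 0.89, 0.11],
     [0.15, 0.55, 0.30],
     [0.25, 0.50, 0.25],
     [0.35, 0.45, 0.20],
     [0.35, 0.40, 0.25],
     [0.29, 0.33, 0.38],
     [0.10, 0.60, 0.30]],
    # high risk
    [[0.05, 0.45, 0.50],
     [0.02, 0.28, 0.70],
     [0.05, 0.35, 0.60],
     [0.10, 0.35, 0.55],
     [0.25, 0.30, 0.45],
     [0.12, 0.28, 0.60],
     [0.05, 0.35, 0.60]],
])

#: follow-up class | baseline class, control arm (rows/cols in CLASS_LABELS
#: order), from the published transition table
TAU_CONTROL = np.array([
    [0.87, 0.05, 0.03, 0.05],
    [0.71, 0.18, 0.07, 0.04],
    [0.61, 0.11, 0.22, 0.06],
    [0.37, 0.22, 0.16, 0.25],
])

#: same for the peer-education arm
TAU_PEI = np.array([
    [0.95, 0.00, 0.03, 0.02],
    [0.64, 0.26, 0.07, 0.03],
    [0.68, 0.06, 0.18, 0.08],
    [0.53, 0.18, 0.15, 0.14],
])

#: baseline class probabilities of the randomized trial cohort
TRIAL_LAMBDA = np.array([0.32, 0.23, 0.21, 0.24])

#: full baseline-sample class mix as printed (sums to 1.01; normalized here)
FULL_SAMPLE_LAMBDA = np.array([0.33, 0.22, 0.19, 0.27]) / 1.01

#: probability of missing the follow-up wave, by (class, arm); the
#: high-risk row reproduces the reported 13% (control) vs 4% (PEI)
DEFAULT_DROPOUT = np.array([
    [0.08, 0.08],
    [0.08, 0.08],
    [0.08, 0.08],
    [0.13, 0.04],
])


def _default_covariates() -> dict:
    # class-conditional covariate distributions loosely matched to the
    # published baseline characteristics table; exercise the regression
    # stage only
    return {
        "p_female": np.array([0.258, 0.357, 0.294, 0.418]),
        "age_mean": np.array([23.92, 23.67, 23.35, 22.92]),
        "age_sd": 3.4,
        "race_probs": np.array([
            [0.5858, 0.1464, 0.2081, 0.0597],
            [0.6845, 0.1042, 0.1667, 0.0446],
            [0.6955, 0.0900, 0.1488, 0.0657],
            [0.7067, 0.0721, 0.1707, 0.0505],
        ]),
        "site_probs": np.full((4, 5), 0.2),
        "p_homeless": np.array([0.414, 0.502, 0.464, 0.514]),
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n: int
    lambda0: np.ndarray
    profiles: np.ndarray                 # (K, 7, 3)
    tau: dict                            # arm label -> (K, K)
    dropout: np.ndarray                  # (K, n_arms)
    arm_prob: float = 0.5                # P(assigned to PEI | randomized)
    randomized_prob: float = 1.0         # P(randomized); <1 adds arm="none" rows
    dependence: float = 0.0              # within-class item dependence switch
    covariate_model: dict = field(default_factory=_default_covariates)
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.lambda0)

    def validate(self) -> None:
        lam = np.asarray(self.lambda0, dtype=float)
        if abs(lam.sum() - 1.0) > 1e-12 or (lam < 0).any():
            raise ValueError("lambda0 must be a probability vector summing to 1")
        prof = np.asarray(self.profiles, dtype=float)
        if prof.shape[0] != self.K or prof.shape[2] != 3:
            raise ValueError("profiles must have shape (K, J, 3)")
        if np.abs(prof.sum(axis=2) - 1.0).max() > 1e-12 or (prof < 0).any():
            raise ValueError("every profile row must sum to 1")
        for arm, t in self.tau.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (self.K, self.K):
                raise ValueError(f"tau[{arm}] must be K x K")
            if np.abs(t.sum(axis=1) - 1.0).max() > 1e-12 or (t < 0).any():
                raise ValueError(f"tau[{arm}] rows must sum to 1")
        drop = np.asarray(self.dropout, dtype=float)
        if drop.shape != (self.K, len(self.tau)):
            raise ValueError("dropout must have shape (K, n_arms)")
        if (drop < 0).any() or (drop > 1).any():
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if not 0.0 <= self.arm_prob <= 1.0 or not 0.0 <= self.randomized_prob <= 1.0:
            raise ValueError("arm_prob and randomized_prob must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated records plus the hidden truth used only by tests."""

    records: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def default_paper_config(n: int = 2000, seed: int = 0,
                         cohort: str = "trial") -> GeneratorConfig:
    """Generator configuration at the published values.

    ``cohort="trial"`` uses the randomized-cohort class mix (32/23/21/24%)
    with everyone randomized; ``cohort="baseline"`` uses the full-sample
    mix (33/22/19/27% as printed, normalized) and a 854/1569 randomization
    rate, for baseline-only analyses including the participation-bias test.
    """
    if cohort == "trial":
        lam, p_rand = TRIAL_LAMBDA, 1.0
    elif cohort == "baseline":
        lam, p_rand = FULL_SAMPLE_LAMBDA, 854.0 / 1569.0
    else:
        raise ValueError("cohort must be 'trial' or 'baseline'")
    cfg = GeneratorConfig(
        n=n,
        lambda0=lam.copy(),
        profiles=DEFAULT_PROFILES.copy(),
        tau={"control": TAU_CONTROL.copy(), "pei": TAU_PEI.copy()},
        dropout=DEFAULT_DROPOUT.copy(),
        arm_prob=0.5,
        randomized_prob=p_rand,
        seed=seed,
    )
    cfg.validate()
    return cfg


def smoothed_config(alpha: float = 0.15, **kwargs) -> GeneratorConfig:
    """Default config with profiles blended toward uniform.

    Replaces the structural zeros of the paper-anchored profiles with
    interior probabilities (pi' = (1-alpha) pi + alpha/3), keeping the
    qualitative class patterns.  Used for calibration studies whose
    asymptotic reference distributions require interior true parameters.
    """
    cfg = default_paper_config(**kwargs)
    prof = (1.0 - alpha) * cfg.profiles + alpha / 3.0
    return replace(cfg, profiles=prof / prof.sum(axis=2, keepdims=True))


def invariance_null_config(n: int, seed: int = 0) -> GeneratorConfig:
    """Two-class, time-invariant generator for level checks of the
    invariance likelihood-ratio test.

    All probabilities are interior and every item-response cell receives
    at least ~n/10 expected observations, so the chi-square reference for
    the invariance LRT is accurate at moderate n.  (With the 4-class
    default profiles the freed wave-2 cells see only tens of observations
    at n=1000 and the naive LRT is measurably liberal; see
    docs/methods.md.)
    """
    low = np.tile([0.50, 0.30, 0.20], (7, 1))
    high = np.tile([0.20, 0.30, 0.50], (7, 1))
    tau = np.array([[0.75, 0.25], [0.35, 0.65]])
    cfg = GeneratorConfig(
        n=n,
        lambda0=np.array([0.55, 0.45]),
        profiles=np.stack([low, high]),
        tau={"control": tau.copy(), "pei": tau.copy()},
        dropout=np.full((2, 2), 0.08),
        covariate_model={
            "p_female": np.array([0.3, 0.3]),
            "age_mean": np.array([23.0, 23.0]),
            "age_sd": 3.0,
            "race_probs": np.full((2, 4), 0.25),
            "site_probs": np.full((2, 5), 0.2),
            "p_homeless": np.array([0.4, 0.4]),
        },
        seed=seed,
    )
    cfg.validate()
    return cfg


def _draw_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw; probs is (N, C) row-stochastic."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum[:, :-1]).sum(axis=1)


def _draw_items(rng, profiles: np.ndarray, classes: np.ndarray,
                dependence: float = 0.0) -> np.ndarray:
    """Draw (N, J) item categories given classes.

    With ``dependence`` > 0, a per-subject shift flips a random fraction of
    items toward the subject's first-item draw, inducing mild within-class
    association (a misspecification switch for robustness studies).
    """
    n = classes.shape[0]
    J = profiles.shape[1]
    P = profiles[classes]  # (N, J, C)
    u = rng.random((n, J))
    cum = np.cumsum(P, axis=2)
    cats = (u[:, :, None] > cum[:, :, :-1]).sum(axis=2)
    if dependence > 0.0:
        flip = rng.random((n, J)) < dependence
        flip[:, 0] = False
        cats = np.where(flip, cats[:, [0]].repeat(J, axis=1), cats)
    return cats


def _categories_to_likert(rng, cats: np.ndarray, reversed_: bool) -> np.ndarray:
    """Map 3-category risk codes back to raw 1..7 responses.

    Draws a raw value uniformly inside the band the recoding collapses:
    0 -> 7 ("never"), 1 -> {5, 6}, 2 -> {1..4}; reverse-scored items are
    then flipped (raw -> 8 - raw) so recoding round-trips exactly.
    """
    raw = np.empty(cats.shape, dtype=np.int64)
    raw[cats == 0] = 7
    m1 = cats == 1
    raw[m1] = rng.integers(5, 7, size=int(m1.sum()))
    m2 = cats == 2
    raw[m2] = rng.integers(1, 5, size=int(m2.sum()))
    if reversed_:
        raw = 8 - raw
    return raw


def _categories_to_partners(rng, cats: np.ndarray) -> np.ndarray:
    out = cats.astype(np.int64).copy()
    m2 = cats == 2
    out[m2] = 2 + rng.geometric(0.6, size=int(m2.sum())) - 1
    return out


def _raw_items_frame(rng, cats: np.ndarray) -> dict:
    cols = {}
    for j, col in enumerate(recoding.LIKERT_COLUMNS):
        rev = recoding.ITEM_NAMES[j] in recoding.REVERSED_ITEMS
        cols[col] = _categories_to_likert(rng, cats[:, j], rev)
    cols[recoding.PARTNER_COLUMN] = _categories_to_partners(rng, cats[:, 6])
    return cols


def generate(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Simulate a cohort; a single seeded RNG stream drives all draws.

    Draw order (fixed contract): baseline class, randomization flag, arm,
    wave-1 categories, wave-2 class, wave-2 categories, dropout,
    covariates, raw-response jitter within each collapsed category.
    Dropout is applied after the wave-2 class draw and depends only on
    (baseline class, arm), so attrition is informative about class but,
    given class, carries no information about the items (MAR given class).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = config.n, config.K
    arms = list(config.tau)
    tau_arr = np.stack([np.asarray(config.tau[a], dtype=float) for a in arms])

    class1 = rng.choice(K, size=n, p=np.asarray(config.lambda0, dtype=float))
    randomized = rng.random(n) < config.randomized_prob
    arm_idx = np.where(rng.random(n) < config.arm_prob, 1, 0)
    arm_idx[~randomized] = -1

    cats1 = _draw_items(rng, config.profiles, class1, config.dependence)
    class2 = np.full(n, -1, dtype=np.int64)
    r = randomized
    class2[r] = _draw_categorical(rng, tau_arr[arm_idx[r], class1[r]])
    cats2 = np.full((n, 7), MISSING, dtype=np.int64)
    cats2[r] = _draw_items(rng, config.profiles, class2[r], config.dependence)

    drop_p = np.zeros(n)
    drop_p[r] = np.asarray(config.dropout, dtype=float)[class1[r], arm_idx[r]]
    dropped = rng.random(n) < drop_p
    dropped[~r] = True  # non-randomized have no follow-up record

    cm = config.covariate_model
    sex = np.where(rng.random(n) < cm["p_female"][class1], "female", "male")
    age = np.clip(rng.normal(cm["age_mean"][class1], cm["age_sd"]), 15.0, 30.0).round(1)
    race_idx = _draw_categorical(rng, cm["race_probs"][class1])
    site_idx = _draw_categorical(rng, cm["site_probs"][class1])
    homeless = rng.random(n) < cm["p_homeless"][class1]

    pid = np.array([f"P{i:06d}" for i in range(n)])
    arm_label = np.where(arm_idx == 1, "pei", np.where(arm_idx == 0, "control", "none"))
    base = {
        "participant_id": pid,
        "wave": "baseline",
        "arm": arm_label,
        **_raw_items_frame(rng, cats1),
        "sex": sex,
        "age": age,
        "race": np.array(recoding.RACES)[race_idx],
        "site": np.array(recoding.SITES)[site_idx],
        "homeless": homeless,
        "randomized": randomized,
        "returned_6m": ~dropped,
    }
    w1 = pd.DataFrame(base)

    ret = ~dropped
    items2 = _raw_items_frame(rng, cats2[ret])
    w2 = pd.DataFrame({
        "participant_id": pid[ret],
        "wave": "m6",
        "arm": arm_label[ret],
        **items2,
        "sex": sex[ret],
        "age": age[ret],
        "race": np.array(recoding.RACES)[race_idx[ret]],
        "site": np.array(recoding.SITES)[site_idx[ret]],
        "homeless": homeless[ret],
        "randomized": randomized[ret],
        "returned_6m": True,
    })
    records = pd.concat([w1, w2], ignore_index=True)

    truth = pd.DataFrame({
        "participant_id": pid,
        "arm": arm_label,
        "randomized": randomized,
        "class_w1": class1,
        "class_w2": class2,
        "dropped": dropped,
    })
    return SyntheticCohort(records=records, truth=truth, config=config)


def empirical_summary(cohort: SyntheticCohort) -> dict:
    """Truth-table summaries: class mix per wave, per-arm empirical
    transitions among retained participants, and dropout by class x arm."""
    t = cohort.truth
    K = cohort.config.K
    arms = list(cohort.config.tau)
    rand = t[t["randomized"]]
    props_w1 = np.bincount(rand["class_w1"], minlength=K) / len(rand)
    kept = rand[~rand["dropped"]]
    props_w2 = np.bincount(kept["class_w2"], minlength=K) / len(kept)

    transitions = {}
    for a in arms:
        sub = kept[kept["arm"] == a]
        tab = np.zeros((K, K))
        np.add.at(tab, (sub["class_w1"].to_numpy(), sub["class_w2"].to_numpy()), 1.0)
        rows = tab.sum(axis=1, keepdims=True)
        transitions[a] = np.divide(tab, rows, out=np.zeros_like(tab), where=rows > 0)

    dropout = np.zeros((K, len(arms)))
    for gi, a in enumerate(arms):
        sub = rand[rand["arm"] == a]
        for k in range(K):
            cell = sub[sub["class_w1"] == k]
            dropout[k, gi] = cell["dropped"].mean() if len(cell) else np.nan

    return {
        "class_props": pd.DataFrame({"baseline": props_w1, "m6": props_w2},
                                    index=list(CLASS_LABELS[:K])),
        "transitions": transitions,
        "dropout": pd.DataFrame(dropout, columns=arms, index=list(CLASS_LABELS[:K])),
    }


def two_wave_matrices(cohort_records: pd.DataFrame):
    """Build aligned wave-1/wave-2 indicator matrices for the trial analysis.

    Returns ``(X1, X2, arm)`` restricted to randomized participants;
    participants without a follow-up record get an all-missing wave-2 row
    (retained in the likelihood via marginalization).
    """
    rand = cohort_records[cohort_records["randomized"].astype(bool)]
    m1 = recoding.build_indicators(rand, "baseline")
    m6 = recoding.build_indicators(rand, "m6")
    pos = {p: i for i, p in enumerate(m6.participant_id)}
    X2 = np.full((m1.n, len(recoding.ITEM_NAMES)), MISSING, dtype=np.int64)
    for i, p in enumerate(m1.participant_id):
        j = pos.get(p)
        if j is not None:
            X2[i] = m6.values[j]
    base = rand[rand["wave"] == "baseline"]
    arm = base["arm"].to_numpy()
    return m1.values, X2, arm
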