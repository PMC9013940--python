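"""Cohort statistics and a synthetic school cohort generator.

The study population behind the simulation parameters is a single-school
junior-middle-school cohort (n = 234, 113 girls / 121 boys) measured in three
annual physical-fitness test rounds (November 2018/2019/2020).  The raw data
are not public; this module therefore provides

* the descriptive/inferential statistics used on such a cohort (prevalence
  reconstruction from printed percentages, prevalence change, two-proportion
  z-test, Pearson chi-square, Pearson correlation), and
* a synthetic cohort generator that reproduces the published per-gender,
  per-round overweight/obesity margins *exactly by construction*, so every
  statistic is testable without the original records.

BMI weight status is classified against a configurable gender- and age-specific
cutoff table (the national standard's 85th/95th BMI percentile cutoffs are not
printed in the source tables, so the defaults here are synthetic but realistic
values for Chinese 13-15 year olds).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "StudentRecord",
    "CutoffTable",
    "CohortConfig",
    "classify_weight_status",
    "reconstruct_counts",
    "prevalence_change",
    "two_proportion_z_test",
    "chi_square_test",
    "pearson_correlation",
    "generate_synthetic_cohort",
    "default_cutoff_table",
    "default_cohort_config",
    "cohort_prevalence",
    "write_cohort_csv",
    "read_cohort_csv",
    "stats_record",
]

FEMALE = "female"
MALE = "male"

WEIGHT_CATEGORIES = ("underweight", "normal", "overweight", "obese")
PF_CATEGORIES = ("excellent", "good", "fair", "fail")

#: Default study rounds (year.month labels of the three test waves).
ROUNDS = ("2018.11", "2019.11", "2020.11")


class ConfigurationError(ValueError):
    """A cutoff/cohort configuration is missing or infeasible."""


class ReconstructionError(ValueError):
    """A printed percentage cannot be mapped back to a unique integer count."""


@dataclass
class StudentRecord:
    """One student's gender, age and per-round BMI / fitness measurements."""

    student_id: str
    gender: str
    age: float
    bmi_by_round: dict[str, float] = field(default_factory=dict)
    pf_status_by_round: dict[str, str] = field(default_factory=dict)
    weight_status_by_round: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.gender not in (FEMALE, MALE):
            raise ValueError(f"unknown gender {self.gender!r}")
        for rnd, bmi in self.bmi_by_round.items():
            if not np.isfinite(bmi) or bmi <= 0:
                raise ValueError(f"non-positive/non-finite BMI {bmi} in round {rnd}")


@dataclass
class CutoffTable:
    """Gender- and age-band-specific BMI cutoffs (kg/m^2).

    ``entries`` maps gender -> list of bands; each band is a dict with keys
    ``min_age``, ``max_age`` (inclusive), ``overweight``, ``obese`` and an
    optional ``underweight``.
    """

    entries: dict[str, list[dict]]

    def lookup(self, gender: str, age: float) -> dict:
        for band in self.entries.get(gender, ()):
            if band["min_age"] <= age <= band["max_age"]:
                if not band["overweight"] < band["obese"]:
                    raise ConfigurationError(
                        f"overweight cutoff must be below obese cutoff for "
                        f"({gender}, {age})"
                    )
                return band
        raise ConfigurationError(f"no BMI cutoff entry for ({gender}, age {age})")

    @classmethod
    def from_dict(cls, data: dict) -> "CutoffTable":
        return cls(entries={g: list(bands) for g, bands in data.items()})


def default_cutoff_table() -> CutoffTable:
    """Synthetic default cutoffs for ages 13-15.

    The national standard's percentile tables are not reproduced here; these
    values sit at realistic 85th/95th BMI percentile positions for Chinese
    junior-middle-school students and are fully configurable.
    """
    return CutoffTable(
        entries={
            FEMALE: [
                {"min_age": 12.0, "max_age": 15.99, "overweight": 22.2, "obese": 25.2}
            ],
            MALE: [
                {"min_age": 12.0, "max_age": 15.99, "overweight": 22.6, "obese": 25.7}
            ],
        }
    )


def classify_weight_status(
    bmi: float, gender: str, age: float, cutoffs: CutoffTable
) -> str:
    """Classify a BMI value as underweight/normal/overweight/obese.

    A BMI exactly at a cutoff classifies into the *higher* category (>=),
    consistent with percentile-based cutoff definitions.
    """
    band = cutoffs.lookup(gender, age)
    if bmi >= band["obese"]:
        return "obese"
    if bmi >= band["overweight"]:
        return "overweight"
    under = band.get("underweight")
    if under is not None and bmi < under:
        return "underweight"
    return "normal"


def reconstruct_counts(prevalence_percent: float, n: int) -> int:
    """Recover the integer numerator behind a printed percentage.

    Returns the unique k in 0..n minimizing ``|100*k/n - prevalence_percent|``.
    Raises :class:`ReconstructionError` when two counts tie or when even the
    best candidate misses the printed value by more than half a count
    (``100 * 0.5 / n``), i.e. the percentage is inconsistent with n.
    """
    if not 0 <= prevalence_percent <= 100:
        raise ValueError("prevalence_percent outside [0, 100]")
    if n <= 0:
        raise ValueError("n must be positive")
    ks = np.arange(n + 1)
    diffs = np.abs(100.0 * ks / n - prevalence_percent)
    best = int(np.argmin(diffs))
    ties = np.flatnonzero(np.isclose(diffs, diffs[best], rtol=0, atol=1e-12))
    if len(ties) > 1:
        raise ReconstructionError(
            f"{prevalence_percent}% of {n} is equidistant from counts {ties.tolist()}"
        )
    if diffs[best] > 100.0 * 0.5 / n:
        raise ReconstructionError(
            f"{prevalence_percent}% is inconsistent with any count out of {n} "
            f"(best candidate {best} gives {100.0 * best / n:.4f}%)"
        )
    return best


def prevalence_change(count_a: int, count_b: int, n: int) -> float:
    """Change in prevalence, in percentage points: ``100*(count_b - count_a)/n``."""
    if n == 0:
        raise ValueError("n must be positive")
    if count_a > n or count_b > n:
        raise ValueError("counts cannot exceed n")
    return 100.0 * (count_b - count_a) / n


def two_proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    z is positive when group 1 has the larger proportion.  The pooled standard
    error degenerates when the pooled proportion is 0 or 1 (no variance); that
    case raises rather than returning an arbitrary statistic.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("counts must satisfy 0 <= k <= n with n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError(
            "degenerate variance: pooled proportion is 0 or 1; "
            "use an exact (binomial/permutation) test instead"
        )
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def chi_square_test(
    table, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected 2x2 variant.  A zero expected count (empty margin) raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("zero expected count (empty margin); chi-square undefined")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=correction)
    return float(stat), int(dof), float(p)


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Margins the synthetic cohort must reproduce.

    ``prevalence`` maps (gender, round) -> overweight/obesity proportion in
    [0, 1]; ``mean_bmi`` maps (gender, round) -> target mean BMI in kg/m^2.
    ``fitness_corr`` is the target Pearson correlation (in (-1, 0]) between
    final-round BMI and the latent fitness score used to derive PF categories.
    """

    n_total: int = 234
    n_female: int = 113
    rounds: tuple[str, ...] = ROUNDS
    prevalence: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_bmi: dict[tuple[str, str], float] = field(default_factory=dict)
    bmi_sd: float = 3.0
    fitness_corr: float = -0.589
    mean_age: float = 13.35
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_female <= self.n_total:
            raise ConfigurationError("n_female must be in [0, n_total]")
        if not -1 < self.fitness_corr <= 0:
            raise ConfigurationError("fitness_corr must lie in (-1, 0]")
        for key, prev in self.prevalence.items():
            if not 0 <= prev <= 1:
                raise ConfigurationError(f"prevalence {prev} for {key} outside [0,1]")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Margins of the study cohort (234 students, three annual rounds)."""
    prevalence = {
        (FEMALE, "2018.11"): 0.3186,
        (FEMALE, "2019.11"): 0.3186,
        (FEMALE, "2020.11"): 0.4071,
        (MALE, "2018.11"): 0.4462,
        (MALE, "2019.11"): 0.4545,
        (MALE, "2020.11"): 0.4711,
    }
    mean_bmi = {
        (FEMALE, "2018.11"): 20.62,
        (FEMALE, "2019.11"): 21.30,
        (FEMALE, "2020.11"): 22.59,
        (MALE, "2018.11"): 22.17,
        (MALE, "2019.11"): 22.54,
        (MALE, "2020.11"): 24.01,
    }
    return CohortConfig(prevalence=prevalence, mean_bmi=mean_bmi, seed=seed)


def _coerce_across_cutoff(
    values: np.ndarray,
    above: np.ndarray,
    cutoff: float,
    rng: np.random.Generator,
    lo: float = 10.0,
    hi: float = 45.0,
) -> np.ndarray:
    """Shift draws across ``cutoff`` so exactly ``above`` rows end up >= cutoff."""
    out = values.copy()
    wrong_low = above & (out < cutoff)
    wrong_high = ~above & (out >= cutoff)
    out[wrong_low] = np.minimum(cutoff + np.abs(rng.normal(0, 0.6, wrong_low.sum())), hi)
    out[wrong_high] = np.maximum(
        cutoff - 0.01 - np.abs(rng.normal(0, 0.6, wrong_high.sum())), lo
    )
    return out


def generate_synthetic_cohort(
    config: CohortConfig, cutoffs: CutoffTable | None = None
) -> list[StudentRecord]:
    """Generate a cohort whose per-(gender, round) status counts are exact.

    Students carry a persistent latent size propensity so overweight/obesity
    status is nested across rounds (the same students stay at the top of the
    BMI distribution).  BMI values are truncated-normal draws around the
    configured per-round means, then minimally shifted across the relevant
    cutoff so the reconstructed integer counts are met exactly.  The latent
    fitness score is an anticorrelated mixture of final-round BMI and noise;
    PF categories are quantile cuts of a noisy per-round fitness value.
    """
    config.validate()
    if cutoffs is None:
        cutoffs = default_cutoff_table()
    rng = np.random.default_rng(config.seed)

    genders = [FEMALE] * config.n_female + [MALE] * (config.n_total - config.n_female)
    ages = np.clip(rng.normal(config.mean_age, 0.3, config.n_total), 13.0, 14.0)
    records = [
        StudentRecord(student_id=f"S{i:04d}", gender=g, age=float(ages[i]))
        for i, g in enumerate(genders)
    ]

    for gender in (FEMALE, MALE):
        idx = np.array([i for i, g in enumerate(genders) if g == gender])
        if len(idx) == 0:
            continue
        n_g = len(idx)
        # persistent size propensity: rank order shared across rounds
        propensity = rng.normal(size=n_g)
        order = np.argsort(-propensity)  # largest first
        for rnd in config.rounds:
            prev = config.prevalence.get((gender, rnd))
            if prev is None:
                raise ConfigurationError(f"no prevalence target for ({gender}, {rnd})")
            k = reconstruct_counts(100.0 * prev, n_g)
            if k > n_g:
                raise ConfigurationError(
                    f"prevalence count {k} exceeds group size {n_g}"
                )
            mu = config.mean_bmi.get((gender, rnd), 21.5)
            band = cutoffs.lookup(gender, float(np.mean(ages[idx])))
            draws = np.clip(rng.normal(mu, config.bmi_sd, n_g), 10.0, 45.0)
            draws.sort()
            draws = draws[::-1]  # align big draws with big propensity
            above = np.zeros(n_g, dtype=bool)
            above[:k] = True
            draws = _coerce_across_cutoff(draws, above, band["overweight"], rng)
            # a third of the overweight/obese group is obese (combined margin
            # only is published); keep the obese subset at the very top
            k_ob = k // 3
            if k > 0:
                ob_mask = np.zeros(n_g, dtype=bool)
                ob_mask[:k_ob] = True
                top = draws[:k].copy()
                top = _coerce_across_cutoff(top, ob_mask[:k], band["obese"], rng,
                                            lo=band["overweight"])
                draws[:k] = top
            for rank_pos, student_pos in enumerate(order):
                rec = records[idx[student_pos]]
                bmi = float(draws[rank_pos])
                rec.bmi_by_round[rnd] = bmi
                rec.weight_status_by_round[rnd] = classify_weight_status(
                    bmi, gender, rec.age, cutoffs
                )

    # latent fitness score anticorrelated with final-round BMI
    final_round = config.rounds[-1]
    bmi_final = np.array([r.bmi_by_round[final_round] for r in records])
    z_bmi = (bmi_final - bmi_final.mean()) / bmi_final.std()
    rho = config.fitness_corr
    noise = rng.normal(size=config.n_total)
    fitness = rho * z_bmi + np.sqrt(1 - rho**2) * noise
    for rnd in config.rounds:
        noisy = fitness + rng.normal(0, 0.35, config.n_total)
        # quantile cuts: 15% excellent / 35% good / 30% fair / 20% fail
        q = np.quantile(noisy, [0.20, 0.50, 0.85])
        for rec, val in zip(records, noisy):
            if val >= q[2]:
                rec.pf_status_by_round[rnd] = "excellent"
            elif val >= q[1]:
                rec.pf_status_by_round[rnd] = "good"
            elif val >= q[0]:
                rec.pf_status_by_round[rnd] = "fair"
            else:
                rec.pf_status_by_round[rnd] = "fail"
    for rec in records:
        rec.latent_fitness = None  # not persisted; correlation checked via PF
    # attach the latent score for analyses that need it (not serialized)
    for rec, fit in zip(records, fitness):
        rec.latent_fitness = float(fit)
    return records


def cohort_prevalence(
    records: list[StudentRecord], gender: str, rnd: str
) -> tuple[int, int]:
    """(overweight-or-obese count, group size) for one gender and round."""
    group = [r for r in records if r.gender == gender]
    k = sum(
        1 for r in group if r.weight_status_by_round.get(rnd) in ("overweight", "obese")
    )
    return k, len(group)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort_csv(records: list[StudentRecord], path) -> None:
    rounds = sorted({rnd for r in records for rnd in r.bmi_by_round})
    fields = (
        ["student_id", "gender", "age"]
        + [f"bmi_{r}" for r in rounds]
        + [f"pf_{r}" for r in rounds]
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            row = {"student_id": rec.student_id, "gender": rec.gender,
                   "age": f"{rec.age:.2f}"}
            for rnd in rounds:
                row[f"bmi_{rnd}"] = f"{rec.bmi_by_round[rnd]:.3f}"
                row[f"pf_{rnd}"] = rec.pf_status_by_round[rnd]
            writer.writerow(row)


def read_cohort_csv(path, cutoffs: CutoffTable | None = None) -> list[StudentRecord]:
    if cutoffs is None:
        cutoffs = default_cutoff_table()
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rec = StudentRecord(
                student_id=row["student_id"],
                gender=row["gender"],
                age=float(row["age"]),
            )
            for key, val in row.items():
                if key.startswith("bmi_"):
                    rnd = key[4:]
                    rec.bmi_by_round[rnd] = float(val)
                    rec.weight_status_by_round[rnd] = classify_weight_status(
                        float(val), rec.gender, rec.age, cutoffs
                    )
                elif key.startswith("pf_"):
                    rec.pf_status_by_round[key[3:]] = val
            rec.validate()
            records.append(rec)
    return records


def stats_record(name: str, statistic: float, p: float, df=None, **inputs) -> dict:
    """One JSON-serializable test result."""
    rec = {"name": name, "statistic": statistic, "df": df, "p": p, "inputs": inputs}
    return json.loads(json.dumps(rec))  # ensure plain types
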