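"""Synthetic encounter data with the statistical structure the analysis assumes.

Generates three artefacts: an environmental covariate series (an AR1-style
climate index or a seasonal overdispersed resource count), an individual
metadata table carrying latent reaction-norm deviations, and a long-format
encounter table produced by a group-formation + imperfect-detection
observation process.

The generative chain: each survey, individuals are independently available;
available individuals are partitioned into groups by a sequential
preference-weighted assignment in which individual ``i``'s propensity to join
an existing group scales with ``exp(eta_it)`` times its community affinity to
the group, where::

    eta_it = b0 + bx*x_t + bs*male_i + bsx*male_i*x_t + u0_i + u1_i*x_t

so realized expected group size is non-decreasing in the linear predictor.
Each group member is then detected (photo-identified) independently with
``detection_prob``; groups with no detected member are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "EnvironmentalSeries",
    "simulate_environment",
    "simulate_population",
    "simulate_encounters",
    "simulate_dataset",
    "write_encounters",
    "write_metadata",
    "write_environment",
    "write_manifest",
]


@dataclass
class EnvironmentalSeries:
    """Monthly covariate series with a yearly aggregation rule.

    ``monthly`` has columns (year, month, value). ``yearly_agg`` is "mean"
    for index-like series and "sum" for count series (counts are summed
    within a calendar year).
    """

    monthly: pd.DataFrame
    kind: str  # "ar1_index" | "seasonal_count"
    yearly_agg: str  # "mean" | "sum"

    def yearly(self) -> pd.DataFrame:
        agg = self.monthly.groupby("year", as_index=False)["value"].agg(
            self.yearly_agg
        )
        return agg

    def monthly_lookup(self) -> dict[tuple[int, int], float]:
        return {
            (int(r.year), int(r.month)): float(r.value)
            for r in self.monthly.itertuples()
        }

    def yearly_lookup(self) -> dict[int, float]:
        return {int(r.year): float(r.value) for r in self.yearly().itertuples()}

    def value_for(self, year: int, month: int | None = None) -> float:
        if month is None:
            return self.yearly_lookup()[int(year)]
        return self.monthly_lookup()[(int(year), int(month))]


def _seasonal_profile(months: np.ndarray) -> np.ndarray:
    """Mid-summer peak, zero-mean over the 12 calendar months."""
    raw = np.cos(2 * np.pi * (months - 7) / 12.0)
    return raw - np.mean(np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12.0))


def simulate_ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR1 with unit marginal variance."""
    if not (-1.0 < rho < 1.0):
        raise ConfigurationError("AR1 autocorrelation must be in (-1, 1)")
    innov_sd = np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


def simulate_environment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> EnvironmentalSeries:
    """Generate the monthly environmental series for the simulated span."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])

    years = np.arange(config.first_year, config.first_year + config.n_years)
    grid = pd.DataFrame(
        [(y, m) for y in years for m in range(1, 13)], columns=["year", "month"]
    )

    if config.env_model == "ar1_index":
        values = simulate_ar1(len(grid), config.env_ar1_rho, rng)
        return EnvironmentalSeries(
            monthly=grid.assign(value=values), kind="ar1_index", yearly_agg="mean"
        )
    elif config.env_model == "seasonal_count":
        season = _seasonal_profile(grid["month"].to_numpy(float))
        mu = config.env_count_mean * np.exp(config.env_seasonal_amplitude * season)
        k = config.env_count_dispersion
        # gamma-Poisson mixture == negative binomial with mean mu, shape k
        values = rng.negative_binomial(k, k / (k + mu)).astype(float)
        return EnvironmentalSeries(
            monthly=grid.assign(value=values), kind="seasonal_count", yearly_agg="sum"
        )
    raise ConfigurationError(f"unknown env_model: {config.env_model!r}")


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw individuals: sex, birth year, latent (u0, u1), community label.

    ``sex`` is the observed label (may be "U"); ``sex_true`` drives the
    generative model. Latent reaction-norm deviations are simulation truth,
    withheld from estimation.
    """
    config.validate()
    if config.n_individuals < 2:
        raise ConfigurationError("need at least 2 individuals")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    n = config.n_individuals
    ids = [f"ID{i:04d}" for i in range(1, n + 1)]
    male = rng.random(n) < config.sex_ratio
    sex_true = np.where(male, "M", "F")
    sex_obs = sex_true.copy().astype(object)
    sex_obs[rng.random(n) < config.unknown_sex_frac] = "U"

    G = config.rn_covariance.as_matrix()
    if np.allclose(G, 0.0):
        u = np.zeros((n, 2))
    else:
        u = rng.multivariate_normal(np.zeros(2), G, size=n, method="svd")

    by_lo, by_hi = config.birth_year_range
    birth_year = rng.integers(by_lo, by_hi + 1, size=n).astype(float)
    birth_year[rng.random(n) < config.unknown_birth_year_frac] = np.nan

    community = rng.integers(0, config.n_communities, size=n)

    return pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex_obs,
            "sex_true": sex_true,
            "birth_year": birth_year,
            "u0": u[:, 0],
            "u1": u[:, 1],
            "community": community,
        }
    )


def _surveys_in_year(config: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = config.surveys_per_year
    if config.mean_surveys_per_year is None:
        return int(rng.integers(lo, hi + 1))
    return int(np.clip(rng.poisson(config.mean_surveys_per_year), lo, hi))


def _assign_groups(
    weights: np.ndarray,
    communities: np.ndarray,
    affinity_ratio: float,
    alpha: float,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Sequential preference-weighted group assignment.

    Individual ``i`` joins existing group ``g`` with probability proportional
    to ``weights[i] * mean community affinity to g``, or opens a new group
    with probability proportional to ``alpha``.
    """
    order = rng.permutation(len(weights))
    groups: list[list[int]] = []
    group_comm_counts: list[np.ndarray] = []  # per group: count per community
    n_comm = int(communities.max()) + 1 if len(communities) else 1
    for i in order:
        if not groups:
            groups.append([i])
            cc = np.zeros(n_comm)
            cc[communities[i]] += 1
            group_comm_counts.append(cc)
            continue
        sizes = np.array([c.sum() for c in group_comm_counts])
        same = np.array([c[communities[i]] for c in group_comm_counts])
        # mean affinity over members: within-community members weigh affinity_ratio
        aff = (same * affinity_ratio + (sizes - same)) / sizes
        join_w = weights[i] * aff
        probs = np.append(join_w, alpha)
        total = probs.sum()
        if not np.isfinite(total) or total <= 0:
            choice = len(groups)
        else:
            choice = rng.choice(len(probs), p=probs / total)
        if choice == len(groups):
            groups.append([i])
            cc = np.zeros(n_comm)
            cc[communities[i]] += 1
            group_comm_counts.append(cc)
        else:
            groups[choice].append(i)
            group_comm_counts[choice][communities[i]] += 1
    return groups


def simulate_encounters(
    config: SimulationConfig,
    env: EnvironmentalSeries,
    population: pd.DataFrame,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the observation process, yielding a long encounter table.

    Returns one row per (encounter, detected individual). With
    ``return_truth=True`` additionally returns a per-group truth table with
    true and detected group sizes.
    """
    config.validate()
    if population.empty:
        raise ConfigurationError("population is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    env_lookup = env.monthly_lookup()
    # standardize the monthly covariate over the active months so the latent
    # scale of eta does not depend on the covariate's raw units
    active_vals = np.array(
        [
            v
            for (y, m), v in env_lookup.items()
            if m in set(config.months_active)
        ]
    )
    mu, sd = active_vals.mean(), active_vals.std()
    if sd == 0:
        sd = 1.0

    fe = config.fixed_effects
    male = (population["sex_true"] == "M").to_numpy(float)
    u0 = population["u0"].to_numpy()
    u1 = population["u1"].to_numpy()
    ids = population["individual_id"].to_numpy()
    communities = population["community"].to_numpy()
    n = len(population)

    months_active = np.asarray(config.months_active)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    encounter_id = 0
    survey_id = 0
    for year in range(config.first_year, config.first_year + config.n_years):
        n_surveys = _surveys_in_year(config, rng)
        for _ in range(n_surveys):
            survey_id += 1
            month = int(months_active[rng.integers(len(months_active))])
            day = int(rng.integers(1, 29))
            key = (year, month)
            if key not in env_lookup:
                raise ConfigurationError(
                    f"environment series does not cover window {key}"
                )
            x = (env_lookup[key] - mu) / sd

            available = np.flatnonzero(rng.random(n) < config.presence_prob)
            if available.size == 0:
                continue
            eta = (
                fe.intercept
                + fe.env * x
                + fe.sex * male[available]
                + fe.sex_env * male[available] * x
                + u0[available]
                + u1[available] * x
            )
            weights = np.exp(np.clip(eta, -700.0, 30.0))
            groups = _assign_groups(
                weights,
                communities[available],
                config.community_affinity_ratio,
                config.group_concentration,
                rng,
            )
            for members in groups:
                members = available[np.asarray(members)]
                detected = members[rng.random(len(members)) < config.detection_prob]
                if return_truth:
                    truth_rows.append(
                        (survey_id, year, month, len(members), len(detected))
                    )
                if detected.size == 0:
                    continue
                encounter_id += 1
                for j in detected:
                    rows.append(
                        (encounter_id, survey_id, year, month, day, ids[j])
                    )

    encounters = pd.DataFrame(
        rows,
        columns=["encounter_id", "survey_id", "year", "month", "day", "individual_id"],
    )
    if return_truth:
        truth = pd.DataFrame(
            truth_rows,
            columns=["survey_id", "year", "month", "true_size", "detected_size"],
        )
        return encounters, truth
    return encounters


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, EnvironmentalSeries]:
    """Run the full generative chain from a single root seed.

    Every stochastic sub-stream (environment, population, encounters) is
    derived deterministically from ``config.seed``, so identical seeds give
    byte-identical outputs.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    env_ss, pop_ss, enc_ss = ss.spawn(3)
    env = simulate_environment(config, np.random.default_rng(env_ss))
    pop = simulate_population(config, np.random.default_rng(pop_ss))
    enc = simulate_encounters(config, env, pop, np.random.default_rng(enc_ss))
    return enc, pop, env


# ---------------------------------------------------------------------------
# writers


def write_encounters(encounters: pd.DataFrame, path: str) -> None:
    cols = ["encounter_id", "survey_id", "year", "month", "day", "individual_id"]
    encounters[cols].to_csv(path, index=False)


def write_metadata(population: pd.DataFrame, path: str) -> None:
    out = population[["individual_id", "sex", "birth_year"]].copy()
    out.to_csv(path, index=False)


def write_environment(env: EnvironmentalSeries, path: str) -> None:
    env.monthly.to_csv(path, index=False)


def write_manifest(config: SimulationConfig, path: str, extra: dict | None = None) -> None:
    doc = {"simulation": config.to_dict(), "seed": config.seed}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
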