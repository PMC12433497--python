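"""Seeded two-line feeding-trial generator built on explicit nutrient mass balance.

The generator draws, per bird, the observable performance traits (daily
feed consumed, body weight, egg laying) and a latent vector of true
digestibility coefficients, then constructs the manure record as the exact
mass-balance consequence:

    excreted nutrient = intake * (1 - DC/100)

for dry matter, fat, (uric-acid-corrected) nitrogen and organic matter.
Manure ash is the balancing residue between excreted DM and excreted
organic matter (organic matter being DM minus ash on both sides), so the
four latent DCs are free parameters and the analysis pipeline's estimates
can be checked against known truth. With zero assay noise the pipeline
recovers every latent DC to machine precision — the central oracle of this
package.

Urinary nitrogen is modelled as a configurable fraction of total excreted
N bound in uric acid; the corresponding uric-acid mass is placed in the
assay so the downstream stoichiometric correction removes exactly the
urinary share.

Default line parameters emulate two White Leghorn layer lines measured at
the end of lay (90-96 weeks) on a corn-wheat diet: line A eats more, lays
less and digests better; line B is the more feed-efficient line despite
uniformly lower digestibility. Printed standard errors are converted back
to between-bird SDs via SE * sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .digestibility import URIC_ACID_N_FRACTION
from .trial_data import BirdRecord, FeedComposition, ManureAssay, TrialDataset

__all__ = [
    "LineParams",
    "SimConfig",
    "SimulationError",
    "simulate_trial",
    "inject_outliers",
    "default_feed",
    "default_line_params",
    "default_sim_config",
]

DC_KEYS = ("dm", "fat", "n", "org")


class SimulationError(ValueError):
    """Raised when a parameter combination breaks the nutrient mass balance."""


@dataclass
class LineParams:
    """Distributional parameters for one genetic line.

    Trait means/SDs are between-bird (g/day for feed, g for body weight and
    eggs); ``laying_prob`` is the per-day probability of laying an egg;
    ``true_dc_means``/``true_dc_sds`` (percent, keys dm/fat/n/org) define
    the latent digestibility distribution, truncated to [0, 100];
    ``manure_moisture_frac`` is the water fraction of fresh manure;
    ``ua_n_frac_of_excreted_n`` the share of total excreted N bound in uric
    acid; ``assay_noise_cv`` a multiplicative coefficient of variation on
    the chemistry; ``airdry_dm`` the DM content (g/kg) of the air-dried
    sample (1000 = drying to constant weight); ``dc_correlation`` an
    optional 4x4 correlation matrix for the latent DCs (default:
    independence).
    """

    n_birds: int
    dfc_mean: float
    dfc_sd: float
    dbw_mean: float
    dbw_sd: float
    egg_weight_mean: float
    egg_weight_sd: float
    laying_prob: float
    true_dc_means: dict[str, float]
    true_dc_sds: dict[str, float]
    manure_moisture_frac: float
    ua_n_frac_of_excreted_n: float = 0.35
    assay_noise_cv: float = 0.0
    airdry_dm: float = 1000.0
    dc_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_birds <= 0:
            raise ValueError("n_birds must be > 0")
        if not 0 < self.laying_prob <= 1:
            raise ValueError("laying_prob must be in (0, 1]")
        if not 0 <= self.manure_moisture_frac < 1:
            raise ValueError("manure_moisture_frac must be in [0, 1)")
        if not 0 <= self.ua_n_frac_of_excreted_n < 1:
            raise ValueError("ua_n_frac_of_excreted_n must be in [0, 1)")
        if not 0 < self.airdry_dm <= 1000:
            raise ValueError("airdry_dm must be in (0, 1000] g/kg")
        for key in DC_KEYS:
            m = self.true_dc_means[key]
            if not 0 <= m <= 100:
                raise ValueError(f"true DC mean for {key} must be in [0, 100], got {m}")
            if self.true_dc_sds[key] < 0:
                raise ValueError(f"true DC sd for {key} must be >= 0")
        for name in ("dfc_sd", "dbw_sd", "egg_weight_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimConfig:
    """A complete simulated-trial specification: diet, lines, seed, windows."""

    feed: FeedComposition
    lines: dict[str, LineParams]
    seed: int
    period_days: int = 7
    expected_eggs: int = 8

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("at least one line is required")
        if self.period_days <= 0 or self.expected_eggs <= 0:
            raise ValueError("period_days and expected_eggs must be > 0")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x <= high:
            return float(x)
    warnings.warn(
        f"truncated-normal rejection failed after {max_tries} draws "
        f"(mean={mean}, sd={sd}); clipping", stacklevel=2,
    )
    return float(np.clip(mean, low, high))


def _dc_feasible(dc: dict[str, float], params: LineParams, feed) -> bool:
    """Mass-balance admissibility of a latent DC vector for the given diet.

    Excreted organic matter, fat and total (faecal + urinary) nitrogen must
    each fit inside the excreted dry matter; the checks are intake-scale
    free, so feasibility depends only on the diet composition and the DCs.
    """
    dm_frac = feed.dm / 1000.0
    exc_dm = dm_frac * (1 - dc["dm"] / 100.0)
    org_frac = (feed.dm - feed.ash) / 1000.0
    if org_frac * (1 - dc["org"] / 100.0) > exc_dm:
        return False
    if feed.fat / 1000.0 * (1 - dc["fat"] / 100.0) > exc_dm:
        return False
    n_total = feed.nitrogen / 1000.0 * (1 - dc["n"] / 100.0) / (
        1 - params.ua_n_frac_of_excreted_n
    )
    if n_total > exc_dm or n_total / URIC_ACID_N_FRACTION * params.ua_n_frac_of_excreted_n > exc_dm:
        return False
    return True


def _draw_dc_vector(
    rng: np.random.Generator, params: LineParams, feed, max_tries: int = 1000
) -> dict[str, float]:
    """One latent DC vector, truncated to [0, 100] and the feasible region.

    The latent distribution is a (possibly correlated) normal truncated to
    the set of DC vectors the nutrient mass balance admits; draws are
    rejected until one lands inside. Parameter combinations whose feasible
    region has negligible probability raise :class:`SimulationError`.
    """
    means = np.array([params.true_dc_means[k] for k in DC_KEYS])
    sds = np.array([params.true_dc_sds[k] for k in DC_KEYS])
    corr = params.dc_correlation
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (4, 4):
            raise ValueError("dc_correlation must be 4x4 (order dm, fat, n, org)")
        cov = np.outer(sds, sds) * corr
    for _ in range(max_tries):
        if corr is None:
            x = rng.normal(means, sds)
        else:
            x = rng.multivariate_normal(means, cov, method="cholesky")
        if not np.all((x >= 0) & (x <= 100)):
            continue
        dc = dict(zip(DC_KEYS, map(float, x)))
        if _dc_feasible(dc, params, feed):
            return dc
    raise SimulationError(
        "latent DC distribution has negligible mass inside the mass-balance-"
        f"feasible region (means {params.true_dc_means}, sds {params.true_dc_sds}); "
        "excreted nutrients would exceed excreted dry matter"
    )


def _noise(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal noise factor."""
    if cv == 0:
        return 1.0
    return float(rng.lognormal(mean=-0.5 * cv * cv, sigma=cv))


def _simulate_bird(
    rng: np.random.Generator,
    bird_id: str,
    label: str,
    params: LineParams,
    config: SimConfig,
) -> tuple[BirdRecord, ManureAssay, dict]:
    feed = config.feed
    dfc = _trunc_normal(rng, params.dfc_mean, params.dfc_sd, 0.0, np.inf)
    dbw = _trunc_normal(rng, params.dbw_mean, params.dbw_sd, 0.0, np.inf)
    lays = rng.random(config.expected_eggs) < params.laying_prob
    eggs_laid = int(lays.sum())
    mean_egg_weight = None
    if eggs_laid > 0:
        weights = [
            _trunc_normal(rng, params.egg_weight_mean, params.egg_weight_sd, 0.0, np.inf)
            for _ in range(eggs_laid)
        ]
        mean_egg_weight = float(np.mean(weights))
    dc = _draw_dc_vector(rng, params, feed)

    # nutrient intakes (g/day); organic matter = DM - ash on the intake side
    feed_dm_in = dfc * feed.dm / 1000.0
    n_in = dfc * feed.nitrogen / 1000.0
    fat_in = dfc * feed.fat / 1000.0
    ash_in = dfc * feed.ash / 1000.0
    org_in = feed_dm_in - ash_in

    # excreted masses from the latent DCs (g DM/day)
    exc_dm = feed_dm_in * (1 - dc["dm"] / 100.0)
    exc_fat = fat_in * (1 - dc["fat"] / 100.0)
    exc_n_faecal = n_in * (1 - dc["n"] / 100.0)
    exc_org = org_in * (1 - dc["org"] / 100.0)
    exc_ash = exc_dm - exc_org  # ash balances DM against organic matter
    # urinary N rides on top of faecal N as uric acid
    exc_n_total = exc_n_faecal / (1 - params.ua_n_frac_of_excreted_n)
    ua_mass = (exc_n_total - exc_n_faecal) / URIC_ACID_N_FRACTION
    for name, mass in (("organic matter", exc_org), ("fat", exc_fat),
                       ("nitrogen", exc_n_total), ("uric acid", ua_mass)):
        if mass > exc_dm:  # unreachable for draws (feasibility-checked); guards sd=0 params
            raise SimulationError(
                f"bird {bird_id}: excreted {name} ({mass:.3f} g) exceeds excreted DM "
                f"({exc_dm:.3f} g)"
            )

    dmw = exc_dm / (1 - params.manure_moisture_frac)
    # air-dried sample: exc_dm grams of DM at airdry_dm g DM per kg sample
    airdry_mass = exc_dm * 1000.0 / params.airdry_dm
    adm = airdry_mass / dmw * 1000.0 if dmw > 0 else 0.0
    to_ad = 1000.0 / airdry_mass if airdry_mass > 0 else 0.0
    cv = params.assay_noise_cv
    assay = ManureAssay(
        bird_id=bird_id,
        adm=min(adm * _noise(rng, cv), 1000.0),
        dm_ad=params.airdry_dm,
        ash_ad=min(exc_ash * to_ad * _noise(rng, cv), params.airdry_dm),
        nitrogen_ad=min(exc_n_total * to_ad * _noise(rng, cv), params.airdry_dm),
        fat_ad=min(exc_fat * to_ad * _noise(rng, cv), params.airdry_dm),
        uric_acid_ad=min(ua_mass * to_ad * _noise(rng, cv), params.airdry_dm),
    )
    bird = BirdRecord(
        bird_id=bird_id,
        line=label,
        dfc=dfc,
        dmw=dmw,
        dbw=dbw,
        eggs_laid=eggs_laid,
        mean_egg_weight=mean_egg_weight,
        expected_eggs=config.expected_eggs,
        period_days=config.period_days,
    )
    truth = {
        "bird_id": bird_id,
        "line": label,
        "true_dc_dm": dc["dm"],
        "true_dc_fat": dc["fat"],
        "true_dc_n": dc["n"],
        "true_dc_org": dc["org"],
        "excreted_dm": exc_dm,
        "moisture_frac": params.manure_moisture_frac,
    }
    return bird, assay, truth


def simulate_trial(config: SimConfig) -> tuple[TrialDataset, pd.DataFrame]:
    """Simulate a trial; returns the dataset and the latent ground-truth table.

    Randomness is split per line and per bird via numpy seed sequences, so
    enlarging a line appends birds without perturbing those already drawn.
    """
    root = np.random.SeedSequence(config.seed)
    labels = sorted(config.lines)
    line_seqs = root.spawn(len(labels))
    birds: list[BirdRecord] = []
    assays: dict[str, ManureAssay] = {}
    truths: list[dict] = []
    for label, line_seq in zip(labels, line_seqs):
        params = config.lines[label]
        for i, bird_seq in enumerate(line_seq.spawn(params.n_birds)):
            rng = np.random.default_rng(bird_seq)
            bird, assay, truth = _simulate_bird(
                rng, f"{label}{i + 1:03d}", label, params, config
            )
            birds.append(bird)
            assays[bird.bird_id] = assay
            truths.append(truth)
    dataset = TrialDataset(birds=birds, assays=assays, feed=config.feed)
    return dataset, pd.DataFrame(truths)


def inject_outliers(
    dataset: TrialDataset,
    k: int,
    magnitude: float,
    seed: int,
    trait: str = "dfc",
) -> tuple[TrialDataset, list[str]]:
    """Displace *trait* for k randomly chosen birds beyond magnitude x IQR.

    Displacement is relative to the trait's within-line quartiles: the new
    value is Q3 + magnitude*IQR or Q1 - magnitude*IQR (direction random,
    flipped upward if a downward displacement would go non-positive).
    Returns the modified dataset and the displaced bird ids. ``magnitude``
    below the fence multiplier used later leaves the birds inside the
    fences — the sub-threshold control case.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if k >= len(dataset.birds):
        raise ValueError(f"k = {k} must be smaller than the number of birds ({len(dataset.birds)})")
    if trait not in ("dfc", "dmw", "dbw", "mean_egg_weight"):
        raise ValueError(f"cannot inject outliers into trait {trait!r}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(dataset.birds), size=k, replace=False)
    chosen = {dataset.birds[i].bird_id for i in idx}

    df = dataset.birds_frame()
    quartiles = {}
    for label, grp in df.groupby("line"):
        vals = grp[trait].dropna().to_numpy(dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        quartiles[label] = (q1, q3, q3 - q1)

    new_birds = []
    for bird in dataset.birds:
        if bird.bird_id in chosen:
            q1, q3, iqr = quartiles[bird.line]
            down = q1 - magnitude * iqr
            up = q3 + magnitude * iqr
            value = down if (rng.random() < 0.5 and down > 0) else up
            new_birds.append(replace(bird, **{trait: float(value)}))
        else:
            new_birds.append(bird)
    out = TrialDataset(birds=new_birds, assays=dict(dataset.assays), feed=dataset.feed)
    return out, sorted(chosen)


# ---------------------------------------------------------------------------
# Default study conditions


def default_feed() -> FeedComposition:
    """The corn-wheat layer diet: 900 DM, 25 N, 50 fat, 131 ash, 38 sugar g/kg as-fed."""
    return FeedComposition(dm=900.0, nitrogen=25.0, fat=50.0, ash=131.0, sugar=38.0)


def _se_to_sd(se: float, n: int) -> float:
    """Between-bird SD reconstructed from a printed standard error of the mean."""
    return se * float(np.sqrt(n))


#: Default latent DC correlation (order dm, fat, n, org). The digestibility
#: coefficients of one bird are strongly coherent — reported within-line
#: correlations reach 0.92-0.95 between DC_DM and DC_Org, with DC_Fat the
#: least coupled — and at the study's between-bird SDs near-independent
#: draws would routinely break the nutrient mass balance.
DEFAULT_DC_CORRELATION = np.array(
    [
        [1.00, 0.50, 0.70, 0.95],
        [0.50, 1.00, 0.40, 0.50],
        [0.70, 0.40, 1.00, 0.70],
        [0.95, 0.50, 0.70, 1.00],
    ]
)


def default_line_params(assay_noise_cv: float = 0.02) -> dict[str, LineParams]:
    """Two layer lines at end of lay, parameterised from published line means/SEs.

    SDs are SE*sqrt(n) with n = 43 (line A) and 44 (line B), the post-
    outlier-removal group sizes behind the printed SEs. Mean egg weights
    are back-calculated from egg mass and laying percentage (EM / LP * 100);
    manure moisture is set so the expected fresh daily manure weight at the
    line means matches the observed line means (121.6 and 146.6 g/day).
    """
    n_a, n_b = 43, 44
    line_a = LineParams(
        n_birds=50,
        dfc_mean=142.0, dfc_sd=_se_to_sd(6.7, n_a),
        dbw_mean=1718.0, dbw_sd=_se_to_sd(26.1, n_a),
        egg_weight_mean=49.3 / 82.0 * 100.0,  # EM 49.3 g at LP 82 %
        egg_weight_sd=5.0,
        laying_prob=0.82,
        true_dc_means={"dm": 74.6, "fat": 86.0, "n": 77.5, "org": 77.5},
        true_dc_sds={
            "dm": _se_to_sd(1.0, n_a), "fat": _se_to_sd(0.8, n_a),
            "n": _se_to_sd(1.0, n_a), "org": _se_to_sd(0.8, n_a),
        },
        manure_moisture_frac=0.733,
        assay_noise_cv=assay_noise_cv,
        dc_correlation=DEFAULT_DC_CORRELATION,
    )
    line_b = LineParams(
        n_birds=50,
        dfc_mean=122.8, dfc_sd=_se_to_sd(2.4, n_b),
        dbw_mean=1683.0, dbw_sd=_se_to_sd(20.9, n_b),
        egg_weight_mean=53.8 / 92.0 * 100.0,  # EM 53.8 g at LP 92 %
        egg_weight_sd=5.0,
        laying_prob=0.92,
        true_dc_means={"dm": 65.5, "fat": 78.8, "n": 73.5, "org": 69.8},
        true_dc_sds={
            "dm": _se_to_sd(0.6, n_b), "fat": _se_to_sd(0.7, n_b),
            "n": _se_to_sd(0.8, n_b), "org": _se_to_sd(0.5, n_b),
        },
        manure_moisture_frac=0.740,
        assay_noise_cv=assay_noise_cv,
        dc_correlation=DEFAULT_DC_CORRELATION,
    )
    return {"A": line_a, "B": line_b}


def default_sim_config(seed: int, assay_noise_cv: float = 0.02) -> SimConfig:
    """The default two-line study configuration at the given seed."""
    return SimConfig(
        feed=default_feed(),
        lines=default_line_params(assay_noise_cv=assay_noise_cv),
        seed=seed,
    )
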