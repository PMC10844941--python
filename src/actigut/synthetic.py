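"""Synthetic study generator: accelerometer count streams, covariates and
compositional microbiome tables with known planted structure.

The generator emulates a free-living actigraphy + faecal metagenomics
cohort: participants wear a hip accelerometer for a week (minute-level
counts with in-bed periods, genuine non-wear bouts and wake-time activity
drawn from the intensity bands), a covariate table mirrors the usual
epidemiological adjustment set, and species abundances follow a
logistic-normal composition (multivariate normal on the log scale mapped
to the simplex), so that effects planted on the clr scale are exact.

A latent "health consciousness" variable can confound exposures and
planted features at a configurable strength.  Every generator draws from
its own RNG stream derived from the master seed, so the three generators
are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import accelerometry
from .errors import AlignmentError, ConfigurationError
from .features import ModuleDefinition

__all__ = ["SynthConfig", "GroundTruth", "generate_covariates", "generate_counts",
           "generate_timeuse", "generate_microbiome", "synthetic_module_definitions"]

#: cohort-style target composition of wear time (percent): SED, LIPA, MPA, VPA
TARGET_COMPOSITION = (55.5, 39.5, 4.7, 0.3)

_EXPOSURE_COLS = {"SED": "z_alr_SED", "MPA": "z_alr_MPA", "VPA": "z_alr_VPA"}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic study.

    ``effect_table`` plants linear effects on the clr scale per 1-SD alr
    exposure: a list of ``(feature_id, exposure, beta)`` with exposure in
    {"SED", "MPA", "VPA"}.  ``zero_inflation`` is the maximum per-entry
    probability of a detection-limit zero (rare species reach it, abundant
    ones are essentially never zeroed).  ``invalid_fraction`` of
    participants are generated with fewer than 4 valid wear days so the
    downstream exclusion logic is exercised.
    """

    n_participants: int = 100
    n_days: int = 7
    epoch_seconds: int = 60
    n_species: int = 200
    n_modules: int = 12
    effect_table: tuple[tuple[str, str, float], ...] = ()
    confounder_strength: float = 0.0
    zero_inflation: float = 0.1
    invalid_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.epoch_seconds != 60:
            raise ConfigurationError("only 60-s epochs are supported")
        if self.n_days < 1 or self.n_species < 2 or self.n_modules < 1:
            raise ConfigurationError("n_days, n_species and n_modules must be positive")
        for p, name in ((self.zero_inflation, "zero_inflation"),
                        (self.invalid_fraction, "invalid_fraction")):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        for feat, exp, beta in self.effect_table:
            if exp not in _EXPOSURE_COLS:
                raise ConfigurationError(f"unknown exposure {exp!r} in effect table")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent RNG stream derived from the master seed."""
        return np.random.default_rng([self.seed, stream])

    def participant_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_participants + 1)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for test assertions."""

    timeuse_fractions: pd.DataFrame  # per participant-day SED/LIPA/MPA/VPA of wear
    in_bed: pd.DataFrame             # participant_id, start, end
    nonwear: pd.DataFrame            # participant_id, start, end
    effect_table: tuple[tuple[str, str, float], ...]
    covariate_effects: dict


def _health_consciousness(config: SynthConfig) -> pd.Series:
    """Latent confounder; same values in every generator (own stream)."""
    rng = config.rng(0)
    return pd.Series(rng.standard_normal(config.n_participants),
                     index=config.participant_ids(), name="health_consciousness")


def generate_covariates(config: SynthConfig) -> pd.DataFrame:
    """Covariate table with realistic continuous and categorical variables.

    Includes the latent ``health_consciousness`` column (not part of any
    adjustment set; exposed for diagnostics) plus medication/antibiotic
    indicator columns for the sensitivity analyses.
    """
    rng = config.rng(1)
    n = config.n_participants
    ids = config.participant_ids()
    hc = _health_consciousness(config)

    df = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    df["age"] = rng.normal(57.6, 4.3, n).round(1)
    df["sex"] = rng.choice(["female", "male"], n, p=[0.53, 0.47])
    df["alcohol"] = np.round(np.exp(rng.normal(np.log(5.4), 0.9, n)), 1)
    df["smoking"] = rng.choice(["never", "former", "current"], n, p=[0.52, 0.36, 0.12])
    df["education"] = rng.choice(["compulsory", "upper_secondary", "university"], n,
                                 p=[0.09, 0.45, 0.46])
    df["country_of_birth"] = rng.choice(["scandinavia", "europe", "asia", "other"], n,
                                        p=[0.85, 0.09, 0.04, 0.02])
    df["site"] = rng.choice(["malmo", "uppsala"], n, p=[0.49, 0.51])
    df["month_of_wear"] = rng.choice([f"m{i:02d}" for i in range(1, 13)], n)
    df["dna_plate"] = rng.choice([f"plate{i:02d}" for i in range(1, 9)], n)
    df["energy_intake"] = np.round(np.exp(rng.normal(np.log(1594), 0.35, n)), 0)
    df["protein"] = rng.normal(16.6, 2.9, n).round(1)
    df["fruit_veg"] = np.round(np.exp(rng.normal(np.log(278), 0.7, n) + 0.15 * hc.to_numpy()), 1)
    df["whole_grain"] = np.round(np.exp(rng.normal(np.log(31), 0.8, n) + 0.1 * hc.to_numpy()), 1)
    df["bmi"] = np.round(26.8 + 3.6 * rng.standard_normal(n) - 0.8 * hc.to_numpy(), 1)
    df["whr"] = np.round(0.92 + 0.07 * rng.standard_normal(n) - 0.01 * hc.to_numpy(), 3)
    df["ppi_use"] = rng.binomial(1, 0.04, n)
    df["medication_use"] = rng.binomial(1, 0.30, n)
    df["antibiotics_3mo"] = rng.binomial(1, 0.06, n)
    df["health_consciousness"] = hc.to_numpy()
    return df


# ----------------------------------------------------------------------
# time-use: fast compositional path
# ----------------------------------------------------------------------

def _draw_alr_timeuse(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw participant-level alr(SED, MPA, VPA vs LIPA) coordinates."""
    n = config.n_participants
    target = np.array(TARGET_COMPOSITION)
    mu = np.log(target[[0, 2, 3]] / target[1])
    sd = np.array([0.30, 0.55, 0.95])
    corr = np.array([[1.0, -0.35, -0.20], [-0.35, 1.0, 0.45], [-0.20, 0.45, 1.0]])
    cov = corr * np.outer(sd, sd)
    alr = rng.multivariate_normal(mu, cov, size=n)
    hc = _health_consciousness(config).to_numpy()
    # health consciousness: less sedentary, more active
    alr += config.confounder_strength * np.outer(hc, np.array([-0.2, 0.5, 0.7]))
    return alr


def _alr_to_pct(alr: np.ndarray) -> np.ndarray:
    """Map alr (vs LIPA) back to percentages of wear time."""
    z = np.concatenate([alr[:, [0]], np.zeros((len(alr), 1)), alr[:, 1:]], axis=1)
    ez = np.exp(z - z.max(axis=1, keepdims=True))
    return 100.0 * ez / ez.sum(axis=1, keepdims=True)


def generate_timeuse(config: SynthConfig) -> pd.DataFrame:
    """Participant-level time-use compositions drawn directly (no count stream).

    Fast path for statistical simulation studies: the same logistic-normal
    composition the minute-level generator targets, with VPA zeros
    introduced for the least-vigorous participants, passed through the
    real alr/zero-replacement/standardization pipeline.  Also carries
    ``wear_minutes`` and ``pct_weekend_wear`` technical covariates.
    """
    rng = config.rng(2)
    pct = _alr_to_pct(_draw_alr_timeuse(config, rng))
    # detection-style VPA zeros: lowest VPA values are recorded as zero
    vpa = pct[:, 3]
    zero = vpa < np.quantile(vpa, 0.25)
    pct[zero, 3] = 0.0
    pct[zero] *= 100.0 / pct[zero].sum(axis=1, keepdims=True)

    comp = pd.DataFrame(pct, columns=[f"pct_{p}" for p in accelerometry.PARTS],
                        index=pd.Index(config.participant_ids(), name="participant_id"))
    comp["valid_days"] = rng.integers(4, config.n_days + 1, config.n_participants)
    comp["wear_minutes"] = (comp["valid_days"] * rng.normal(870, 60, config.n_participants)).round().astype(int)
    comp["pct_weekend_wear"] = np.clip(rng.normal(28.6, 3.0, config.n_participants), 0, 100)

    alr = accelerometry.alr_transform(comp.reset_index(), reference="LIPA").set_index(comp.index)
    alr = accelerometry.standardize_alr(alr)
    return pd.concat([comp, alr.drop(columns=["participant_id"], errors="ignore")], axis=1)


# ----------------------------------------------------------------------
# minute-level count streams
# ----------------------------------------------------------------------

_START = datetime(2022, 3, 7)  # a Monday


def _day_minutes(
    rng: np.random.Generator,
    fractions: np.ndarray,
    bed_end_min: int,
    bed_start_min: int,
    insert_nonwear: bool,
    invalid: bool,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One day (1440 min) of cpm values; returns counts + non-wear intervals."""
    cpm = np.zeros(1440, dtype=np.int64)
    wake = np.arange(bed_end_min, bed_start_min)
    # wake-time intensities from the participant's target composition
    states = rng.choice(4, size=len(wake), p=fractions)
    lo = np.array([10, 200, 2690, 6167])
    hi = np.array([199, 2689, 6166, 9000])
    cpm[wake] = rng.integers(lo[states], hi[states] + 1)

    nonwear: list[tuple[int, int]] = []
    if invalid:
        # wipe most of the wake window: day ends up with <600 wear minutes
        start = bed_end_min + 30
        stop = bed_start_min - 60
        cpm[start:stop] = 0
        nonwear.append((start, stop))
    elif insert_nonwear:
        length = int(rng.integers(60, 181))
        start = int(rng.integers(bed_end_min + 60, bed_start_min - length - 60))
        cpm[start:start + length] = 0
        if rng.random() < 0.5 and length >= 20:
            # a short tolerated low-count interruption inside the bout
            k = int(rng.integers(1, 3))
            pos = start + int(rng.integers(5, length - 5 - k))
            cpm[pos:pos + k] = rng.integers(1, 200, k)
        nonwear.append((start, start + length))
    return cpm, nonwear


def generate_counts(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Minute-level cpm streams for every participant.

    Each day has an in-bed period around 23:00-07:00 (±90 min jitter, zero
    counts), optional genuine daytime non-wear bouts (some with tolerated
    ≤2-min low-count interruptions) and wake-time counts drawn from the
    participant's target intensity composition.  A configured fraction of
    participants receives fewer than 4 valid days.
    """
    rng = config.rng(3)
    alr = _draw_alr_timeuse(config, rng)
    pct = _alr_to_pct(alr)
    ids = config.participant_ids()
    n_invalid = int(round(config.invalid_fraction * config.n_participants))
    invalid_ids = set(ids[:n_invalid])

    frames = []
    frac_rows, bed_rows, nw_rows = [], [], []
    minutes_per_day = 1440
    for pi, pid in enumerate(ids):
        fractions = pct[pi] / 100.0
        day_counts = []
        invalid_days = (
            rng.choice(config.n_days, size=config.n_days - 3, replace=False)
            if pid in invalid_ids and config.n_days > 3 else np.array([], dtype=int)
        )
        for d in range(config.n_days):
            day0 = _START + timedelta(days=d)
            bed_end = int(np.clip(rng.normal(7 * 60, 45), 5.5 * 60, 8.5 * 60))
            bed_start = int(np.clip(rng.normal(23 * 60, 45), 21.5 * 60, 24 * 60 - 1))
            cpm, nw = _day_minutes(
                rng, fractions, bed_end, bed_start,
                insert_nonwear=rng.random() < 0.25, invalid=d in invalid_days,
            )
            day_counts.append(cpm)
            bed_rows.append({"participant_id": pid,
                             "start": day0 + timedelta(minutes=bed_start),
                             "end": day0 + timedelta(days=1, minutes=bed_end)})
            for s, e in nw:
                nw_rows.append({"participant_id": pid,
                                "start": day0 + timedelta(minutes=s),
                                "end": day0 + timedelta(minutes=e)})
            wear = cpm[bed_end:bed_start]
            wear = wear[wear > 0]
            if len(wear):
                bands = np.searchsorted([200, 2690, 6167], wear, side="right")
                fr = np.bincount(bands, minlength=4) / len(wear)
            else:
                fr = np.zeros(4)
            frac_rows.append({"participant_id": pid, "day": d,
                              **{p: fr[k] for k, p in enumerate(accelerometry.PARTS)}})
        cpm_all = np.concatenate(day_counts)
        ts = pd.date_range(_START, periods=config.n_days * minutes_per_day, freq="min")
        frames.append(pd.DataFrame({"participant_id": pid, "timestamp": ts, "cpm": cpm_all}))

    counts = pd.concat(frames, ignore_index=True)
    gt = GroundTruth(
        timeuse_fractions=pd.DataFrame(frac_rows),
        in_bed=pd.DataFrame(bed_rows),
        nonwear=pd.DataFrame(nw_rows),
        effect_table=config.effect_table,
        covariate_effects={"health_consciousness": config.confounder_strength},
    )
    return counts, gt


# ----------------------------------------------------------------------
# microbiome
# ----------------------------------------------------------------------

def species_ids(config: SynthConfig) -> list[str]:
    return [f"sp_{i:04d}" for i in range(1, config.n_species + 1)]


def generate_microbiome(
    config: SynthConfig,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species relative abundances and an ortholog table for module scoring.

    Species follow a logistic-normal model: per-sample log abundances are
    multivariate normal, planted features get ``beta * z_alr_exposure``
    added (exact on the clr scale, since clr is invariant to the softmax
    normaliser), the latent health-consciousness confounder is added to
    planted features at ``confounder_strength``, and detection-limit zero
    inflation is applied with renormalisation.  The last few species are
    engineered to sit far below the prevalence filter threshold.

    ``exposures`` must carry ``z_alr_SED/MPA/VPA`` indexed like
    ``covariates`` (participant ids).
    """
    if not exposures.index.equals(covariates.index):
        raise AlignmentError("exposures and covariates must share the participant index")
    rng = config.rng(4)
    ids = exposures.index
    n = len(ids)
    S = config.n_species
    names = species_ids(config)

    mu = rng.normal(-2.0, 2.0, S)
    n_rare = max(2, S // 50)
    mu[-n_rare:] = -16.0  # engineered to fail the prevalence filter
    sigma = np.exp(rng.normal(0.0, 0.25, S))  # per-species clr noise SD ~ 1

    Z = mu[None, :] + rng.standard_normal((n, S)) * sigma[None, :]
    hc = covariates["health_consciousness"].to_numpy() if "health_consciousness" in covariates else np.zeros(n)
    for feat, exp, beta in config.effect_table:
        j = names.index(feat)
        mu[j] = 0.0  # planted features are abundant
        Z[:, j] = 0.0 + rng.standard_normal(n) * sigma[j]
        Z[:, j] += beta * exposures[_EXPOSURE_COLS[exp]].to_numpy()
        Z[:, j] += config.confounder_strength * hc

    X = np.exp(Z - Z.max(axis=1, keepdims=True))
    X /= X.sum(axis=1, keepdims=True)

    if config.zero_inflation > 0:
        # detection-limit zeros: a per-species dropout probability that decays
        # with the species' typical abundance (rare species are lost most)
        typical = np.exp(mu) / np.exp(mu).sum()
        p_zero = config.zero_inflation * np.exp(-typical / 1e-3)
        X[rng.random(X.shape) < p_zero[None, :]] = 0.0
        X /= X.sum(axis=1, keepdims=True)

    species = pd.DataFrame(X, index=ids, columns=names)

    # ortholog table: log-normal abundances over the synthetic module universe
    defs = synthetic_module_definitions(config)
    orthologs = sorted({o for m in defs for step in m.steps for o in step})
    G = np.exp(rng.normal(2.0, 1.0, (n, len(orthologs))))
    # some orthologs absent in some samples so module coverage varies
    G[rng.random(G.shape) < 0.15] = 0.0
    genes = pd.DataFrame(G, index=ids, columns=orthologs)
    return species, genes


def synthetic_module_definitions(config: SynthConfig) -> list[ModuleDefinition]:
    """Deterministic synthetic stepwise module definitions.

    Each module has 2-5 steps with 1-3 alternative orthologs per step;
    ortholog identifiers follow a KEGG-like ``K######`` pattern.  Purely
    synthetic stand-ins for curated module catalogues.
    """
    rng = config.rng(5)
    defs = []
    counter = 1
    for m in range(1, config.n_modules + 1):
        n_steps = int(rng.integers(2, 6))
        steps = []
        for _ in range(n_steps):
            k = int(rng.integers(1, 4))
            steps.append(frozenset(f"K{counter + i:06d}" for i in range(k)))
            counter += k
        defs.append(ModuleDefinition(f"mod_{m:03d}", f"synthetic module {m}", tuple(steps)))
    return defs
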