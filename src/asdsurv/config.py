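"""Generator configuration: per-site parameters and named site presets.

A :class:`GeneratorConfig` describes a synthetic surveillance network: one
:class:`SiteConfig` per site controls the population (size, sex and
race/ethnicity mix), the latent case process (true prevalence with a
male:female rate ratio), the record-generating process (which of the three
identification types a case carries, source availability, chart
accessibility), diagnosis/evaluation age distributions by cognitive band,
and the census-tract landscape. The named presets approximate the eleven
surveillance sites of the 2018 network (population sizes, demographics,
source availability and chart accessibility as published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .ascertain import IQ_BANDS, REGIONS
from .errors import ConfigurationError
from .ses import RACE_CATEGORIES

__all__ = [
    "AgeDistribution",
    "SiteConfig",
    "GeneratorConfig",
    "mixture_from_marginals",
    "scenario_preset",
    "network_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class AgeDistribution:
    """Parametric age-in-months distribution, truncated to [low, high].

    The default family is a log-normal parameterised by its median (so the
    configured medians are directly interpretable against the reported
    tables) with log-scale sigma, truncated to ages observable for an
    8-year-old (12–107 months) via inverse-CDF sampling. Samples are
    rounded to integer months.
    """

    family: str = "lognormal"
    median: float = 50.0
    sigma: float = 0.40
    low: int = 12
    high: int = 107

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ConfigurationError(f"unsupported age distribution family {self.family!r}")
        if not (self.low < self.high):
            raise ConfigurationError("age distribution requires low < high")
        if self.median <= 0 or self.sigma <= 0:
            raise ConfigurationError("median and sigma must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu = math.log(self.median)
        lo = sps.norm.cdf((math.log(self.low) - mu) / self.sigma)
        hi = sps.norm.cdf((math.log(self.high) - mu) / self.sigma)
        u = rng.uniform(lo, hi, size=size)
        ages = np.exp(mu + self.sigma * sps.norm.ppf(u))
        return np.clip(np.rint(ages), self.low, self.high).astype(int)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "median": self.median,
            "sigma": self.sigma,
            "low": self.low,
            "high": self.high,
        }


def mixture_from_marginals(p_dx: float, p_sped: float, p_icd: float) -> dict:
    """Identification mixture over the 7 regions from indicator marginals.

    Treats the three indicators as independent and conditions on at least
    one being present, which reproduces the marginal shares approximately
    (exactly in the limit of no empty-combination mass).
    """
    for name, p in (("p_dx", p_dx), ("p_sped", p_sped), ("p_icd", p_icd)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
    flags = {
        "dx-only": (1, 0, 0),
        "sped-only": (0, 1, 0),
        "icd-only": (0, 0, 1),
        "dx+sped": (1, 1, 0),
        "dx+icd": (1, 0, 1),
        "sped+icd": (0, 1, 1),
        "all-three": (1, 1, 1),
    }
    raw = {}
    for region, (d, s, i) in flags.items():
        raw[region] = (
            (p_dx if d else 1 - p_dx)
            * (p_sped if s else 1 - p_sped)
            * (p_icd if i else 1 - p_icd)
        )
    total = sum(raw.values())
    if total <= 0:
        raise ConfigurationError("marginals leave no mass on any identification region")
    return {region: w / total for region, w in raw.items()}


_WEIGHT_TOL = 1e-9


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SiteConfig:
    """Parameters for one synthetic surveillance site."""

    site_name: str
    n_children: int
    pct_male: float = 0.511
    race_mix: dict = field(
        default_factory=lambda: {
            "white-nh": 0.516,
            "black-nh": 0.212,
            "hispanic": 0.205,
            "api-nh": 0.060,
            "aian-nh": 0.006,
            "other-multiracial": 0.001,
        }
    )
    true_prevalence: float = 0.023
    male_female_rate_ratio: float = 4.2
    has_education_source: bool = True
    record_accessible_fraction: float = 1.0
    tract_count: int = 30
    tract_mhi_range: tuple = (30_000.0, 150_000.0)
    missing_tract_fraction: float = 0.064
    identification_mixture: dict = field(
        default_factory=lambda: mixture_from_marginals(0.758, 0.617, 0.667)
    )
    p_suspected_before_confirmed: float = 0.331
    p_ruled_out_ever: float = 0.109
    p_ruled_out_more_recent: float = 0.041
    iq_available_fraction: float = 0.595
    iq_band_probs: dict = field(
        default_factory=lambda: {"<=70": 0.352, "71-85": 0.231, ">85": 0.417}
    )
    dx_age_months_distribution: dict = field(
        default_factory=lambda: {
            "<=70": AgeDistribution(median=44.0),
            "71-85": AgeDistribution(median=53.0),
            ">85": AgeDistribution(median=53.0),
        }
    )
    first_eval_age_months_distribution: AgeDistribution = field(
        default_factory=lambda: AgeDistribution(median=38.0, sigma=0.45)
    )
    false_trigger_rate: float = 0.0005

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ConfigurationError(f"{self.site_name}: n_children must be positive")
        if self.tract_count < 1:
            raise ConfigurationError(f"{self.site_name}: tract_count must be >= 1")
        _check_prob(self.pct_male, f"{self.site_name}: pct_male")
        _check_prob(self.true_prevalence, f"{self.site_name}: true_prevalence")
        if self.male_female_rate_ratio <= 0:
            raise ConfigurationError(f"{self.site_name}: male_female_rate_ratio must be positive")
        _check_prob(self.record_accessible_fraction, f"{self.site_name}: record_accessible_fraction")
        _check_prob(self.missing_tract_fraction, f"{self.site_name}: missing_tract_fraction")
        _check_prob(self.p_suspected_before_confirmed, f"{self.site_name}: p_suspected_before_confirmed")
        _check_prob(self.p_ruled_out_ever, f"{self.site_name}: p_ruled_out_ever")
        _check_prob(self.p_ruled_out_more_recent, f"{self.site_name}: p_ruled_out_more_recent")
        if self.p_ruled_out_more_recent > self.p_ruled_out_ever + _WEIGHT_TOL:
            raise ConfigurationError(
                f"{self.site_name}: p_ruled_out_more_recent exceeds p_ruled_out_ever"
            )
        _check_prob(self.iq_available_fraction, f"{self.site_name}: iq_available_fraction")
        _check_prob(self.false_trigger_rate, f"{self.site_name}: false_trigger_rate")
        if set(self.race_mix) != set(RACE_CATEGORIES):
            raise ConfigurationError(
                f"{self.site_name}: race_mix must cover exactly {RACE_CATEGORIES}"
            )
        for name, probs, expect in (
            ("race_mix", self.race_mix, None),
            ("identification_mixture", self.identification_mixture, set(REGIONS)),
            ("iq_band_probs", self.iq_band_probs, set(IQ_BANDS)),
        ):
            if expect is not None and set(probs) != expect:
                raise ConfigurationError(
                    f"{self.site_name}: {name} must cover exactly {sorted(expect)}"
                )
            for key, p in probs.items():
                _check_prob(p, f"{self.site_name}: {name}[{key}]")
            if abs(sum(probs.values()) - 1.0) > _WEIGHT_TOL:
                raise ConfigurationError(
                    f"{self.site_name}: {name} weights sum to {sum(probs.values())}, not 1"
                )
        lo, hi = self.tract_mhi_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"{self.site_name}: invalid tract_mhi_range {self.tract_mhi_range}")
        if set(self.dx_age_months_distribution) != set(IQ_BANDS):
            raise ConfigurationError(
                f"{self.site_name}: dx_age_months_distribution needs one entry per IQ band"
            )

    def sex_specific_prevalence(self) -> tuple[float, float]:
        """(male, female) true prevalence implied by the overall rate and ratio.

        p_male = RR · p_female with the sex mix fixed so that
        pct_male·p_male + (1−pct_male)·p_female equals true_prevalence.
        """
        rr = self.male_female_rate_ratio
        p_f = self.true_prevalence / (self.pct_male * rr + (1.0 - self.pct_male))
        return min(1.0, rr * p_f), p_f


@dataclass
class GeneratorConfig:
    """A full synthetic surveillance network."""

    sites: list
    global_seed: int = 0
    analysis_year: int = 2018
    birth_year: int = 2010

    def validate(self) -> None:
        if not self.sites:
            raise ConfigurationError("at least one site is required")
        names = [s.site_name for s in self.sites]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"site names must be unique, got {names}")
        for site in self.sites:
            site.validate()


# Site roster: population aged 8, %male, race percentages (White-NH,
# Black-NH, Hispanic, A/PI-NH, AI/AN-NH), education source, % of requested
# records fully accessible, ascertained prevalence per 1,000, M:F ratio,
# identification marginals (% ICD, % sped, % dx), % suspected, % ruled-out
# ever / more recently, % with IQ info, IQ band % (<=70, 71-85, >85),
# median dx age (months) for IQ<=70 / IQ>70, median first-eval age.
_SITE_TABLE = {
    "arizona": (13313, 51.1, (42.7, 7.2, 42.9, 3.8, 3.4), True, 100.0, 24.9, 3.4,
                (29.3, 84.3, 68.6), 37.8, 15.4, 4.8, 87.6, (31.4, 23.8, 44.8), (55, 60), 41),
    "arkansas": (15435, 51.5, (63.6, 25.0, 9.5, 1.4, 0.4), True, 98.1, 22.9, 4.5,
                 (67.7, 66.3, 85.6), 48.7, 15.3, 4.5, 88.7, (39.9, 25.2, 34.8), (49, 56), 40),
    "california": (15076, 50.9, (24.3, 9.5, 51.8, 14.0, 0.4), True, 99.8, 38.9, 5.2,
                   (58.7, 88.2, 77.0), 20.0, 24.7, 12.5, 77.5, (20.5, 25.6, 54.0), (35.5, 36), 35),
    "georgia": (23580, 50.9, (25.9, 40.5, 24.5, 8.9, 0.2), True, 66.6, 21.8, 4.5,
                (41.6, 72.8, 62.5), 49.2, 5.6, 2.1, 68.7, (38.5, 18.4, 43.1), (46.5, 60), 37),
    "maryland": (20666, 50.7, (55.3, 25.8, 8.9, 9.8, 0.3), True, 31.4, 20.5, 4.4,
                 (53.9, 72.6, 54.8), 32.4, 11.8, 4.5, 33.3, (44.7, 17.7, 37.6), (36, 38.5), 30),
    "minnesota": (10081, 51.2, (51.1, 24.7, 14.3, 8.3, 1.7), True, 99.9, 27.5, 4.2,
                  (61.0, 82.3, 63.5), 18.4, 10.8, 3.6, 81.2, (28.9, 19.1, 52.0), (57, 72), 39),
    "missouri": (24481, 51.3, (65.6, 25.2, 5.1, 3.8, 0.2), False, 100.0, 16.5, 3.3,
                 (94.6, 26.4, 91.6), 34.1, 10.6, 2.5, 32.1, (26.2, 24.6, 49.2), (54, 74), 43),
    "new-jersey": (17289, 51.5, (28.0, 32.3, 33.8, 5.6, 0.3), True, 99.7, 28.4, 4.5,
                   (68.0, 69.9, 94.1), 25.5, 1.4, 0.4, 64.2, (34.6, 27.3, 38.1), (45, 44), 39),
    "tennessee": (25237, 51.2, (62.8, 19.6, 13.9, 3.3, 0.3), True, 85.4, 22.7, 4.1,
                  (77.1, 54.8, 74.3), 33.0, 8.4, 4.0, 62.8, (52.5, 19.2, 28.3), (34, 61.5), 43),
    "utah": (25459, 51.3, (71.1, 2.5, 21.2, 4.5, 0.6), True, 67.7, 21.5, 3.6,
             (82.8, 42.2, 71.9), 32.1, 4.2, 2.4, 37.8, (27.1, 31.9, 41.1), (47, 59), 42),
    "wisconsin": (29664, 50.9, (57.5, 19.4, 17.4, 5.2, 0.5), True, 100.0, 18.8, 4.2,
                  (84.2, 33.6, 84.6), 34.1, 12.9, 2.5, 39.3, (44.7, 20.5, 34.7), (42, 52), 39),
}

PRESET_NAMES = tuple(sorted(_SITE_TABLE))


def _race_mix(pcts: tuple) -> dict:
    values = [p / 100.0 for p in pcts]
    other = max(0.0, 1.0 - sum(values))
    values.append(other)
    total = sum(values)
    return {cat: v / total for cat, v in zip(RACE_CATEGORIES, values)}


def _site_preset(name: str) -> SiteConfig:
    (
        n, pct_male, races, has_edu, access, prev, mf_ratio,
        (p_icd, p_sped, p_dx), p_susp, p_ro, p_ro_recent, iq_avail,
        (b_low, b_mid, b_high), (dx_lo, dx_hi), eval_median,
    ) = _SITE_TABLE[name]
    bands = np.array([b_low, b_mid, b_high]) / 100.0
    bands = [float(b) for b in bands / bands.sum()]
    return SiteConfig(
        site_name=name,
        n_children=n,
        pct_male=pct_male / 100.0,
        race_mix=_race_mix(races),
        true_prevalence=prev / 1000.0,
        male_female_rate_ratio=mf_ratio,
        has_education_source=has_edu,
        record_accessible_fraction=access / 100.0,
        tract_count=max(3, n // 500),
        identification_mixture=mixture_from_marginals(
            p_dx / 100.0, p_sped / 100.0, p_icd / 100.0
        ),
        p_suspected_before_confirmed=p_susp / 100.0,
        p_ruled_out_ever=p_ro / 100.0,
        p_ruled_out_more_recent=p_ro_recent / 100.0,
        iq_available_fraction=iq_avail / 100.0,
        iq_band_probs={"<=70": bands[0], "71-85": bands[1], ">85": bands[2]},
        dx_age_months_distribution={
            "<=70": AgeDistribution(median=dx_lo),
            "71-85": AgeDistribution(median=dx_hi),
            ">85": AgeDistribution(median=dx_hi),
        },
        first_eval_age_months_distribution=AgeDistribution(median=eval_median, sigma=0.45),
    )


def scenario_preset(name: str) -> GeneratorConfig:
    """A single-site GeneratorConfig approximating one of the 11 sites.

    Raises :class:`ConfigurationError` listing valid names on an unknown
    preset.
    """
    key = name.strip().lower().replace(" ", "-").replace("_", "-")
    if key not in _SITE_TABLE:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    config = GeneratorConfig(sites=[_site_preset(key)])
    config.validate()
    return config


def network_preset() -> GeneratorConfig:
    """All 11 site presets combined into one network-scale configuration."""
    config = GeneratorConfig(sites=[_site_preset(name) for name in PRESET_NAMES])
    config.validate()
    return config
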