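"""Synthetic field-trial and genotype data with known ground truth.

The generator emulates the design of a multi-year pea heat-tolerance
screening: a germplasm panel of spring-sowing (SS) and winter-sowing (WS)
accessions sown at a normal date (NS, 1 March) and two late dates (LS1,
16 March; LS2, 31 March) so the reproductive phase of the late sowings runs
into summer heat.  Each accession carries a latent heat-tolerance class
(HT or HS) that drives its grain-weight loss under late sowing, and a SNP
panel with two marker sets: neutral loci differentiated between two
subpopulations (aligned with sowing type) under a Balding–Nichols model,
and heat-tolerance-related loci differentiated by the latent class.

All randomness flows through a mandatory integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from peaheat.divstats import MISSING_CALL, NEUTRAL, HT_RELATED, GenotypeMatrix

STAGES = ("NS", "LS1", "LS2")
#: Sowing day-of-month in March for NS / LS1 / LS2.
SOWING_DAYS = {"NS": 1, "LS1": 16, "LS2": 31}


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Daily mean temperature record for one site."""

    site_label: str
    dates: np.ndarray          # datetime64[D], strictly increasing, daily
    t_mean: np.ndarray         # °C

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.t_mean = np.asarray(self.t_mean, dtype=float)
        if self.dates.size != self.t_mean.size:
            raise ValueError("dates and t_mean must have equal length")
        if self.dates.size == 0:
            raise ValueError("empty temperature series")
        diffs = np.diff(self.dates).astype("timedelta64[D]").astype(int)
        if diffs.size and not np.all(diffs == 1):
            raise ValueError("dates must be strictly increasing with daily spacing")
        if not np.all(np.isfinite(self.t_mean)):
            raise ValueError("t_mean must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.astype(str), "t_mean": self.t_mean})

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t", site_label: str = "") -> "TemperatureSeries":
        df = pd.read_csv(path, sep=sep)
        return cls(site_label, df["date"].to_numpy(dtype="datetime64[D]"), df["t_mean"].to_numpy(float))


@dataclass
class TemperatureSimConfig:
    """Seasonal sinusoid + linear warming trend + iid Gaussian noise.

    Defaults describe a north-China-plain spring: ~5 °C on 1 March rising to
    ~27 °C by mid-July (annual mean 14 °C, amplitude 13 °C, peak at day 196).
    """

    seed: int
    site_label: str = "synthetic-site"
    year: int = 2018
    start: str = "03-01"
    end: str = "07-31"
    annual_mean: float = 14.0
    seasonal_amplitude: float = 13.0
    peak_doy: int = 196
    trend_per_day: float = 0.0
    noise_sd: float = 1.5


def simulate_temperatures(config: TemperatureSimConfig) -> TemperatureSeries:
    """Simulate a daily mean temperature series covering the trial season.

    The deterministic part is ``annual_mean + amplitude·cos(2π(doy−peak)/365)
    + trend·(day index)``; Gaussian noise is added on top.  With the default
    rising seasonal curve, any late-sowing growth window (16 March onward) is
    warmer in expectation than the same-length window 15 days earlier.
    """
    start = np.datetime64(f"{config.year}-{config.start}")
    end = np.datetime64(f"{config.year}-{config.end}")
    if end < start:
        raise ValueError("non-positive date span")
    n = int((end - start).astype(int)) + 1
    dates = start + np.arange(n).astype("timedelta64[D]")
    doy = (dates - np.datetime64(f"{config.year}-01-01")).astype(int) + 1
    det = (
        config.annual_mean
        + config.seasonal_amplitude * np.cos(2 * np.pi * (doy - config.peak_doy) / 365.0)
        + config.trend_per_day * np.arange(n)
    )
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    return TemperatureSeries(config.site_label, dates, det + noise)


# ---------------------------------------------------------------------------
# field-trial phenotypes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanelConfig:
    """Panel design and effect sizes for the phenotype generator.

    ``effect`` is the separation (percentage points of grain-weight loss)
    between the latent HT and HS class means under late sowing; ``noise_sd``
    is the accession × stage loss noise in points.  Survival probabilities
    default to the mean field survival rates observed NS/LS1/LS2 in a large
    first-round screening (61.8 / 47.4 / 28.5%).
    """

    n_accessions: int
    seed: int
    prop_ss: float = 0.55
    prop_ht_latent: float = 0.5
    effect: float = 60.0
    noise_sd: float = 5.0
    reps_per_stage: int = 1
    sown: int = 10
    plants_weighed: int = 5
    weight_median: float = 25.0      # g, NS per-plant grain weight median
    weight_log_sd: float = 0.5       # accession-level lognormal sd
    plant_cv: float = 0.10           # within-accession plant-to-plant cv
    stage_shift_ls2: float = 5.0     # extra loss (points) at LS2 vs LS1
    loss_centre: float = 50.0        # midpoint between class means
    survival_p: tuple[float, float, float] = (0.618, 0.474, 0.285)
    missing_stage_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be ≥ 2")
        if self.reps_per_stage < 1:
            raise ValueError("reps_per_stage must be ≥ 1")
        for frac in (self.prop_ss, self.prop_ht_latent):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class SimulatedTrial:
    """One simulated screening round plus the hidden truth table."""

    records: pd.DataFrame     # trial table, one row per accession×stage×replicate
    truth: pd.DataFrame       # accession_id, latent_class, sowing_type, origin
    n_truncated: int          # loss-scale draws that fell outside [0, 100] pre-squash

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        self.records.to_csv(path, sep=sep, index=False)


def _loss_fraction(g: np.ndarray) -> np.ndarray:
    """Squash a percent-scale loss score into (0, 1).

    Logistic transform centred at 50 with unit slope there, so mid-range
    scores map almost linearly while extremes are pinned inside the valid
    loss range.
    """
    return expit((np.asarray(g, float) - 50.0) / 25.0)


def read_trial_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"accession": str, "plant_weights": str})
    return df


def simulate_trial(
    panel: SyntheticPanelConfig,
    temps: TemperatureSeries | None = None,
    round_no: int = 1,
    accession_ids: Sequence[str] | None = None,
    latent_class: Sequence[str] | None = None,
) -> SimulatedTrial:
    """Simulate one screening round of field phenotypes.

    Per accession the NS per-plant grain weight is lognormal; LS1/LS2
    weights are the NS weight times ``1 − loss`` where the loss score is
    class mean + stage shift + Gaussian noise squashed through a logistic,
    so losses always lie in (0, 1).  Survivors out of ``sown`` seeds are
    binomial with stage-specific survival probability; phenology dates obey
    sowing < flowering < maturity.

    ``accession_ids`` / ``latent_class`` allow carrying a fixed panel into
    later rounds; by default a fresh panel is drawn from the config.
    """
    rng = np.random.default_rng(panel.seed)
    n = panel.n_accessions if accession_ids is None else len(accession_ids)
    if accession_ids is None:
        accession_ids = [f"G{i + 1:04d}" for i in range(n)]
    if latent_class is None:
        latent_class = np.where(rng.random(n) < panel.prop_ht_latent, "HT", "HS")
    else:
        latent_class = np.asarray(latent_class)
    sowing_type = np.where(rng.random(n) < panel.prop_ss, "SS", "WS")
    # geographic origin loosely tied to sowing type (SS mostly north)
    origin = np.where(
        rng.random(n) < np.where(sowing_type == "SS", 0.85, 0.15), "NorthChina", "SouthChina"
    )

    # align the trial calendar with the temperature series when one is given
    year = int(str(temps.dates[0])[:4]) if temps is not None else 2016 + round_no
    ns_median = panel.weight_median * np.exp(rng.normal(0.0, panel.weight_log_sd, size=n))
    half = panel.effect / 2.0
    class_mean = np.where(np.asarray(latent_class) == "HT", panel.loss_centre - half, panel.loss_centre + half)

    n_truncated = 0
    rows = []
    for si, stage in enumerate(STAGES):
        sow_date = dt.date(year, 3, SOWING_DAYS[stage])
        if stage == "NS":
            loss = np.zeros(n)
        else:
            g = class_mean + (panel.stage_shift_ls2 if stage == "LS2" else 0.0)
            g = g + rng.normal(0.0, panel.noise_sd, size=n)
            n_truncated += int(np.sum((g < 0.0) | (g > 100.0)))
            loss = _loss_fraction(g)
        stage_weight = ns_median * (1.0 - loss)
        # phenology: later sowing flowers a little sooner after sowing and
        # matures faster under heat
        flower_days = np.clip(np.round(rng.normal(68 - 4 * si, 3, size=n)), 30, None).astype(int)
        fill_days = np.clip(np.round(rng.normal(36 - 5 * si, 3, size=n)), 10, None).astype(int)
        hgw = np.clip(rng.normal(20.0, 2.0, size=n) * (1.0 - 0.5 * loss), 0.1, None)
        for r in range(1, panel.reps_per_stage + 1):
            survivors = rng.binomial(panel.sown, panel.survival_p[si], size=n)
            for i, acc in enumerate(accession_ids):
                if panel.missing_stage_rate > 0 and rng.random() < panel.missing_stage_rate:
                    continue
                n_weigh = min(panel.plants_weighed, survivors[i])
                weights = stage_weight[i] * np.exp(
                    rng.normal(0.0, panel.plant_cv, size=n_weigh) - 0.5 * panel.plant_cv**2
                )
                fdate = sow_date + dt.timedelta(days=int(flower_days[i]))
                mdate = fdate + dt.timedelta(days=int(fill_days[i]))
                rows.append(
                    {
                        "accession": acc,
                        "round": round_no,
                        "stage": stage,
                        "replicate": r,
                        "sown": panel.sown,
                        "survivors": int(survivors[i]),
                        "plant_weights": ";".join(f"{w:.4f}" for w in weights),
                        "flowering_date": fdate.isoformat(),
                        "maturity_date": mdate.isoformat(),
                        "hundred_grain_weight": round(float(hgw[i]), 4),
                    }
                )
    records = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "accession": list(accession_ids),
            "latent_class": list(latent_class),
            "sowing_type": sowing_type,
            "origin": origin,
        }
    )
    return SimulatedTrial(records=records, truth=truth, n_truncated=n_truncated)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSimConfig:
    """Balding–Nichols genotype simulation parameters.

    ``fst`` controls the dispersion of per-group allele frequencies around
    the ancestral frequency; ``prop_triallelic`` is the fraction of loci
    given a third allele (SNP panels in legumes carry a minority of
    tri-allelic calls).
    """

    n_markers_neutral: int
    n_markers_ht: int
    fst: float
    seed: int
    missing_rate: float = 0.0
    prop_triallelic: float = 0.1
    ancestral_low: float = 0.2
    ancestral_high: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


_BASES = np.array(["A", "C", "G", "T"])


def _balding_nichols_freqs(rng: np.random.Generator, p_anc: np.ndarray, fst: float, n_groups: int) -> np.ndarray:
    """Per-group allele frequencies ~ Dirichlet(p_anc (1−F)/F), one draw per group."""
    scale = (1.0 - fst) / fst
    return np.stack([rng.dirichlet(p_anc * scale) for _ in range(n_groups)])


def simulate_genotypes(
    metadata: pd.DataFrame, config: GenotypeSimConfig, return_truth: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict]:
    """Simulate a two-set SNP panel over the accessions in ``metadata``.

    ``metadata`` needs columns ``accession``, ``subpopulation`` (drives the
    neutral markers) and ``latent_class`` (drives the heat-tolerance-related
    markers).  For each locus an ancestral frequency vector is drawn, then
    per-group frequencies from the Balding–Nichols Dirichlet, and genotypes
    under within-group random mating.  Missing calls are masked at
    ``missing_rate``.

    With ``return_truth=True`` also returns the drawn per-group allele
    frequencies, keyed by marker id, as ``{"groups": [...], "alleles":
    [...], "freqs": array (groups × alleles)}`` — the generator's ground
    truth for calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    accs = metadata["accession"].to_list()
    n = len(accs)
    truth: dict[str, dict] = {}

    def _simulate_set(n_markers: int, labels: np.ndarray, prefix: str) -> dict[str, list[str]]:
        groups = sorted(set(labels))
        if len(groups) < 2:
            raise ValueError(f"need ≥ 2 groups to differentiate markers ({prefix}); got {groups}")
        gidx = np.array([groups.index(l) for l in labels])
        cols: dict[str, list[str]] = {}
        for m in range(n_markers):
            k = 3 if rng.random() < config.prop_triallelic else 2
            alleles = rng.choice(_BASES, size=k, replace=False)
            if k == 2:
                p = rng.uniform(config.ancestral_low, config.ancestral_high)
                p_anc = np.array([p, 1.0 - p])
            else:
                p_anc = rng.dirichlet(np.full(k, 2.0))
            freqs = _balding_nichols_freqs(rng, p_anc, config.fst, len(groups))
            truth[f"{prefix}{m + 1:03d}"] = {
                "groups": list(groups), "alleles": [str(a) for a in alleles], "freqs": freqs,
            }
            cells = []
            for i in range(n):
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    cells.append(MISSING_CALL)
                    continue
                f = freqs[gidx[i]]
                a, b = rng.choice(k, size=2, p=f)
                pair = sorted([alleles[a], alleles[b]])
                cells.append(f"{pair[0]}/{pair[1]}")
            cols[f"{prefix}{m + 1:03d}"] = cells
        return cols

    neutral = _simulate_set(config.n_markers_neutral, metadata["subpopulation"].to_numpy(), "N")
    htrel = _simulate_set(config.n_markers_ht, metadata["latent_class"].to_numpy(), "H")
    df = pd.DataFrame({**neutral, **htrel}, index=accs)
    marker_set = {m: NEUTRAL for m in neutral} | {m: HT_RELATED for m in htrel}
    matrix = GenotypeMatrix(df, marker_set)
    if return_truth:
        return matrix, truth
    return matrix


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run config; a top-level integer ``seed`` is mandatory."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with a mandatory 'seed'")
    return cfg
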