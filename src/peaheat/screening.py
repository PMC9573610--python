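"""Heat-tolerance screening of germplasm from grain-weight loss under late sowing.

The screen compares each accession's average grain weight per plant under
normal sowing (``W_NS``) with the two late sowings (``W_LS1``, ``W_LS2``)
and scores the loss rates::

    LR1 (%) = [1 − (W_LS1 / W_NS)] × 100
    LR2 (%) = [1 − (W_LS2 / W_NS)] × 100

Accessions whose two loss rates differ by more than 40 points are excluded
as inconsistent; the rest are placed on a nine-level scale built from
20-point bands of (LR1, LR2).  Levels 1–3 are heat-tolerant (HT), 7–9
heat-sensitive (HS).  Iterating the screen over successive years, carrying
forward only HT and HS accessions, yields "extremely" tolerant/sensitive
sets and a cross-round consistency set.

The main entry point is :class:`HeatScreeningModel` (one round) /
:func:`iterative_screening` (multi-round); the individual statistics are
exposed as plain functions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov

STAGES = ("NS", "LS1", "LS2")
EXCLUDED = "EXCLUDED"
HT = "HT"
HS = "HS"
INTERMEDIATE = "INTERMEDIATE"

#: Loss-rate band edges; each 20-point band contributes its index (0–4) to
#: the level, level = band(LR1) + band(LR2) + 1.  Ties at the edges fall in
#: the lower band.
_BAND_EDGES = (20.0, 40.0, 60.0, 80.0)
#: Exclusion threshold on |LR1 − LR2| (points).
LR_DIFF_LIMIT = 40.0


@dataclass
class TrialRecord:
    """One accession × round × stage × replicate field observation."""

    accession_id: str
    round: int
    stage: str
    replicate: int
    survivors: int
    plant_weights: list[float]
    sown: int = 10
    flowering_date: str | None = None
    maturity_date: str | None = None
    hundred_grain_weight: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not 0 <= self.survivors <= self.sown:
            raise ValueError("require 0 ≤ survivors ≤ sown")
        if any(w < 0 for w in self.plant_weights):
            raise ValueError("plant weights must be ≥ 0")


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "accession": r.accession_id,
                "round": r.round,
                "stage": r.stage,
                "replicate": r.replicate,
                "sown": r.sown,
                "survivors": r.survivors,
                "plant_weights": ";".join(f"{w:g}" for w in r.plant_weights),
                "flowering_date": r.flowering_date,
                "maturity_date": r.maturity_date,
                "hundred_grain_weight": r.hundred_grain_weight,
            }
        )
    return pd.DataFrame(rows)


def _parse_weights(cell) -> list[float]:
    if isinstance(cell, (list, tuple, np.ndarray)):
        return [float(w) for w in cell]
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    return [float(w) for w in str(cell).split(";") if w != ""]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def field_survival_rate(survivors_per_rep: Sequence[int], sown: int = 10) -> float:
    """Field survival rate (%): total survivors over total seeds sown.

    With *n* replicates of ``sown`` seeds each, FSR = Σ survivors /
    (n · sown) × 100, so the single-replicate first screening and the
    three-replicate later screenings use the same estimator.
    """
    reps = list(survivors_per_rep)
    if not reps:
        raise ValueError("need at least one replicate count")
    if any(s < 0 or s > sown for s in reps):
        raise ValueError("survivors must be within [0, sown]")
    return 100.0 * sum(reps) / (sown * len(reps))


def grain_filling_rate(hundred_grain_weight: float, flowering_date, maturity_date) -> float:
    """Grain filling rate (g/day): hundred-grain weight over the flowering → maturity span."""
    f = np.datetime64(flowering_date, "D")
    m = np.datetime64(maturity_date, "D")
    days = int((m - f).astype(int))
    if days <= 0:
        raise ValueError("maturity must be after flowering")
    return float(hundred_grain_weight) / days


def mean_grain_weight(plant_weights_per_rep: Sequence[Sequence[float]], max_plants: int = 5) -> float | None:
    """Average grain weight per plant: per-replicate mean of up to ``max_plants`` plants, averaged over replicates.

    Replicates without surviving weighed plants are skipped; returns ``None``
    when no replicate has any weight (the accession is unscoreable for the
    stage).
    """
    rep_means = []
    for weights in plant_weights_per_rep:
        w = list(weights)[:max_plants]
        if w:
            rep_means.append(float(np.mean(w)))
    if not rep_means:
        return None
    return float(np.mean(rep_means))


def loss_rates(w_ns: float, w_ls1: float, w_ls2: float) -> tuple[float, float]:
    """Loss rates LR1/LR2 (%) relative to normal sowing, clamped to [0, 100].

    A late-sown yield *gain* (negative raw loss) clamps to 0: the
    classification's domain starts at "no loss".
    """
    if w_ns is None or w_ns <= 0:
        raise ValueError("W_NS must be positive to score loss rates")
    lr1 = (1.0 - w_ls1 / w_ns) * 100.0
    lr2 = (1.0 - w_ls2 / w_ns) * 100.0
    return (min(100.0, max(0.0, lr1)), min(100.0, max(0.0, lr2)))


def _band(lr: float) -> int:
    for i, edge in enumerate(_BAND_EDGES):
        if lr <= edge:
            return i
    return len(_BAND_EDGES)


def classify_level(lr1: float, lr2: float):
    """Nine-level heat-tolerance class from the two loss rates.

    Each loss rate falls in one of five 20-point bands (0 ≤ LR ≤ 20 is band
    0, 20 < LR ≤ 40 band 1, …); the level is the band-index sum plus one,
    which reproduces the printed rule table (level *k* collects the band
    pairs summing to *k* − 1).  Accessions with |LR1 − LR2| > 40 are
    ``EXCLUDED`` as inconsistent between the two late sowings.
    """
    for lr in (lr1, lr2):
        if not 0.0 <= lr <= 100.0:
            raise ValueError(f"loss rate outside [0, 100]: {lr}")
    if abs(lr1 - lr2) > LR_DIFF_LIMIT:
        return EXCLUDED
    return _band(lr1) + _band(lr2) + 1


def categorize(level) -> str:
    """HT for levels 1–3, HS for 7–9, INTERMEDIATE for 4–6."""
    if level == EXCLUDED:
        raise ValueError("excluded accessions have no category")
    if level not in range(1, 10):
        raise ValueError(f"level must be 1..9, got {level!r}")
    if level <= 3:
        return HT
    if level >= 7:
        return HS
    return INTERMEDIATE


class KSNormality(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def ks_normality(levels: Sequence[float]) -> KSNormality:
    """One-sample Kolmogorov–Smirnov test of the level values against a
    normal with the sample mean and standard deviation.

    The p-value is the plain asymptotic Kolmogorov-series probability (no
    Lilliefors correction), i.e. the SPSS-style one-sample KS output.  Zero
    sample variance makes the test undefined and is flagged.
    """
    x = np.sort(np.asarray(levels, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need ≥ 5 classified accessions for the KS test")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return KSNormality(float("nan"), float("nan"), True)
    cdf = stats.norm.cdf(x, loc=float(np.mean(x)), scale=sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    d = float(max(d_plus, d_minus))
    p = float(kolmogorov(math.sqrt(n) * d))
    return KSNormality(d, p, False)


def compare_gfr(results: pd.DataFrame, groups: tuple[str, str] = (HT, HS)) -> pd.DataFrame:
    """One-way ANOVA of grain filling rate between categories, per stage.

    Returns a table with F and p for each stage where every requested group
    has ≥ 2 scored accessions.
    """
    rows = []
    for stage in STAGES:
        col = f"GFR_{stage}"
        if col not in results.columns:
            continue
        samples = []
        for g in groups:
            vals = results.loc[results["category"] == g, col].dropna().to_numpy(float)
            samples.append(vals)
        if any(len(v) < 2 for v in samples):
            raise ValueError(f"each group needs ≥ 2 GFR values at stage {stage}")
        f, p = stats.f_oneway(*samples)
        rows.append({"stage": stage, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# round summary / model
# ---------------------------------------------------------------------------

@dataclass
class RoundSummary:
    level_counts: dict[int, int]
    ks_statistic: float
    ks_p: float
    ks_degenerate: bool
    n_classified: int
    n_excluded: int
    n_ht: int
    n_hs: int


class HeatScreeningModel:
    """One screening round, fitted from a trial table.

    Parameters
    ----------
    trials : DataFrame or iterable of TrialRecord
        Trial observations with columns ``accession, round, stage,
        replicate, sown, survivors, plant_weights, flowering_date,
        maturity_date, hundred_grain_weight`` (the on-disk schema).
    max_plants : int
        Plants weighed per replicate when averaging grain weight
        (five mature plants by design).
    """

    def __init__(self, trials, max_plants: int = 5):
        if not isinstance(trials, pd.DataFrame):
            trials = records_to_frame(trials)
        if trials.empty:
            raise ValueError("empty trial dataset")
        self.trials = trials.copy()
        self.trials["accession"] = self.trials["accession"].astype(str)
        self.max_plants = max_plants

    def fit(self) -> "HeatScreeningResults":
        per_acc_rows = []
        exclusions = []
        for acc, grp in self.trials.groupby("accession", sort=True):
            row: dict = {"accession": acc}
            w: dict[str, float | None] = {}
            for stage in STAGES:
                sub = grp[grp["stage"] == stage]
                if sub.empty:
                    w[stage] = None
                    row[f"W_{stage}"] = np.nan
                    row[f"FSR_{stage}"] = np.nan
                    row[f"GFR_{stage}"] = np.nan
                    continue
                weights = [_parse_weights(c) for c in sub["plant_weights"]]
                w[stage] = mean_grain_weight(weights, self.max_plants)
                row[f"W_{stage}"] = np.nan if w[stage] is None else w[stage]
                row[f"FSR_{stage}"] = field_survival_rate(
                    sub["survivors"].to_list(), int(sub["sown"].iloc[0])
                )
                row[f"GFR_{stage}"] = self._stage_gfr(sub)
            reason = None
            if w["NS"] is None:
                reason = "W_NS_MISSING"
            elif w["NS"] <= 0:
                reason = "W_NS_NONPOSITIVE"
            elif w["LS1"] is None or w["LS2"] is None:
                reason = "MISSING_LATE_STAGE"
            if reason is not None:
                exclusions.append({"accession": acc, "reason": reason})
                row.update({"LR1": np.nan, "LR2": np.nan, "level": EXCLUDED, "category": None})
                per_acc_rows.append(row)
                continue
            lr1, lr2 = loss_rates(w["NS"], w["LS1"], w["LS2"])
            level = classify_level(lr1, lr2)
            row["LR1"], row["LR2"] = lr1, lr2
            row["level"] = level
            if level == EXCLUDED:
                exclusions.append({"accession": acc, "reason": "LR_DIFF_GT_40"})
                row["category"] = None
            else:
                row["category"] = categorize(level)
            per_acc_rows.append(row)
        results = pd.DataFrame(per_acc_rows)
        levels = [l for l in results["level"] if l != EXCLUDED]
        counts = Counter(levels)
        if len(levels) >= 5:
            ks = ks_normality(levels)
        else:
            ks = KSNormality(float("nan"), float("nan"), True)
        summary = RoundSummary(
            level_counts={k: counts.get(k, 0) for k in range(1, 10)},
            ks_statistic=ks.statistic,
            ks_p=ks.pvalue,
            ks_degenerate=ks.degenerate,
            n_classified=len(levels),
            n_excluded=len(results) - len(levels),
            n_ht=int((results["category"] == HT).sum()),
            n_hs=int((results["category"] == HS).sum()),
        )
        return HeatScreeningResults(self, results, summary, pd.DataFrame(exclusions, columns=["accession", "reason"]))

    def _stage_gfr(self, sub: pd.DataFrame) -> float:
        vals = []
        for _, r in sub.iterrows():
            hgw, f, m = r.get("hundred_grain_weight"), r.get("flowering_date"), r.get("maturity_date")
            if pd.isna(hgw) or pd.isna(f) or pd.isna(m):
                continue
            vals.append(grain_filling_rate(float(hgw), f, m))
        return float(np.mean(vals)) if vals else np.nan


class HeatScreeningResults:
    """Per-accession scores and the round summary for one screening round."""

    def __init__(self, model: HeatScreeningModel, results: pd.DataFrame, round_summary: RoundSummary,
                 exclusions: pd.DataFrame):
        self.model = model
        self.results = results
        self.round_summary = round_summary
        self.exclusions = exclusions

    @property
    def ht_accessions(self) -> list[str]:
        return self.results.loc[self.results["category"] == HT, "accession"].to_list()

    @property
    def hs_accessions(self) -> list[str]:
        return self.results.loc[self.results["category"] == HS, "accession"].to_list()

    def summary(self) -> str:
        s = self.round_summary
        lines = [
            "Heat-tolerance screening round summary",
            "=" * 44,
            f"accessions scored     : {len(self.results)}",
            f"classified (levels)   : {s.n_classified}",
            f"excluded              : {s.n_excluded}",
            f"heat-tolerant (1-3)   : {s.n_ht}",
            f"heat-sensitive (7-9)  : {s.n_hs}",
            "level histogram       : "
            + " ".join(f"{k}:{s.level_counts[k]}" for k in range(1, 10)),
        ]
        if not s.ks_degenerate:
            lines.append(f"KS normality          : D = {s.ks_statistic:.4f}, p = {s.ks_p:.3f}")
        else:
            lines.append("KS normality          : undefined (degenerate sample)")
        return "\n".join(lines)


def run_round(trials) -> tuple[pd.DataFrame, RoundSummary, pd.DataFrame]:
    """Functional wrapper: fit one round, return (results, summary, exclusion ledger)."""
    res = HeatScreeningModel(trials).fit()
    return res.results, res.round_summary, res.exclusions


# ---------------------------------------------------------------------------
# iterative screening
# ---------------------------------------------------------------------------

@dataclass
class IterativeScreeningResult:
    rounds: list[HeatScreeningResults]
    final_ht: list[str]            # "extremely HT" after the last round
    final_hs: list[str]            # "extremely HS"
    consistency_set: list[str]     # same HT/HS category in every round they appear
    carry_forward_violations: list[str] = field(default_factory=list)


def iterative_screening(round_tables: Sequence[pd.DataFrame]) -> IterativeScreeningResult:
    """Run successive screening rounds with HT/HS carry-forward.

    Round *r*+1 is expected to contain only accessions categorised HT or HS
    in round *r*; violations are reported, not rejected (simulated rounds
    may deliberately re-screen everything).  The last round's HT and HS sets
    are the extreme sets; the consistency set holds accessions with the same
    HT/HS category in every round in which they appear.
    """
    if not round_tables:
        raise ValueError("need at least one round")
    fitted: list[HeatScreeningResults] = []
    violations: list[str] = []
    prev_extreme: set[str] | None = None
    prev_accessions: set[str] | None = None
    for tbl in round_tables:
        res = HeatScreeningModel(tbl).fit()
        accs = set(res.results["accession"])
        if prev_accessions is not None and not (accs & prev_accessions):
            raise ValueError("round accession sets are disjoint; not an iterative screen")
        if prev_extreme is not None:
            violations.extend(sorted(accs - prev_extreme))
        prev_extreme = set(res.ht_accessions) | set(res.hs_accessions)
        prev_accessions = accs
        fitted.append(res)

    category_history: dict[str, list[str]] = {}
    for res in fitted:
        for _, r in res.results.iterrows():
            if r["category"] in (HT, HS):
                category_history.setdefault(r["accession"], []).append(r["category"])
            elif r["category"] is not None or r["level"] == EXCLUDED:
                category_history.setdefault(r["accession"], []).append("OTHER")
    n_rounds_seen = {
        acc: sum(acc in set(res.results["accession"]) for res in fitted) for acc in category_history
    }
    consistency = sorted(
        acc
        for acc, hist in category_history.items()
        if len(hist) == n_rounds_seen[acc] and len(set(hist)) == 1 and hist[0] in (HT, HS)
    )
    last = fitted[-1]
    return IterativeScreeningResult(
        rounds=fitted,
        final_ht=sorted(last.ht_accessions),
        final_hs=sorted(last.hs_accessions),
        consistency_set=consistency,
        carry_forward_violations=sorted(set(violations)),
    )
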