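"""Climate-dissimilarity arithmetic and the exposure / sensitivity / risk
rule engines.

Exposure (levels 1-4) combines the ecological-niche-model (ENM) suitability
change with the dissimilarity in maximum temperature and summer rainfall
between the current and future time slices:

  temperature increase:  low < 6 degC, medium 6-8, high > 8;
  rainfall decrease:     low < 25%, medium 25-50%, high > 50%;
  ENM: relative occurrence-probability change </> 25%, and whether the
  area stays climatically suitable or flips to unsuitable.

  level 4: unsuitable AND (temp high OR rain high)
  level 3: unsuitable OR temp high OR rain high
  level 2: remains suitable AND ENM change > 25% AND (temp OR rain medium)
  level 1: remains suitable AND ENM change < 25% AND temp low AND rain low

Levels are evaluated top-down and the highest satisfied level wins.  Some
combinations satisfy no formula exactly; the documented fallback assigns
level 1 when the ENM change is small and the area stays suitable, else the
nearest lower level, and flags the record as a rule mismatch.

Sensitivity combines an adaptive code (frequency of climate-adaptive
alleles: ++/+/0/-) with a neutral code (heterozygosity bins: +/0/-) by an
additive score; risk integrates exposure, overall sensitivity and the
range-shift flag, weighting exposure highest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ----------------------------------------------------------------------
# Dissimilarity arithmetic
# ----------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used in reported tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class ExposureRecord:
    pop: str
    tmax_now: float
    tmax_future: float
    rain_now: float
    rain_future: float
    suit_now: float
    suit_future: float
    suitable_now: bool
    suitable_future: bool

    @property
    def delta_tmax(self) -> float:
        return round_half_away(self.tmax_future - self.tmax_now)

    @property
    def delta_rain(self) -> float:
        return round_half_away(self.rain_future - self.rain_now)

    @property
    def pct_change_rain(self) -> float:
        if self.rain_now == 0:
            raise ZeroDivisionError("percent change undefined: current rain is 0")
        return round_half_away(
            100.0 * (self.rain_future - self.rain_now) / self.rain_now)

    @property
    def pct_change_suit(self) -> float:
        if self.suit_now == 0:
            raise ZeroDivisionError("percent change undefined: current ENM is 0")
        return round_half_away(
            100.0 * (self.suit_future - self.suit_now) / self.suit_now)


def climate_dissimilarity(now: float, future: float,
                          as_percent: bool = False) -> float:
    """future - now, or 100*(future - now)/now, rounded to one decimal
    (half away from zero)."""
    if as_percent:
        if now == 0:
            raise ZeroDivisionError("percent change undefined for baseline 0")
        return round_half_away(100.0 * (future - now) / now)
    return round_half_away(future - now)


# ----------------------------------------------------------------------
# ENM thresholding (max sensitivity + specificity)
# ----------------------------------------------------------------------

def max_sss_threshold(presence: np.ndarray, background: np.ndarray) -> float:
    """Suitability cut-off maximizing sensitivity + specificity.

    Candidates are the observed values; a cell is classified suitable when
    its value >= threshold.  Ties break toward the lower threshold.
    """
    presence = np.asarray(presence, float)
    background = np.asarray(background, float)
    if presence.size == 0 or background.size == 0:
        raise ValueError("need at least one presence and one background value")
    values = np.unique(np.concatenate([presence, background]))
    if values.size == 1:
        raise ValueError("degenerate input: all suitability values identical")
    best_t, best_score = None, -np.inf
    for t in values:  # ascending, so ties keep the lower threshold
        sens = float(np.mean(presence >= t))
        spec = float(np.mean(background < t))
        if sens + spec > best_score + 1e-12:
            best_score, best_t = sens + spec, float(t)
    return best_t


# ----------------------------------------------------------------------
# Exposure engine
# ----------------------------------------------------------------------

TEMP_BINS = (6.0, 8.0)       # degC increase: low < 6, medium 6-8, high > 8
RAIN_BINS = (25.0, 50.0)     # % decrease:   low < 25, medium 25-50, high > 50
ENM_CHANGE_CUT = 25.0        # % |change| in relative occurrence probability


def _temp_class(delta_tmax: float) -> str:
    if delta_tmax > TEMP_BINS[1]:
        return "high"
    if delta_tmax >= TEMP_BINS[0]:
        return "medium"
    return "low"


def _rain_class(pct_change_rain: float) -> str:
    decrease = -pct_change_rain if pct_change_rain < 0 else 0.0
    if decrease > RAIN_BINS[1]:
        return "high"
    if decrease >= RAIN_BINS[0]:
        return "medium"
    return "low"


@dataclass
class ExposureAssessment:
    pop: str
    level: int
    temp_class: str
    rain_class: str
    rule_path: str
    rule_mismatch: bool


def exposure_level(record: ExposureRecord) -> ExposureAssessment:
    """Assign the exposure level 1-4, highest satisfied formula first."""
    t = _temp_class(record.delta_tmax)
    r = _rain_class(record.pct_change_rain)
    became_unsuitable = record.suitable_now and not record.suitable_future
    remains_suitable = record.suitable_now and record.suitable_future
    enm_small = abs(record.pct_change_suit) < ENM_CHANGE_CUT

    if became_unsuitable and (t == "high" or r == "high"):
        return ExposureAssessment(record.pop, 4, t, r,
                                  "unsuitable + (temp|rain high)", False)
    if became_unsuitable or t == "high" or r == "high":
        return ExposureAssessment(record.pop, 3, t, r,
                                  "unsuitable | temp high | rain high", False)
    if remains_suitable and not enm_small and (t == "medium" or r == "medium"):
        return ExposureAssessment(record.pop, 2, t, r,
                                  "suitable + ENM>25% + (temp|rain medium)", False)
    if remains_suitable and enm_small and t == "low" and r == "low":
        return ExposureAssessment(record.pop, 1, t, r,
                                  "suitable + ENM<25% + temp low + rain low", False)
    # no formula satisfied exactly: documented fallback, flagged
    if remains_suitable and enm_small:
        return ExposureAssessment(record.pop, 1, t, r,
                                  "fallback: suitable, small ENM change", True)
    if remains_suitable:
        return ExposureAssessment(record.pop, 2, t, r,
                                  "fallback: suitable, large ENM change", True)
    return ExposureAssessment(record.pop, 1, t, r, "fallback: lowest level", True)


# ----------------------------------------------------------------------
# Sensitivity engines
# ----------------------------------------------------------------------

def adaptive_sensitivity(mean_freq: float, fraction_below_025: float) -> str:
    """Code the adaptive-allele frequency profile: ++, +, 0 or -.

    ++ : mean adaptive-allele frequency < 0.5, > 1/3 of loci below 0.25;
    +  : mean < 0.5, at most 1/3 below 0.25;
    0  : mean >= 0.5 but at least one low-frequency adaptive allele;
    -  : mean > 0.5 (boundary 0.5 included) and none below 0.25.
    """
    if not (0 <= mean_freq <= 1 and 0 <= fraction_below_025 <= 1):
        raise ValueError("inputs must lie in [0, 1]")
    if mean_freq < 0.5:
        return "++" if fraction_below_025 > 1 / 3 else "+"
    return "0" if fraction_below_025 > 0 else "-"


def neutral_sensitivity(heterozygosity: float) -> str:
    """Code neutral diversity: high diversity (>0.9) is low sensitivity '-',
    0.75-0.9 is '0', below 0.75 is high sensitivity '+'."""
    if not 0 <= heterozygosity <= 1:
        raise ValueError("heterozygosity must lie in [0, 1]")
    if heterozygosity > 0.9:
        return "-"
    if heterozygosity >= 0.75:
        return "0"
    return "+"


_SENS_SCORE = {"++": 2, "+": 1, "0": 0, "-": -1}


def combine_sensitivity(adaptive_code: str, neutral_code: str) -> str:
    """Additive combination of the adaptive and neutral codes.

    Scores ++ -> 2, + -> 1, 0 -> 0, - -> -1 are summed; overall is '+'
    when the sum >= 1, '0' at 0, '-' at <= -1.
    """
    for code, allowed in ((adaptive_code, ("++", "+", "0", "-")),
                          (neutral_code, ("+", "0", "-"))):
        if code not in allowed:
            raise ValueError(f"invalid sensitivity code {code!r}")
    s = _SENS_SCORE[adaptive_code] + _SENS_SCORE[neutral_code]
    return "+" if s >= 1 else ("0" if s == 0 else "-")


# ----------------------------------------------------------------------
# Risk engine
# ----------------------------------------------------------------------

RISK_ORDER = ["Low", "Medium", "Medium-high", "High"]


@dataclass
class RiskAssessment:
    pop: str
    exposure: int
    sensitivity: str
    range_shift: str
    risk: str
    rule_path: str


def risk_level(exposure: int, sensitivity: str, range_shift: str,
               pop: str = "") -> RiskAssessment:
    """Integrate the three components, rules evaluated High -> Low.

    Combinations covered by no rule return risk "Unclassified" with a
    diagnostic path (never silently classified).
    """
    if exposure not in (1, 2, 3, 4):
        raise ValueError("exposure must be 1-4")
    if sensitivity not in ("+", "0", "-"):
        raise ValueError("overall sensitivity must be +, 0 or -")
    if range_shift not in ("+", "-"):
        raise ValueError("range-shift flag must be + or -")

    if exposure in (3, 4) and sensitivity == "+" and range_shift == "-":
        return RiskAssessment(pop, exposure, sensitivity, range_shift, "High",
                              "exp 3-4 + sens high + range low")
    if exposure in (3, 4) and (sensitivity == "+" or range_shift == "-"):
        return RiskAssessment(pop, exposure, sensitivity, range_shift,
                              "Medium-high", "exp 3-4 + (sens high | range low)")
    if exposure == 2 and (sensitivity in ("0", "+") or range_shift == "-"):
        return RiskAssessment(pop, exposure, sensitivity, range_shift, "Medium",
                              "exp 2 + (sens mid-high | range low)")
    if exposure == 3 and sensitivity in ("-", "0") and range_shift == "+":
        return RiskAssessment(pop, exposure, sensitivity, range_shift, "Medium",
                              "exp 3 + sens low-mid + range high")
    if exposure == 1 and (sensitivity == "-" or range_shift == "+"):
        return RiskAssessment(pop, exposure, sensitivity, range_shift, "Low",
                              "exp 1 + (sens low | range high)")
    if exposure == 2 and sensitivity == "-" and range_shift == "+":
        return RiskAssessment(pop, exposure, sensitivity, range_shift, "Low",
                              "exp 2 + sens low + range high")
    return RiskAssessment(pop, exposure, sensitivity, range_shift,
                          "Unclassified",
                          f"no rule covers (exp={exposure}, sens={sensitivity}, "
                          f"range={range_shift})")


def assess(exposures: pd.DataFrame, sensitivities: pd.DataFrame,
           range_flags: pd.DataFrame) -> pd.DataFrame:
    """Join the three per-population components into the final risk table.

    Expects columns: exposures[pop, exposure]; sensitivities[pop,
    adaptive_code, neutral_code] (or an overall 'sensitivity' column);
    range_flags[pop, range_shift].
    """
    for df, col in ((exposures, "exposure"), (range_flags, "range_shift")):
        if "pop" not in df.columns or col not in df.columns:
            raise ValueError(f"missing column {col!r} or 'pop'")
    ids = set(exposures["pop"])
    if ids != set(sensitivities["pop"]) or ids != set(range_flags["pop"]):
        raise ValueError("population ids do not match across components")

    sens = sensitivities.copy()
    if "sensitivity" not in sens.columns:
        sens["sensitivity"] = [
            combine_sensitivity(a, n)
            for a, n in zip(sens["adaptive_code"], sens["neutral_code"])
        ]
    merged = (exposures.merge(sens, on="pop").merge(range_flags, on="pop"))
    rows = []
    for rec in merged.itertuples():
        ra = risk_level(int(rec.exposure), rec.sensitivity, rec.range_shift,
                        pop=rec.pop)
        rows.append({"pop": rec.pop, "exposure": ra.exposure,
                     "sensitivity": ra.sensitivity,
                     "range_shift": ra.range_shift, "risk": ra.risk,
                     "rule_path": ra.rule_path})
    return pd.DataFrame(rows)
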