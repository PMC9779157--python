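"""Pedestrian attributes, categorical codings, and synthetic survey generation.

The escape-decision model is driven by a coded attribute vector per
respondent — age grade, gender, education, familiarity with the area,
companion-group size, residence distance, and travel mode.  This module owns
the label-to-code mappings, a reproducible population sampler, and a
questionnaire emulator that draws stay/escape outcomes from the probit hazard
implied by a coefficient set.  The emulator exists because the original
survey data (4527 respondents) is not publicly deposited; it lets every
downstream stage be exercised and calibrated end to end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedestrian",
    "AttributeDistributions",
    "CodingError",
    "ATTR_FIELDS",
    "CODINGS",
    "encode_record",
    "decode_record",
    "sample_population",
    "default_distributions",
    "simulate_survey",
    "read_records",
    "write_records",
    "RECORD_COLUMNS",
]


class CodingError(ValueError):
    """Raised when a raw label does not match any known category."""


#: Field order of the attribute vector.
ATTR_FIELDS = ("age", "gen", "edu", "time", "group", "zone", "mode")

# Canonical label -> numeric code, one mapping per field.  Age has five
# grades; gender is 1 = male, 0 = female; travel mode is entered as a single
# numeric covariate with codes 1..7 in the listed order.
_AGE = {"<18": 1, "18-30": 2, "31-45": 3, "46-60": 4, ">60": 5}
_GEN = {"male": 1, "female": 0}
_EDU = {"high school and below": 1, "college": 2, "graduate and above": 3}
_TIME = {"<2 years": 1, "2-5 years": 2, "5-10 years": 3, ">10 years": 4}
_GROUP = {"1 ped": 1, "2 ped": 2, "3 ped": 3, ">3 ped": 4}
_ZONE = {"<2 km": 1, "2-5 km": 2, "5-10 km": 3, "10-30 km": 4, ">30 km": 5}
_MODE = {
    "car": 1,
    "subway": 2,
    "tricycle": 3,
    "conventional bus": 4,
    "bicycle": 5,
    "walk": 6,
    "taxi": 7,
}

CODINGS: Mapping[str, Mapping[str, int]] = {
    "age": _AGE,
    "gen": _GEN,
    "edu": _EDU,
    "time": _TIME,
    "group": _GROUP,
    "zone": _ZONE,
    "mode": _MODE,
}

# Common paraphrases seen on survey forms, normalised to canonical labels.
_SYNONYMS: Mapping[str, Mapping[str, str]] = {
    "age": {"less than 18": "<18", "under 18": "<18", "over 60": ">60", "60 above": ">60"},
    "time": {"less than 2 years": "<2 years", "10 year above": ">10 years", "10 years above": ">10 years"},
    "group": {"3 ped and above": ">3 ped"},
    "zone": {"30 km above": ">30 km", "less than 2 km": "<2 km"},
    "mode": {"bus": "conventional bus", "walking": "walk"},
}

_CODE_RANGES = {
    "age": (1, 5),
    "gen": (0, 1),
    "edu": (1, 3),
    "time": (1, 4),
    "group": (1, 4),
    "zone": (1, 5),
    "mode": (1, 7),
}


def _normalize(label: str) -> str:
    s = str(label).strip().lower()
    s = s.replace("–", "-").replace("—", "-").replace("~", "-")
    s = re.sub(r"\s*-\s*", "-", s)
    s = re.sub(r"\s+", " ", s)
    return s


@dataclass
class Pedestrian:
    """One respondent or simulated agent with coded attributes.

    ``position`` (planar metres) and ``origin_zone`` are set only for agents
    placed in a simulation scene.
    """

    id: int
    age_grade: int
    gender: int
    education: int
    familiarity_time: int
    group_size: int
    zone_distance: int
    travel_mode: int
    position: tuple[float, float] | None = None
    origin_zone: int | None = None

    def __post_init__(self) -> None:
        for fname, attr in zip(ATTR_FIELDS, (
            "age_grade", "gender", "education", "familiarity_time",
            "group_size", "zone_distance", "travel_mode",
        )):
            lo, hi = _CODE_RANGES[fname]
            v = getattr(self, attr)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ValueError(
                    f"{attr} must be an integer in [{lo}, {hi}], got {v!r}"
                )

    def coded(self) -> dict[str, int]:
        """Attribute vector as a field-name -> code mapping."""
        return {
            "age": int(self.age_grade),
            "gen": int(self.gender),
            "edu": int(self.education),
            "time": int(self.familiarity_time),
            "group": int(self.group_size),
            "zone": int(self.zone_distance),
            "mode": int(self.travel_mode),
        }


def encode_record(raw: Mapping[str, str], id: int = 0) -> Pedestrian:
    """Encode a raw labelled record into a coded :class:`Pedestrian`.

    Every attribute field must be present and match one of the documented
    categories (case-insensitive, tolerant of dash variants).  Unknown labels
    raise :class:`CodingError` naming the field and the offending label —
    records are never silently imputed.
    """
    codes: dict[str, int] = {}
    for fname in ATTR_FIELDS:
        if fname not in raw:
            raise CodingError(f"missing field {fname!r} in record {dict(raw)!r}")
        label = _normalize(raw[fname])
        label = _SYNONYMS.get(fname, {}).get(label, label)
        table = CODINGS[fname]
        if label not in table:
            raise CodingError(
                f"unknown category {raw[fname]!r} for field {fname!r}; "
                f"expected one of {sorted(table)}"
            )
        codes[fname] = table[label]
    return Pedestrian(
        id=id,
        age_grade=codes["age"],
        gender=codes["gen"],
        education=codes["edu"],
        familiarity_time=codes["time"],
        group_size=codes["group"],
        zone_distance=codes["zone"],
        travel_mode=codes["mode"],
    )


def decode_record(ped: Pedestrian) -> dict[str, str]:
    """Canonical labels of a coded pedestrian (inverse of :func:`encode_record`)."""
    inv = {f: {v: k for k, v in CODINGS[f].items()} for f in ATTR_FIELDS}
    coded = ped.coded()
    return {f: inv[f][coded[f]] for f in ATTR_FIELDS}


@dataclass
class AttributeDistributions:
    """Per-attribute category probabilities for population sampling.

    ``probs[field][j]`` is the probability of the j-th category code (codes
    ascending; for gender that is ``[P(female), P(male)]``).  Attributes are
    sampled independently: the survey the generator emulates reports no
    dependence structure, so none is imposed.
    """

    probs: Mapping[str, Sequence[float]]
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population size must be >= 1, got {self.n}")
        for fname in ATTR_FIELDS:
            if fname not in self.probs:
                raise ValueError(f"missing probability vector for field {fname!r}")
            p = np.asarray(self.probs[fname], dtype=float)
            if len(p) != len(CODINGS[fname]):
                raise ValueError(
                    f"{fname}: expected {len(CODINGS[fname])} category "
                    f"probabilities, got {len(p)}"
                )
            if (p < 0).any():
                raise ValueError(f"{fname}: negative probability mass")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{fname}: probabilities sum to {p.sum()!r}, not 1")

    def codes(self, fname: str) -> np.ndarray:
        return np.array(sorted(CODINGS[fname].values()))


def default_distributions(n: int, seed: int | None = None) -> AttributeDistributions:
    """Plausible urban-survey marginals used as the package default.

    The original survey's marginal tables are not published; these values
    describe a mixed metropolitan day-time crowd (working-age majority,
    near-even gender split, transit-heavy mode mix) and are documented in the
    methods note.
    """
    return AttributeDistributions(
        probs={
            "age": (0.06, 0.34, 0.31, 0.18, 0.11),
            "gen": (0.48, 0.52),
            "edu": (0.35, 0.45, 0.20),
            "time": (0.25, 0.30, 0.25, 0.20),
            "group": (0.45, 0.30, 0.15, 0.10),
            "zone": (0.15, 0.25, 0.25, 0.20, 0.15),
            "mode": (0.20, 0.30, 0.03, 0.17, 0.10, 0.15, 0.05),
        },
        n=n,
        seed=seed,
    )


def sample_population(
    dist: AttributeDistributions, rng: np.random.Generator | None = None
) -> list[Pedestrian]:
    """Draw ``dist.n`` pedestrians with independent categorical attributes.

    With a fixed seed the output is bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(dist.seed)
    draws = {
        f: rng.choice(dist.codes(f), size=dist.n, p=np.asarray(dist.probs[f], float))
        for f in ATTR_FIELDS
    }
    return [
        Pedestrian(
            id=i,
            age_grade=int(draws["age"][i]),
            gender=int(draws["gen"][i]),
            education=int(draws["edu"][i]),
            familiarity_time=int(draws["time"][i]),
            group_size=int(draws["group"][i]),
            zone_distance=int(draws["zone"][i]),
            travel_mode=int(draws["mode"][i]),
        )
        for i in range(dist.n)
    ]


#: Fixed column order of the respondent-level record table.
RECORD_COLUMNS = (
    "pid", "age", "gen", "edu", "time", "group", "zone", "mode",
    "rcs", "dfd", "rnc", "response", "period", "is_control",
)

_SCALE_VALUES = np.array([1.00, 0.75, 0.50, 0.25])


def _context_matrix(context, n: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve the context specification into an (n, 3) array of scales."""
    from .risk import RiskContext  # local to avoid import cycles in docs builds

    if isinstance(context, str):
        if context != "random":
            raise ValueError(f"unknown context spec {context!r}")
        return rng.choice(_SCALE_VALUES, size=(n, 3))
    if isinstance(context, RiskContext):
        return np.tile([context.rcs, context.dfd, context.rnc], (n, 1))
    ctx = np.asarray(context, dtype=float)
    if ctx.shape != (n, 3):
        raise ValueError(f"context array must have shape ({n}, 3), got {ctx.shape}")
    if ((ctx < 0) | (ctx > 1)).any():
        raise ValueError("context values must lie in [0, 1]")
    return ctx


def simulate_survey(
    population: Sequence[Pedestrian],
    coeffs,
    context="random",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_periods: int | None = None,
    intercept_mode: str = "periods",
    control_subjects: int = 0,
    control_rate: float | None = None,
) -> pd.DataFrame:
    """Emulate a questionnaire wave: stay/escape outcomes from the probit hazard.

    For each respondent a per-period escape probability
    ``p_t = C + (1 - C) * Phi(lp_t / sigma)`` is evaluated on that
    respondent's linear predictor and the first-escape period is drawn
    sequentially; respondents who never escape within the horizon are
    recorded as censored (``response = 0`` at the final period).

    Parameters
    ----------
    population
        Coded pedestrians (e.g. from :func:`sample_population`).
    coeffs
        A :class:`~preevac.model.CoefficientSet`.
    context
        ``"random"`` (each respondent judges an independently drawn
        level-quantized scenario vignette), a single
        :class:`~preevac.risk.RiskContext` shared by all respondents, or an
        ``(n, 3)`` array of (rcs, dfd, rnc) values.
    n_periods
        Decision periods observed; defaults to the number of period
        intercepts in ``coeffs`` (minimum 1).
    intercept_mode
        ``"periods"`` uses the per-period intercepts (``coeffs.thresholds``);
        ``"const"`` uses the single constant — the single-equation probit
        special case.
    control_subjects, control_rate
        Optional control-group rows whose response probability is the
        natural-response rate alone (default ``coeffs.natural_rate``).

    Returns
    -------
    pandas.DataFrame
        One row per respondent with columns :data:`RECORD_COLUMNS`.
    """
    from .model import hazard_probability, period_intercept

    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(population)
    if n == 0:
        raise ValueError("population is empty")
    if intercept_mode not in ("periods", "const"):
        raise ValueError(f"intercept_mode must be 'periods' or 'const', got {intercept_mode!r}")
    T = n_periods if n_periods is not None else max(len(coeffs.thresholds), 1)
    if T < 1:
        raise ValueError(f"n_periods must be >= 1, got {T}")

    coded = pd.DataFrame([p.coded() for p in population])
    ctx = _context_matrix(context, n, rng)

    attr_names = list(coeffs.attr_coeffs)
    missing = [a for a in attr_names if a not in coded.columns]
    if missing:
        raise ValueError(f"missing covariates for coefficients {missing!r}")
    beta = np.array([coeffs.attr_coeffs[a] for a in attr_names])
    gamma = np.array([coeffs.context_coeffs.get(c, 0.0) for c in ("rcs", "dfd", "rnc")])
    base = coded[attr_names].to_numpy(float) @ beta + ctx @ gamma

    # Sequential first-escape draw, vectorised over respondents.
    u = rng.random((n, T))
    response = np.zeros(n, dtype=int)
    period = np.full(n, T, dtype=int)
    alive = np.ones(n, dtype=bool)
    for t in range(1, T + 1):
        icpt = coeffs.const if intercept_mode == "const" else period_intercept(coeffs, t)
        p_t = hazard_probability(base + icpt, coeffs)
        esc = alive & (u[:, t - 1] < p_t)
        response[esc] = 1
        period[esc] = t
        alive &= ~esc

    out = pd.DataFrame({
        "pid": [p.id for p in population],
        **{a: coded[a].to_numpy() for a in ATTR_FIELDS},
        "rcs": ctx[:, 0],
        "dfd": ctx[:, 1],
        "rnc": ctx[:, 2],
        "response": response,
        "period": period,
        "is_control": 0,
    })

    if control_subjects:
        C = coeffs.natural_rate if control_rate is None else float(control_rate)
        if not 0.0 <= C < 1.0:
            raise ValueError(f"control rate must lie in [0, 1), got {C!r}")
        pick = rng.integers(0, n, size=control_subjects)
        ctrl = out.iloc[pick, : 8 + 3].copy().reset_index(drop=True)
        ctrl["pid"] = np.arange(n, n + control_subjects)
        ctrl["response"] = (rng.random(control_subjects) < C).astype(int)
        ctrl["period"] = 1
        ctrl["is_control"] = 1
        out = pd.concat([out, ctrl], ignore_index=True)

    return out[list(RECORD_COLUMNS)]


def write_records(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a respondent-level record table as delimited UTF-8 text."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns {missing!r}")
    df[list(RECORD_COLUMNS)].to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_records(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a respondent-level record table, validating the fixed schema."""
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path!s} missing columns {missing!r}")
    from .model import validate_records

    validate_records(df)
    return df
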