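"""Left-censored biomarker handling: detection limits, classification,
prevalence and percentile tables, substitution, deficiency flags.

Trace-element assays report a concentration only when it exceeds the limit
of quantification (LoQ); values between the limit of detection (LoD) and
the LoQ are "detected but not quantified", and values below the LoD are
indistinguishable from blank noise. Every record therefore carries a
three-state censoring category (plus a toxicity flag), and all summaries
here are rank-based so that censored mass is never converted into invented
numbers silently. When a numeric vector is unavoidable (spatial statistics,
interpolation) the substitution scheme is an explicit, recorded choice.

Category labels are stable strings: ``below_lod``, ``lod_loq``,
``quantified``, ``toxic``. Interval convention is half-open:
[0, LoD) -> below_lod, [LoD, LoQ) -> lod_loq, [LoQ, toxic) -> quantified,
[toxic, inf) -> toxic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DataError

CATEGORIES = ("below_lod", "lod_loq", "quantified", "toxic")

#: Published serum detection/quantification limits and acute-exposure upper
#: limits, ug/L (clinical-chemistry reference thresholds for children).
PUBLISHED_LIMITS: dict[str, "DetectionLimits"] = {}


@dataclass(frozen=True)
class DetectionLimits:
    """Per-analyte LoD / LoQ / toxicity threshold, all ug/L."""

    analyte: str
    lod: float
    loq: float
    toxic: float

    def __post_init__(self):
        if not (0 < self.lod < self.loq < self.toxic):
            raise ConfigurationError(
                f"{self.analyte}: limits must satisfy 0 < lod < loq < toxic, "
                f"got lod={self.lod}, loq={self.loq}, toxic={self.toxic}"
            )


for _name, _lod, _loq, _tox in [
    ("As", 0.2, 0.55, 20.0),
    ("Cd", 0.006, 0.019, 50.0),
    ("Hg", 0.2, 0.83, 50.0),
    ("Pb", 0.6, 2.1, 50.0),
]:
    PUBLISHED_LIMITS[_name] = DetectionLimits(_name, _lod, _loq, _tox)


@dataclass
class CensoredSeries:
    """Per-record analyte observations with censoring categories.

    ``values`` holds the measured concentration where the category is
    ``quantified`` or ``toxic`` and NaN otherwise — a censored record has no
    usable number, only its category.
    """

    analyte: str
    category: np.ndarray  # dtype object/str, entries in CATEGORIES
    values: np.ndarray  # float, NaN where censored
    limits: DetectionLimits

    def __post_init__(self):
        self.category = np.asarray(self.category, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.category.shape != self.values.shape:
            raise DataError("category and values must have identical shape")
        bad = set(self.category) - set(CATEGORIES)
        if bad:
            raise DataError(f"unknown categories {sorted(bad)}")

    def __len__(self) -> int:
        return self.category.size

    @property
    def n(self) -> int:
        return self.category.size

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.category == c)) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"analyte": self.analyte, "category": self.category, "value": self.values}
        )


@dataclass(frozen=True)
class PrevalenceRow:
    """One Table-3-style row: counts and percentages per censoring category.

    ``detected`` aggregates everything at or above the LoD; ``quantified``
    percentages include toxic records (toxicity is a sub-state of
    quantification for counting purposes).
    """

    analyte: str
    n: int
    counts: dict[str, int]
    percentages: dict[str, float]
    detected_count: int
    detected_pct: float
    quantified_total_count: int
    quantified_total_pct: float


@dataclass(frozen=True)
class CensoredPercentiles:
    """Rank-based percentile summary; each entry is a float (ug/L) or a
    censored label string."""

    analyte: str
    percentiles: dict[float, "float | str"]


@dataclass(frozen=True)
class Substitution:
    """Numeric stand-in vector for a censored series, with the scheme recorded."""

    analyte: str
    scheme: str
    values: np.ndarray


@dataclass(frozen=True)
class DeficiencyThresholds:
    """Micronutrient / haematology deficiency cut-offs (strict ``<``).

    ``se_unit`` declares the unit the selenium column is expressed in
    (``"ug_L"`` or ``"ug_dL"``); the threshold value must be given in that
    same unit — reference texts quote Se cut-offs in ug/dL while serum
    panels often report ug/L, so neither reading is hard-coded.
    """

    hb_anemia: float = 11.0  # g/dL
    transferrin_sat_pct: float = 20.0  # %
    zn: float = 65.0  # ug/dL
    se: float = 70.0  # in se_unit
    se_unit: str = "ug_L"
    cu: float = 80.0  # ug/dL
    z_cutoff: float = -2.0  # growth z-scores

    def __post_init__(self):
        for name in ("hb_anemia", "transferrin_sat_pct", "zn", "se", "cu"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be strictly positive")
        if self.se_unit not in ("ug_L", "ug_dL"):
            raise ConfigurationError(f"unknown se_unit {self.se_unit!r}")


def compute_limits(
    blanks: Sequence[float], toxic_threshold: float, analyte: str = ""
) -> DetectionLimits:
    """Detection limits from instrument blanks: LoD = 3*SD, LoQ = 10*SD.

    SD is the sample standard deviation (n-1 denominator) of the blank
    measurements taken through the full preparation procedure.
    """
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 2:
        raise DataError("need at least 2 blank measurements")
    sd = float(np.std(blanks, ddof=1))
    if sd == 0.0:
        raise DataError(f"{analyte or 'analyte'}: blanks are constant (SD = 0), limits degenerate")
    return DetectionLimits(analyte=analyte, lod=3.0 * sd, loq=10.0 * sd, toxic=float(toxic_threshold))


def classify(values: Sequence[float], limits: DetectionLimits) -> CensoredSeries:
    """Classify raw concentrations into censoring categories.

    Half-open intervals: ``[0, lod)`` below_lod, ``[lod, loq)`` lod_loq,
    ``[loq, toxic)`` quantified, ``>= toxic`` toxic. Numeric values are
    retained only for quantified/toxic records.
    """
    values = np.asarray(values, dtype=float)
    neg = np.flatnonzero(values < 0)
    if neg.size:
        raise DataError(
            f"{limits.analyte}: negative concentration at record(s) {neg[:5].tolist()}"
        )
    category = np.empty(values.shape, dtype=object)
    category[values < limits.lod] = "below_lod"
    category[(values >= limits.lod) & (values < limits.loq)] = "lod_loq"
    category[(values >= limits.loq) & (values < limits.toxic)] = "quantified"
    category[values >= limits.toxic] = "toxic"
    out = values.copy()
    out[(category == "below_lod") | (category == "lod_loq")] = np.nan
    return CensoredSeries(limits.analyte, category, out, limits)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_table(series: CensoredSeries) -> PrevalenceRow:
    """Counts and percentages (1 decimal, half-up) per censoring category."""
    if series.n == 0:
        raise DataError("empty series")
    counts = series.counts()
    n = series.n
    pct = {c: _round_half_up(100.0 * counts[c] / n) for c in CATEGORIES}
    detected = counts["lod_loq"] + counts["quantified"] + counts["toxic"]
    quant = counts["quantified"] + counts["toxic"]
    return PrevalenceRow(
        analyte=series.analyte,
        n=n,
        counts=counts,
        percentages=pct,
        detected_count=detected,
        detected_pct=_round_half_up(100.0 * detected / n),
        quantified_total_count=quant,
        quantified_total_pct=_round_half_up(100.0 * quant / n),
    )


def prevalence_frame(rows: Sequence[PrevalenceRow]) -> pd.DataFrame:
    """Assemble PrevalenceRows into a Table-3-style DataFrame."""
    recs = []
    for r in rows:
        rec = {"analyte": r.analyte, "n": r.n}
        for c in CATEGORIES:
            rec[f"{c}_n"] = r.counts[c]
            rec[f"{c}_pct"] = r.percentages[c]
        rec["detected_n"] = r.detected_count
        rec["detected_pct"] = r.detected_pct
        recs.append(rec)
    return pd.DataFrame(recs)


DEFAULT_PROBS = (5.0, 25.0, 50.0, 75.0, 95.0, 99.0)


def censored_percentiles(
    series: CensoredSeries, probs: Sequence[float] = DEFAULT_PROBS
) -> CensoredPercentiles:
    """Rank-based percentiles of a censored sample.

    Records are ordered below_lod < lod_loq < numeric ascending. Each
    requested percentile is located by the linear-interpolation rule on
    order statistics (h = (n-1)p); if either bracketing order statistic is
    censored the censored label is emitted (the later statistic wins when
    both are censored), otherwise the numeric interpolation. Output is
    non-decreasing in p under the ordering
    below_lod < lod_loq < any number >= LoQ.
    """
    n = series.n
    if n == 0:
        raise DataError("empty series")
    order = {"below_lod": 0, "lod_loq": 1}
    # sort key: censored blocks first (value irrelevant inside a block),
    # then numeric ascending
    keys = np.array(
        [
            (order.get(c, 2), v if np.isfinite(v) else -np.inf)
            for c, v in zip(series.category, series.values)
        ]
    )
    idx = np.lexsort((keys[:, 1], keys[:, 0]))
    cat_sorted = series.category[idx]
    val_sorted = series.values[idx]

    out: dict[float, float | str] = {}
    for p in probs:
        if not (0 <= p <= 100):
            raise ConfigurationError(f"percentile {p} outside [0, 100]")
        h = (n - 1) * p / 100.0
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        if cat_sorted[hi] in ("below_lod", "lod_loq"):
            out[float(p)] = str(cat_sorted[hi])
        elif cat_sorted[lo] in ("below_lod", "lod_loq"):
            out[float(p)] = str(cat_sorted[lo])
        else:
            out[float(p)] = float(val_sorted[lo] + (h - lo) * (val_sorted[hi] - val_sorted[lo]))
    return CensoredPercentiles(series.analyte, out)


SUBSTITUTION_SCHEMES = ("half_lod_mid", "lod_sqrt2", "category_rank")


def substitute(series: CensoredSeries, scheme: str = "half_lod_mid") -> Substitution:
    """Replace censored records by explicit numeric stand-ins.

    Schemes
    -------
    half_lod_mid
        below_lod -> LoD/2, lod_loq -> (LoD+LoQ)/2 (interval midpoints).
    lod_sqrt2
        below_lod -> LoD/sqrt(2) (the classic nondetect convention),
        lod_loq -> (LoD+LoQ)/2.
    category_rank
        Ordinal encoding: below_lod -> 0, lod_loq -> 1, numeric records ->
        2, 3, ... in ascending value order (average ranks for ties). Rank
        order is identical to any monotone numeric scheme, so rank-based
        statistics are substitution-invariant under it.
    """
    if scheme not in SUBSTITUTION_SCHEMES:
        raise ConfigurationError(
            f"unknown substitution scheme {scheme!r}; choose from {SUBSTITUTION_SCHEMES}"
        )
    lod, loq = series.limits.lod, series.limits.loq
    below = series.category == "below_lod"
    mid = series.category == "lod_loq"
    numeric = ~(below | mid)
    out = series.values.astype(float).copy()
    if scheme == "category_rank":
        out[below] = 0.0
        out[mid] = 1.0
        if numeric.any():
            out[numeric] = 1.0 + rankdata(series.values[numeric], method="average")
    else:
        out[below] = lod / 2.0 if scheme == "half_lod_mid" else lod / np.sqrt(2.0)
        out[mid] = (lod + loq) / 2.0
    return Substitution(series.analyte, scheme, out)


#: covariate column -> (threshold attribute, comparison) used by flag_deficiencies
_FLAG_SPEC = {
    "anemia": ("hb", "hb_anemia"),
    "iron_deficiency": ("transferrin_sat", "transferrin_sat_pct"),
    "zinc_deficiency": ("zn", "zn"),
    "selenium_deficiency": ("se", "se"),
    "copper_deficiency": ("cu", "cu"),
    "stunting": ("haz", "z_cutoff"),
    "wasting": ("whz", "z_cutoff"),
    "underweight": ("waz", "z_cutoff"),
}


def flag_deficiencies(
    covariates: pd.DataFrame,
    thresholds: DeficiencyThresholds | None = None,
) -> pd.DataFrame:
    """Boolean deficiency flags per record (strict ``<`` thresholds).

    Expects columns among ``hb`` (g/dL), ``transferrin_sat`` (%), ``zn``
    (ug/dL), ``se`` (in ``thresholds.se_unit``), ``cu`` (ug/dL) and growth
    z-scores ``haz``/``whz``/``waz``. A missing value yields ``pd.NA``
    (unknown), never ``False``; a wholly absent column is skipped.
    """
    thresholds = thresholds or DeficiencyThresholds()
    flags = pd.DataFrame(index=covariates.index)
    for flag, (col, attr) in _FLAG_SPEC.items():
        if col not in covariates.columns:
            continue
        x = pd.to_numeric(covariates[col], errors="coerce")
        cut = getattr(thresholds, attr)
        f = pd.array(x < cut, dtype="boolean")
        f[x.isna()] = pd.NA
        flags[flag] = f
    return flags
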