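"""Clinical screening arithmetic for primary aldosteronism.

Primary aldosteronism (PA) is screened with the aldosterone:renin ratio
(ARR).  Laboratory reports routinely censor values at assay detection limits
("<0.1", ">200"), so the ratio must be propagated through interval
arithmetic: an exact aldosterone over a renin reported below its detection
bound yields a *lower bound* on the ratio, and so on.  Classification rules:

* ARR > 20 (ng/dl per ng/ml/hr) with aldosterone > 15 ng/dl is indicative of
  PA;
* using a direct renin immunoassay, aldosterone/direct-renin > 2.4 with
  aldosterone > 15 ng/dl is the equivalent rule;
* a marginally elevated ARR (> 20 with aldosterone <= 15 ng/dl) counts only
  in the presence of unexplained hypokalemia (K+ < 3.5 mmol/l).

Censored values are evaluated conservatively: a rule fires only when every
value consistent with the censoring satisfies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = [
    "CensoredMeasure",
    "LabPanel",
    "PAClassification",
    "compute_arr",
    "classify_pa",
    "read_lab_panels",
]

Relation = Literal["equal", "below", "above", "indeterminate"]

#: ARR threshold (aldosterone ng/dl per PRA ng/ml/hr) indicative of PA.
ARR_THRESHOLD = 20.0
#: Equivalent threshold for the aldosterone / direct-renin ratio.
DIRECT_RATIO_THRESHOLD = 2.4
#: Aldosterone threshold (ng/dl) accompanying an elevated ratio.
ALDO_THRESHOLD = 15.0
#: Hypokalemia bound (mmol/l) for the marginal rule.
HYPOKALEMIA_K = 3.5


@dataclass(frozen=True)
class CensoredMeasure:
    """A laboratory value with a censoring relation.

    ``relation="equal"`` means the value is exact; ``"below"`` means the true
    value lies in ``[0, value)`` (reported as ``<value``); ``"above"`` means
    it lies in ``(value, inf)`` (reported as ``>value``).  The
    ``"indeterminate"`` relation is produced only by interval arithmetic on
    doubly censored operands and carries an explicit ``upper`` bound.
    """

    value: float
    relation: Relation = "equal"
    units: str = ""
    upper: float | None = None  # only for relation == "indeterminate"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentrations must be non-negative")
        if self.relation == "indeterminate" and self.upper is None:
            raise ValueError("indeterminate measure requires an upper bound")

    @classmethod
    def parse(cls, text: str | float, units: str = "") -> "CensoredMeasure":
        """Parse ``"<0.1"`` / ``">200"`` / plain-number strings."""
        if isinstance(text, (int, float)):
            return cls(float(text), "equal", units)
        s = str(text).strip()
        if s.startswith("<"):
            return cls(float(s[1:]), "below", units)
        if s.startswith(">"):
            return cls(float(s[1:]), "above", units)
        return cls(float(s), "equal", units)

    def interval(self) -> tuple[float, float]:
        """The set of true values consistent with the report, as (lo, hi)."""
        if self.relation == "equal":
            return self.value, self.value
        if self.relation == "below":
            return 0.0, self.value
        if self.relation == "above":
            return self.value, math.inf
        return self.value, float(self.upper)  # indeterminate

    def definitely_gt(self, threshold: float) -> bool:
        """True iff every consistent value exceeds ``threshold``."""
        lo, hi = self.interval()
        if self.relation == "equal":
            return self.value > threshold
        # open lower end for "above"/"indeterminate": lo itself excluded
        return lo >= threshold if self.relation in ("above", "indeterminate") else False

    def definitely_lt(self, threshold: float) -> bool:
        """True iff every consistent value is below ``threshold``."""
        if self.relation == "equal":
            return self.value < threshold
        if self.relation == "below":
            return self.value <= threshold
        return False

    def __str__(self) -> str:
        prefix = {"equal": "", "below": "<", "above": ">"}.get(self.relation)
        if prefix is None:
            return f"[{self.value:g}, {self.upper:g}] (indeterminate)"
        return f"{prefix}{self.value:g}"


@dataclass(frozen=True)
class LabPanel:
    """One subject's screening panel.

    At least one of ``pra`` (plasma renin activity, ng/ml/hr) or
    ``direct_renin`` (µIU/ml) must be present for PA classification.
    """

    aldosterone: CensoredMeasure
    pra: CensoredMeasure | None = None
    direct_renin: CensoredMeasure | None = None
    potassium: CensoredMeasure | None = None
    subject: str = ""


@dataclass(frozen=True)
class PAClassification:
    """Outcome of the PA screening rules for one panel."""

    arr: CensoredMeasure
    indicative: bool
    rule_fired: str
    renin_kind: str


def compute_arr(
    aldosterone: CensoredMeasure,
    renin: CensoredMeasure,
    renin_kind: str = "pra",
) -> CensoredMeasure:
    """Aldosterone:renin ratio with censoring propagated by interval arithmetic.

    The ratio interval is ``[aldo_lo/renin_hi, aldo_hi/renin_lo]``; it maps
    back onto a censored scalar where one end is trivial, and is flagged
    indeterminate otherwise.  Values are *not* rounded here; round at the
    reporting boundary (e.g. :meth:`CensoredMeasure.__str__` consumers use 1
    decimal).

    Raises
    ------
    ZeroDivisionError
        If the renin is exactly zero ("undefined ratio").
    """
    if renin.relation == "equal" and renin.value == 0:
        raise ZeroDivisionError("undefined ratio: renin is exactly 0")
    if renin.relation == "below" and renin.value <= 0:
        raise ValueError("censored renin bound must be positive")
    units = f"{aldosterone.units}:{renin.units}" if aldosterone.units else ""

    a_lo, a_hi = aldosterone.interval()
    r_lo, r_hi = renin.interval()
    lo = 0.0 if math.isinf(r_hi) else a_lo / r_hi
    hi = math.inf if r_lo == 0 else a_hi / r_lo

    if lo == hi:
        return CensoredMeasure(lo, "equal", units)
    if math.isinf(hi):
        if lo == 0.0:
            # conflicting censoring: no information about the ratio
            return CensoredMeasure(0.0, "indeterminate", units, upper=math.inf)
        return CensoredMeasure(lo, "above", units)
    if lo == 0.0:
        return CensoredMeasure(hi, "below", units)
    return CensoredMeasure(lo, "indeterminate", units, upper=hi)


def round_ratio(m: CensoredMeasure, ndigits: int = 1) -> CensoredMeasure:
    """Ratio rounded for reporting (thresholds are applied before rounding)."""
    upper = None if m.upper is None else round(m.upper, ndigits)
    return CensoredMeasure(round(m.value, ndigits), m.relation, m.units, upper)


def classify_pa(panel: LabPanel) -> PAClassification:
    """Apply the PA screening rules to one lab panel.

    Rules (first match wins):

    1. ``arr_elevated`` — ARR (via PRA) > 20 and aldosterone > 15 ng/dl.
    2. ``direct_ratio_elevated`` — aldosterone/direct-renin > 2.4 and
       aldosterone > 15 ng/dl.
    3. ``marginal_with_hypokalemia`` — ratio above its threshold but
       aldosterone <= 15, with K+ < 3.5 mmol/l.

    Censored inputs only satisfy a rule when the rule holds for every value
    consistent with the censoring.
    """
    if panel.pra is None and panel.direct_renin is None:
        raise ValueError("classification requires PRA or direct renin")

    if panel.pra is not None:
        ratio = compute_arr(panel.aldosterone, panel.pra, "pra")
        threshold, kind = ARR_THRESHOLD, "pra"
    else:
        ratio = compute_arr(panel.aldosterone, panel.direct_renin, "direct")
        threshold, kind = DIRECT_RATIO_THRESHOLD, "direct"

    ratio_high = ratio.definitely_gt(threshold)
    aldo_high = panel.aldosterone.definitely_gt(ALDO_THRESHOLD)
    hypokalemic = panel.potassium is not None and panel.potassium.definitely_lt(
        HYPOKALEMIA_K
    )

    if ratio_high and aldo_high:
        rule = "arr_elevated" if kind == "pra" else "direct_ratio_elevated"
        return PAClassification(ratio, True, rule, kind)
    if ratio_high and not aldo_high and hypokalemic:
        return PAClassification(ratio, True, "marginal_with_hypokalemia", kind)
    return PAClassification(ratio, False, "none", kind)


def read_lab_panels(path) -> list[LabPanel]:
    """Read screening panels from CSV.

    Expected headers: ``subject`` (optional), ``aldo`` (ng/dl), and at least
    one of ``pra`` (ng/ml/hr) / ``direct_renin`` (µIU/ml); optional ``k``
    (mmol/l).  Any cell may be prefixed ``<`` or ``>``.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "aldo" not in df.columns:
        raise ValueError("lab CSV requires an 'aldo' column")

    def cell(row, col, units):
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        raw = str(raw).strip()
        if raw == "" or raw.upper() in ("NA", "NAN"):
            return None
        return CensoredMeasure.parse(raw, units)

    panels = []
    for _, row in df.iterrows():
        panels.append(
            LabPanel(
                aldosterone=cell(row, "aldo", "ng/dl"),
                pra=cell(row, "pra", "ng/ml/hr"),
                direct_renin=cell(row, "direct_renin", "uIU/ml"),
                potassium=cell(row, "k", "mmol/l"),
                subject=str(row.get("subject", "")).strip(),
            )
        )
    return panels
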