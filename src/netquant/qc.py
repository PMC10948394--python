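"""Supervised quality control of automated NET percentages.

Slides whose automated NET percentage falls strictly outside
mean +/- k * SD (default k = 2) of their own (group, condition) stratum
are flagged for visual recount. Where a recount was done, the manual
value replaces the automated one in downstream analysis; the automated
value and a provenance flag are always preserved. Flagged slides that
were never recounted keep the automated value with a persistent
"unreviewed_outlier" flag — data are never silently dropped.

The standard deviation is the sample (n - 1) SD. Strata with fewer than
three slides are reported as unflaggable rather than tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .net_calling import SlideResult


@dataclass
class StratumQc:
    group: str
    condition: str
    n: int
    mean: float
    sd: float
    lower: float
    upper: float
    flaggable: bool
    flagged: list[tuple[str, float]] = dc_field(default_factory=list)


@dataclass
class QcReport:
    k: float
    strata: list[StratumQc]
    overrides_applied: list[str] = dc_field(default_factory=list)

    @property
    def flagged_slides(self) -> list[tuple[str, str]]:
        """(slide_id, condition) pairs of every flagged slide."""
        out = []
        for s in self.strata:
            out.extend((sid, s.condition) for sid, _ in s.flagged)
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "strata": [
                {
                    "group": s.group, "condition": s.condition, "n": s.n,
                    "mean": s.mean, "sd": s.sd,
                    "lower": s.lower, "upper": s.upper,
                    "flaggable": s.flaggable,
                    "flagged": [{"slide_id": sid, "value": v} for sid, v in s.flagged],
                }
                for s in self.strata
            ],
            "overrides_applied": list(self.overrides_applied),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)


def flag_outliers(slide_results: Sequence[SlideResult], k: float = 2.0) -> QcReport:
    """Flag slides strictly outside mean +/- k * sample SD of their stratum.

    Strata are (group, condition); slides with undefined NET percentages
    are excluded from their stratum's statistics. Strata with n < 3 are
    reported but marked unflaggable.
    """
    strata: dict[tuple[str, str], list[SlideResult]] = {}
    for s in slide_results:
        strata.setdefault((s.group, s.condition), []).append(s)

    out: list[StratumQc] = []
    for (group, condition), members in sorted(strata.items()):
        valid = [m for m in members if not math.isnan(m.net_percent)]
        values = np.array([m.net_percent for m in valid], dtype=float)
        n = len(values)
        if n < 3:
            out.append(StratumQc(group, condition, n, math.nan, math.nan,
                                 math.nan, math.nan, flaggable=False))
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        lower, upper = mean - k * sd, mean + k * sd
        flagged = [(m.slide_id, m.net_percent) for m in valid
                   if m.net_percent < lower or m.net_percent > upper]
        out.append(StratumQc(group, condition, n, mean, sd, lower, upper,
                             flaggable=True, flagged=flagged))
    return QcReport(k=k, strata=out)


OverrideTable = Union[pd.DataFrame, Iterable[Mapping]]


def apply_overrides(
    slide_results: Sequence[SlideResult],
    overrides: OverrideTable,
) -> list[SlideResult]:
    """Replace automated values with visual recounts where provided.

    ``overrides`` has columns/keys slide_id, condition, manual_net_percent.
    The override targets must exist and the manual values lie in [0, 100].
    Applying the same override twice is a no-op (idempotent).
    """
    if isinstance(overrides, pd.DataFrame):
        records = overrides.to_dict("records")
    else:
        records = [dict(r) for r in overrides]

    index = {(s.slide_id, s.condition): i for i, s in enumerate(slide_results)}
    updated = list(slide_results)
    for rec in records:
        key = (str(rec["slide_id"]), str(rec["condition"]))
        if key not in index:
            raise ValidationError(f"override for unknown slide/condition {key}")
        value = float(rec["manual_net_percent"])
        if not (0.0 <= value <= 100.0):
            raise ValidationError(
                f"manual NET percentage {value} for {key} outside [0, 100]")
        updated[index[key]] = updated[index[key]].with_override(value)
    return updated


def mark_unreviewed_outliers(
    slide_results: Sequence[SlideResult],
    report: QcReport,
) -> list[SlideResult]:
    """Tag flagged slides that received no manual recount."""
    flagged = set(report.flagged_slides)
    out = []
    for s in slide_results:
        if (s.slide_id, s.condition) in flagged and s.manual_override is None:
            out.append(replace(
                s, flags=tuple(dict.fromkeys((*s.flags, "unreviewed_outlier")))))
        else:
            out.append(s)
    return out
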