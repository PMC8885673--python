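"""Baseline-characteristics summary of the paired cohort."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError


@dataclass
class CohortSummary:
    """Table-1-style cohort description.

    Continuous characteristics are mean (sd); sd is None (absent, not
    zero) for a single subject.  Categorical characteristics are
    count (%) over non-missing values.  Adherence gets mean, median and
    range.
    """

    n: int
    age_mean: float
    age_sd: float | None
    sex_counts: dict
    sex_percent: dict
    hla_counts: dict
    hla_percent: dict
    autoantibody_counts: dict  # by "0" / "1" / ">=2"
    autoantibody_percent: dict
    adherence_mean: float
    adherence_median: float
    adherence_range: tuple

    def summary(self) -> str:
        lines = [
            f"Cohort of {self.n} paired subjects",
            f"  age: {self.age_mean:.1f}"
            + (f" ({self.age_sd:.1f})" if self.age_sd is not None else " (sd n/a)")
            + " years",
            "  sex: "
            + ", ".join(
                f"{k} {v} ({self.sex_percent[k]:.0f}%)"
                for k, v in sorted(self.sex_counts.items())
            ),
            "  HLA risk: "
            + ", ".join(
                f"{k} {v} ({self.hla_percent[k]:.0f}%)"
                for k, v in sorted(self.hla_counts.items())
            ),
            "  autoantibodies: "
            + ", ".join(
                f"{k}: {v} ({self.autoantibody_percent[k]:.0f}%)"
                for k, v in self.autoantibody_counts.items()
            ),
            f"  adherence: mean {self.adherence_mean:.0f}%, "
            f"median {self.adherence_median:.0f}%, "
            f"range {self.adherence_range[0]:.0f}-{self.adherence_range[1]:.0f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["adherence_range"] = list(self.adherence_range)
        return d


def summarize_cohort(pairs) -> CohortSummary:
    """Summarise subject metadata into a baseline-characteristics table."""
    pairs = list(pairs)
    if not pairs:
        raise EmptyInputError("empty cohort")
    n = len(pairs)
    ages = np.array([p.age for p in pairs], dtype=float)
    adherence = np.array([p.adherence for p in pairs], dtype=float)

    def count_pct(values):
        counts: dict = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        pct = {k: 100.0 * v / n for k, v in counts.items()}
        return counts, pct

    sex_counts, sex_pct = count_pct([p.sex for p in pairs])
    hla_counts, hla_pct = count_pct([p.hla_risk for p in pairs])
    aab_bin = [
        "0" if p.autoantibody_count == 0
        else "1" if p.autoantibody_count == 1
        else ">=2"
        for p in pairs
    ]
    aab_counts, aab_pct = count_pct(aab_bin)
    ordered = {k: aab_counts.get(k, 0) for k in ("0", "1", ">=2")}
    ordered_pct = {k: aab_pct.get(k, 0.0) for k in ("0", "1", ">=2")}

    return CohortSummary(
        n=n,
        age_mean=float(np.nanmean(ages)),
        age_sd=float(np.nanstd(ages, ddof=1)) if n > 1 else None,
        sex_counts=sex_counts,
        sex_percent=sex_pct,
        hla_counts=hla_counts,
        hla_percent=hla_pct,
        autoantibody_counts=ordered,
        autoantibody_percent=ordered_pct,
        adherence_mean=float(np.nanmean(adherence)),
        adherence_median=float(np.nanmedian(adherence)),
        adherence_range=(float(np.nanmin(adherence)), float(np.nanmax(adherence))),
    )
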